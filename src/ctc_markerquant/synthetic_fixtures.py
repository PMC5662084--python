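"""Synthetic thumbnails, cell-line populations, cohorts and reader panels.

Everything downstream of the microscope is testable without real data:
this module renders blob-shaped cells on Gaussian background noise at 12-bit
depth, archives them to 8-bit with recorded min/max headers exactly the way
the loader expects, and generates event populations, patient cohorts and
reader-score matrices with known ground truth (including closed-form
expected accuracies, so scoring tests have an analytic oracle).

Blobs are flat-top disks with an optional Gaussian-smoothed skirt outside
the disk, so the plateau intensity *is* the expected in-mask mean — the
quantification oracle is exact.  Background noise defaults to sigma = 6.6
(the typical background spread of archived thumbnails) around a low positive
level so that clipping at zero is negligible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import SpecError
from .io_rescale import (
    CHANNELS,
    DEFAULT_PIXEL_SIZE_UM,
    FULL_SCALE_12BIT,
    EventThumbnail,
    FluorescentFrame,
    load_thumbnail,
    write_thumbnail_tiff,
)
from .scoring import CLASSES, Her2Thresholds, ReaderScoreMatrix

#: Default background noise level (robust sd of archived thumbnails).
DEFAULT_BACKGROUND_SIGMA: float = 6.6
#: Default background mean, high enough that zero-clipping is negligible.
DEFAULT_BACKGROUND_MU: float = 30.0
#: Default thumbnail size in pixels.
DEFAULT_SHAPE: tuple[int, int] = (80, 80)


@dataclass(frozen=True)
class BlobSpec:
    """A flat-top disk: plateau value inside ``radius``, soft Gaussian skirt.

    The default is a hard edge (softness 0), which keeps the in-mask truth
    mean exactly at the plateau *and* makes the plateau extent recoverable
    exactly; a positive softness adds a sub-pixel Gaussian skirt outside the
    disk for more realistic edge profiles.
    """

    center: tuple[float, float]
    radius_px: float
    plateau: float
    softness_px: float = 0.0

    def __post_init__(self) -> None:
        if self.radius_px < 2:
            raise SpecError("blob radius must be >= 2 px")
        if not 0 <= self.plateau <= FULL_SCALE_12BIT:
            raise SpecError(f"plateau must lie in [0, {FULL_SCALE_12BIT}]")
        if self.softness_px < 0:
            raise SpecError("softness must be non-negative")


@dataclass(frozen=True)
class EventSpec:
    """Recipe for one synthetic four-channel thumbnail."""

    blobs: Mapping[str, tuple[BlobSpec, ...]] = field(default_factory=dict)
    background_mu: float = DEFAULT_BACKGROUND_MU
    background_sigma: float = DEFAULT_BACKGROUND_SIGMA
    shape: tuple[int, int] = DEFAULT_SHAPE
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.blobs) - set(CHANNELS)
        if unknown:
            raise SpecError(f"unknown channels in blob map: {sorted(unknown)}")
        if self.background_sigma < 0 or not (
            0 <= self.background_mu <= FULL_SCALE_12BIT
        ):
            raise SpecError("background parameters out of range")
        for blobs in self.blobs.values():
            for blob in blobs:
                # plateau 0 encodes "no signal"; a real blob must sit above bg
                if 0 < blob.plateau <= self.background_mu:
                    raise SpecError(
                        "blob plateau must be 0 (absent) or above the "
                        f"background level {self.background_mu}"
                    )


@dataclass(frozen=True)
class ChannelTruth:
    """Ground truth for one rendered channel."""

    mask: np.ndarray            # union of blob disks (d <= radius)
    truth_mean: float           # expected in-mask mean (0 if no blob)
    centers: tuple[tuple[float, float], ...]
    header_min: int = 0
    header_max: int = 0


@dataclass(frozen=True)
class EventTruth:
    channels: Mapping[str, ChannelTruth]
    pre_archive: Mapping[str, np.ndarray]   # float 12-bit frames before archiving


def _render_channel(
    spec: EventSpec, channel: str, rng: np.random.Generator
) -> tuple[np.ndarray, ChannelTruth]:
    h, w = spec.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    amplitude = np.zeros(spec.shape)
    mask = np.zeros(spec.shape, dtype=bool)
    centers = []
    for blob in spec.blobs.get(channel, ()):
        if blob.plateau == 0:   # encodes "no signal in this channel"
            continue
        d = np.hypot(yy - blob.center[0], xx - blob.center[1])
        inside = d <= blob.radius_px
        if blob.softness_px > 0:
            skirt = np.exp(-((d - blob.radius_px) ** 2)
                           / (2.0 * blob.softness_px**2))
            wgt = np.where(inside, 1.0, skirt)
        else:
            wgt = inside.astype(float)
        # overlapping blobs combine by max, so plateaus are preserved
        amplitude = np.maximum(amplitude, wgt * (blob.plateau - spec.background_mu))
        mask |= inside
        centers.append(blob.center)
    clean = spec.background_mu + amplitude
    noisy = clean + rng.normal(0.0, spec.background_sigma, size=spec.shape)
    frame12 = np.clip(noisy, 0.0, float(FULL_SCALE_12BIT))
    truth_mean = 0.0
    if mask.any():
        truth_mean = float(np.mean(clean[mask]))
    return frame12, ChannelTruth(mask=mask, truth_mean=truth_mean,
                                 centers=tuple(centers))


def _archive_channel(frame12: np.ndarray) -> tuple[np.ndarray, int, int]:
    """12-bit float frame -> 8-bit page plus integer (min, max) header."""
    mn = int(np.floor(frame12.min()))
    mx = int(np.ceil(frame12.max()))
    if mx == mn:
        mx = mn + 1  # degenerate constant frame: 1-count span
    page = np.rint((frame12 - mn) * (255.0 / (mx - mn))).astype(np.uint8)
    return page, mn, mx


def render_event(spec: EventSpec) -> tuple[dict[str, np.ndarray], EventTruth]:
    """Render the four 12-bit float channel frames plus ground truth."""
    rng = np.random.default_rng(spec.seed)
    frames: dict[str, np.ndarray] = {}
    truths: dict[str, ChannelTruth] = {}
    for channel in CHANNELS:   # fixed order keeps the noise stream reproducible
        frame12, truth = _render_channel(spec, channel, rng)
        frames[channel] = frame12
        truths[channel] = truth
    return frames, EventTruth(channels=truths, pre_archive=frames)


def thumbnail_from_spec(
    spec: EventSpec,
    event_id: str = "synthetic",
    sample_id: str = "",
    patient_id: str = "",
) -> tuple[EventThumbnail, EventTruth]:
    """Render, archive and reload in memory (no disk round trip).

    The returned thumbnail contains archived, *un-rescaled* 8-bit frames with
    header min/max exactly as a TIFF written by :func:`generate_thumbnail`
    would reload.
    """
    frames12, truth = render_event(spec)
    frames: dict[str, FluorescentFrame] = {}
    truth_channels: dict[str, ChannelTruth] = {}
    for channel in CHANNELS:
        page, mn, mx = _archive_channel(frames12[channel])
        frames[channel] = FluorescentFrame(
            channel_name=channel,
            pixels=page.astype(np.float64),
            stored_bit_depth=8,
            header_min=float(mn),
            header_max=float(mx),
            pixel_size_um=spec.pixel_size_um,
            is_rescaled=False,
        )
        ct = truth.channels[channel]
        truth_channels[channel] = ChannelTruth(
            mask=ct.mask, truth_mean=ct.truth_mean, centers=ct.centers,
            header_min=mn, header_max=mx,
        )
    thumb = EventThumbnail(event_id=event_id, sample_id=sample_id,
                           patient_id=patient_id, frames=frames)
    return thumb, EventTruth(channels=truth_channels, pre_archive=frames12)


def generate_thumbnail(
    spec: EventSpec,
    out_dir: str | Path,
    event_id: str = "synthetic",
    channel_order: Sequence[str] = CHANNELS,
) -> tuple[Path, EventTruth]:
    """Write an archived thumbnail TIFF plus a JSON truth manifest.

    Deterministic per seed: the same spec produces byte-identical files.
    Returns the TIFF path and the in-memory ground truth.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _, truth = thumbnail_from_spec(spec, event_id=event_id)
    pages, headers = [], []
    for channel in channel_order:
        page, mn, mx = _archive_channel(truth.pre_archive[channel])
        pages.append(page)
        headers.append((mn, mx))
    tiff_path = out_dir / f"{event_id}.tif"
    write_thumbnail_tiff(tiff_path, pages, headers)
    manifest = {
        "event_id": event_id,
        "seed": spec.seed,
        "shape": list(spec.shape),
        "background": {"mu": spec.background_mu, "sigma": spec.background_sigma},
        "channel_order": list(channel_order),
        "channels": {
            ch: {
                "truth_mean": truth.channels[ch].truth_mean,
                "centers": [list(c) for c in truth.channels[ch].centers],
                "header_min": truth.channels[ch].header_min,
                "header_max": truth.channels[ch].header_max,
            }
            for ch in channel_order
        },
    }
    (out_dir / f"{event_id}.json").write_text(json.dumps(manifest, indent=2))
    return tiff_path, truth


def reload_thumbnail(
    tiff_path: str | Path, channel_order: Sequence[str] = CHANNELS, **kwargs
) -> EventThumbnail:
    """Convenience loader matching :func:`generate_thumbnail`'s layout."""
    channel_map = {i: ch for i, ch in enumerate(channel_order)}
    return load_thumbnail(tiff_path, channel_map, **kwargs)


# ---------------------------------------------------------------------------
# Cell-line-like populations with closed-form expected accuracy


@dataclass(frozen=True)
class ClassModel:
    """Generative model of the mean marker intensity for one truth class.

    ``kind`` is one of 'constant', 'normal', 'truncnorm' (truncated below at
    ``lower``), or 'uniform'.  ``params``:
      constant: (value,); normal: (mu, sd); truncnorm: (mu, sd, lower);
      uniform: (low, high).
    """

    kind: str
    params: tuple[float, ...]

    def _frozen(self):
        if self.kind == "normal":
            mu, sd = self.params
            return stats.norm(mu, sd)
        if self.kind == "truncnorm":
            mu, sd, lower = self.params
            a = (lower - mu) / sd
            return stats.truncnorm(a, np.inf, loc=mu, scale=sd)
        if self.kind == "uniform":
            low, high = self.params
            return stats.uniform(low, high - low)
        raise SpecError(f"unknown class model kind {self.kind!r}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "constant":
            return np.full(n, self.params[0])
        dist = self._frozen()
        return dist.rvs(size=n, random_state=rng)

    def prob_in(self, low: float, high: float) -> float:
        """P(low < X < high); ``high=inf`` for an upper tail, closed form."""
        if self.kind == "constant":
            return float(low < self.params[0] < high)
        dist = self._frozen()
        hi = 1.0 if np.isinf(high) else float(dist.cdf(high))
        return hi - float(dist.cdf(low))

    def prob_at_most(self, value: float) -> float:
        if self.kind == "constant":
            return float(self.params[0] <= value)
        return float(self._frozen().cdf(value))


def default_population_models() -> dict[str, ClassModel]:
    """Cell-line-like regime: negative exactly 0; dim and bright Gaussian
    populations overlapping the bright threshold so some misclassification
    occurs (as in real cell-line calibration runs)."""
    return {
        "negative": ClassModel("constant", (0.0,)),
        "dim": ClassModel("truncnorm", (80.0, 15.0, 0.0)),
        "bright": ClassModel("normal", (120.0, 15.0)),
    }


@dataclass(frozen=True)
class PopulationSpec:
    """Class sizes default to a three-cell-line calibration run
    (373 negative-line, 496 dim-line, 361 bright-line cells)."""

    models: Mapping[str, ClassModel] = field(
        default_factory=default_population_models)
    sizes: Mapping[str, int] = field(
        default_factory=lambda: {"negative": 373, "dim": 496, "bright": 361})
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.sizes) - set(CLASSES) or set(self.models) - set(CLASSES):
            raise SpecError(f"classes must be among {CLASSES}")
        if any(n < 1 for n in self.sizes.values()):
            raise SpecError("class sizes must be >= 1")
        missing = set(self.sizes) - set(self.models)
        if missing:
            raise SpecError(f"no model for classes {sorted(missing)}")


def analytic_accuracy(
    spec: PopulationSpec, thresholds: Her2Thresholds | None = None
) -> float:
    """Closed-form expected accuracy of threshold classification."""
    thresholds = thresholds or Her2Thresholds()
    total = sum(spec.sizes.values())
    acc = 0.0
    for cls, n in spec.sizes.items():
        model = spec.models[cls]
        if cls == "negative":
            p = model.prob_at_most(thresholds.t_dim)
        elif cls == "dim":
            p = model.prob_in(thresholds.t_dim, thresholds.t_bright)
        else:
            if model.kind == "constant":
                p = float(model.params[0] >= thresholds.t_bright)
            else:  # continuous: P(X >= t) == P(X > t)
                p = 1.0 - model.prob_at_most(thresholds.t_bright)
        acc += n * p
    return acc / total


def generate_population(
    spec: PopulationSpec,
) -> tuple[np.ndarray, list[str], float]:
    """Sample per-event mean intensities with truth labels.

    Returns ``(means, true_classes, analytic_accuracy)``; the analytic value
    is the oracle the empirical classification accuracy is checked against.
    Negative draws (possible for an un-truncated normal) are clipped to 0,
    mirroring the physical floor of measured intensities.
    """
    rng = np.random.default_rng(spec.seed)
    means, labels = [], []
    for cls in CLASSES:   # fixed order for reproducibility
        if cls not in spec.sizes:
            continue
        draws = spec.models[cls].sample(rng, spec.sizes[cls])
        means.append(np.clip(draws, 0.0, None))
        labels.extend([cls] * spec.sizes[cls])
    return np.concatenate(means), labels, analytic_accuracy(spec)


# ---------------------------------------------------------------------------
# Patient cohorts


@dataclass(frozen=True)
class CohortSpec:
    """A metastatic-cohort-like mixture of patient heterogeneity patterns.

    Defaults emulate a 132-patient, 4084-event study: a small fraction of
    patients with every event marker-positive, a larger fraction with none,
    and the rest mixed with Beta-distributed positive fractions; positive
    events split dim vs bright so that bright events stay rare.
    """

    n_patients: int = 132
    n_events: int = 4084
    p_all_positive: float = 8 / 132
    p_none_positive: float = 14 / 132
    mixed_beta: tuple[float, float] = (2.0, 3.1)
    p_bright_given_positive: float = 0.062
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_events < self.n_patients:
            raise SpecError("need >= 1 patient and >= 1 event per patient")
        if not 0 <= self.p_all_positive + self.p_none_positive <= 1:
            raise SpecError("pattern probabilities must be a sub-probability")


def generate_cohort(spec: CohortSpec) -> "list[tuple[str, list[str]]]":
    """Per-patient lists of true event classes, ``[(patient_id, classes)]``.

    Event counts per patient follow a heavy-tailed (lognormal) distribution,
    normalised to the requested cohort total with a minimum of one event per
    patient, matching the skewed per-patient tumor-cell counts seen in real
    cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    raw = rng.lognormal(mean=0.0, sigma=1.3, size=spec.n_patients)
    counts = np.maximum(1, np.rint(raw * (spec.n_events / raw.sum())).astype(int))
    # adjust the largest patients so totals match exactly
    diff = spec.n_events - int(counts.sum())
    order = np.argsort(-counts)
    i = 0
    while diff != 0:
        idx = order[i % spec.n_patients]
        step = 1 if diff > 0 else -1
        if counts[idx] + step >= 1:
            counts[idx] += step
            diff -= step
        i += 1
    cohort: list[tuple[str, list[str]]] = []
    for p in range(spec.n_patients):
        n = int(counts[p])
        u = rng.random()
        if u < spec.p_all_positive:
            n_pos = n
        elif u < spec.p_all_positive + spec.p_none_positive:
            n_pos = 0
        else:
            frac = rng.beta(*spec.mixed_beta)
            if n == 1:
                # a single-event patient cannot be mixed; realize the latent
                # fraction as an all-or-none outcome
                n_pos = int(rng.random() < frac)
            else:
                # a mixed-pattern patient shows both classes by construction
                n_pos = int(np.clip(rng.binomial(n, frac), 1, n - 1))
        positives = [
            "bright" if rng.random() < spec.p_bright_given_positive else "dim"
            for _ in range(n_pos)
        ]
        classes = positives + ["negative"] * (n - n_pos)
        perm = rng.permutation(n)
        cohort.append((f"patient_{p:03d}", [classes[i] for i in perm]))
    return cohort


# ---------------------------------------------------------------------------
# Reader panels


def generate_reader_scores(
    true_positive: Sequence[bool],
    flip_probabilities: Sequence[float],
    seed: int = 0,
    display_condition: str = "quantitative",
) -> ReaderScoreMatrix:
    """Binary reviewer calls: truth flipped independently per reviewer.

    ``flip_probabilities`` gives each reviewer's error rate; deterministic
    per seed.
    """
    if any(not 0 <= p <= 1 for p in flip_probabilities):
        raise SpecError("flip probabilities must lie in [0, 1]")
    if len(flip_probabilities) < 2:
        raise SpecError("need at least two reviewers")
    rng = np.random.default_rng(seed)
    truth = np.asarray(true_positive, dtype=bool)[:, None]
    flips = rng.random((truth.shape[0], len(flip_probabilities))) < np.asarray(
        flip_probabilities)[None, :]
    votes = truth ^ flips
    return ReaderScoreMatrix(
        votes=votes,
        reviewer_ids=tuple(f"reviewer_{i + 1}" for i in range(len(flip_probabilities))),
        event_ids=tuple(f"event_{i:04d}" for i in range(truth.shape[0])),
        display_condition=display_condition,
    )
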