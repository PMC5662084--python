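"""Per-object, per-channel measurements and derived statistics.

For every segmented object we report the feature vector used throughout the
pipeline: eccentricity, perimeter, mean intensity, maximum intensity, size,
standard deviation of the intensity, mass (sum of all intensity values) and
perimeter2area (a circularity measure normalised so a perfect disk -> 1).
Intensities are on the restored 12-bit instrument scale and are *not*
background-subtracted: a channel with no detectable object is encoded as an
all-zero record (size 0, mean 0), which is exactly what makes a mean-intensity
cutoff of 0 separate marker-negative from marker-dim events.

Also here: the relative overlay of two channels' segmented areas, the Welch
two-sided t-test used to compare the in-contour pixel populations of two
events, and the ordinary-least-squares line calibrating measured marker
intensity to absolute antigen counts (bead-based flow-cytometry reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage import measure

from .errors import FormatError
from .io_rescale import CHANNELS, EventThumbnail, FluorescentFrame, ensure_rescaled
from .segmentation import (
    SegmentedObject,
    segment_multiscale,
    select_event_object,
)


@dataclass(frozen=True)
class ChannelMeasurements:
    """The per-object, per-channel feature vector (all-zero when no object)."""

    eccentricity: float = 0.0
    perimeter: float = 0.0
    mean_intensity: float = 0.0
    max_intensity: float = 0.0
    size: int = 0
    std_intensity: float = 0.0
    mass: float = 0.0
    perimeter2area: float = 0.0
    median_intensity: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.eccentricity < 1.0 + 1e-12:
            raise FormatError("eccentricity must lie in [0, 1)")
        if self.size < 0 or self.mean_intensity < 0 or self.mass < 0:
            raise FormatError("size, mean and mass must be non-negative")
        if self.size and self.max_intensity < self.mean_intensity - 1e-9:
            raise FormatError("max intensity cannot undercut the mean")


@dataclass
class EventRecord:
    """All measurements for one event, across the four channels."""

    event_id: str
    patient_id: str
    sample_id: str = ""
    channels: dict[str, ChannelMeasurements] = field(default_factory=dict)
    dapi_cd45_overlay: float = 0.0
    dapi_ck_overlay: float = 0.0
    her2_class: str | None = None   # filled by the scoring stage
    manual_her2_score: int | None = None

    def __post_init__(self) -> None:
        for frac in (self.dapi_cd45_overlay, self.dapi_ck_overlay):
            if not 0.0 <= frac <= 1.0:
                raise FormatError("overlay fractions must lie in [0, 1]")

    @property
    def marker_mean(self) -> float:
        return self.channels["MARKER1"].mean_intensity


@dataclass(frozen=True)
class CalibrationLine:
    """Least-squares line mapping measured intensity to antigens per cell."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise FormatError("r_squared must lie in [0, 1]")


def measure_channel(
    obj: SegmentedObject | None, frame: FluorescentFrame
) -> ChannelMeasurements:
    """Measure one channel's event object; absent object -> all-zero record.

    Mean/max/std/mass are computed over the raw rescaled pixels inside the
    mask (population std, so a single-pixel object has std 0).  Perimeter is
    the polyline length of the object's traced contour; eccentricity comes
    from central second moments, sqrt(1 - (minor/major)^2); perimeter2area is
    perimeter^2 / (4*pi*size).
    """
    if obj is None:
        return ChannelMeasurements()
    if obj.mask.shape != frame.pixels.shape:
        raise FormatError("object mask is not congruent with the frame")
    values = frame.pixels[obj.mask]
    perimeter = _polyline_length(obj.contour)
    props = measure.regionprops(obj.mask.astype(np.uint8))[0]
    size = int(obj.area_px)
    return ChannelMeasurements(
        eccentricity=float(props.eccentricity),
        perimeter=perimeter,
        mean_intensity=float(values.mean()),
        max_intensity=float(values.max()),
        size=size,
        std_intensity=float(values.std(ddof=0)),
        mass=float(values.sum()),
        perimeter2area=perimeter**2 / (4.0 * np.pi * size),
        median_intensity=float(np.median(values)),
    )


def _polyline_length(contour: np.ndarray) -> float:
    diffs = np.diff(contour, axis=0)
    return float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())


def relative_overlay(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """|a intersect b| / |a|; 0 when the reference mask ``a`` is empty.

    Convention: ``mask_a`` is the reference (DAPI) mask, i.e. the overlay is
    the fraction of the nuclear area that the other channel shares.
    """
    if mask_a.shape != mask_b.shape:
        raise FormatError("overlay masks must be congruent")
    denom = int(mask_a.sum())
    if denom == 0:
        return 0.0
    return float((mask_a & mask_b).sum() / denom)


def measure_event(thumbnail: EventThumbnail) -> EventRecord:
    """Run the full per-event pipeline: rescale, segment, select, measure.

    Every channel is segmented independently; the event-defining object per
    channel is the one best overlapping the DAPI nucleus (largest DAPI
    object).  Deterministic for a given thumbnail.
    """
    frames = {name: ensure_rescaled(f) for name, f in thumbnail.frames.items()}
    objects = {name: segment_multiscale(frames[name]) for name in CHANNELS}

    dapi_objs = objects["DAPI"]
    if dapi_objs:
        nucleus = max(dapi_objs, key=lambda o: (o.area_px, o.centroid)).mask
    else:
        nucleus = np.zeros(thumbnail.shape, dtype=bool)

    selected = {
        name: select_event_object(objects[name], nucleus) for name in CHANNELS
    }
    channels = {
        name: measure_channel(selected[name], frames[name]) for name in CHANNELS
    }
    empty = np.zeros(thumbnail.shape, dtype=bool)
    dapi_mask = selected["DAPI"].mask if selected["DAPI"] else empty
    cd45_mask = selected["CD45"].mask if selected["CD45"] else empty
    ck_mask = selected["CK"].mask if selected["CK"] else empty
    return EventRecord(
        event_id=thumbnail.event_id,
        patient_id=thumbnail.patient_id,
        sample_id=thumbnail.sample_id,
        channels=channels,
        dapi_cd45_overlay=relative_overlay(dapi_mask, cd45_mask),
        dapi_ck_overlay=relative_overlay(dapi_mask, ck_mask),
        manual_her2_score=thumbnail.manual_her2_score,
    )


def intensity_difference_test(
    pixels_a: np.ndarray, pixels_b: np.ndarray
) -> tuple[float, float]:
    """Welch two-sided t-test between two events' in-contour pixel samples.

    Treats pixels as independent draws (spatial correlation is ignored, a
    documented caveat).  Returns (t statistic, two-sided p value).
    """
    a = np.asarray(pixels_a, dtype=np.float64).ravel()
    b = np.asarray(pixels_b, dtype=np.float64).ravel()
    if a.size < 2 or b.size < 2:
        raise FormatError("both pixel samples need at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(t):  # identical constant samples: no mean difference
        return 0.0, 1.0
    return float(t), float(p)


def fit_antigen_calibration(
    points: "list[tuple[float, float]]",
) -> CalibrationLine:
    """OLS line through (measured marker intensity, antigens per cell) pairs.

    Needs at least two distinct intensity values; a degenerate design (all
    intensities identical) raises a :class:`FormatError`.
    """
    if len(points) < 2:
        raise FormatError("calibration needs at least two points")
    x = np.asarray([p[0] for p in points], dtype=np.float64)
    y = np.asarray([p[1] for p in points], dtype=np.float64)
    if np.allclose(x, x[0]):
        raise FormatError("degenerate calibration: all intensities identical")
    fit = stats.linregress(x, y)
    return CalibrationLine(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )
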