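"""HER-2 expression classification and cohort-level statistics.

Per-event classification uses two fixed intensity thresholds on the restored
12-bit scale: an event with mean marker intensity exactly 0 (no segmented
object) is *negative*, strictly between 0 and 100 is *dim*, and at or above
100 is *bright*.  The 0 cutoff works because segmentation constructs a
separating gap: channels without real signal produce no object at all.

Cohort statistics mirror the downstream reporting needs: per-patient
negative/dim/bright counts with an all/none/mixed heterogeneity label,
pooled class percentages, Pearson correlation between manual and automated
positive-event counts per sample, and the reader-concordance histogram for a
panel of reviewers scoring the same events.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import FormatError

CLASSES: tuple[str, ...] = ("negative", "dim", "bright")

#: Manual ordinal scores (0,1+,2+,3+ as ranks 0..3) count as positive from 2+.
MANUAL_POSITIVE_MIN_RANK: int = 2


@dataclass(frozen=True)
class Her2Thresholds:
    """The two intensity cutoffs separating negative/dim/bright."""

    t_dim: float = 0.0
    t_bright: float = 100.0

    def __post_init__(self) -> None:
        if not 0 <= self.t_dim < self.t_bright:
            raise FormatError("thresholds must satisfy 0 <= t_dim < t_bright")


@dataclass(frozen=True)
class PatientSummary:
    patient_id: str
    n_total: int
    n_negative: int
    n_dim: int
    n_bright: int
    heterogeneity: str      # 'all_positive' | 'none_positive' | 'mixed'
    fraction_positive: float

    def __post_init__(self) -> None:
        if self.n_total != self.n_negative + self.n_dim + self.n_bright:
            raise FormatError("class counts must partition the total")


@dataclass(frozen=True)
class ReaderScoreMatrix:
    """Events x reviewers grid of binary calls (True = marker positive)."""

    votes: np.ndarray               # boolean (n_events, n_reviewers)
    reviewer_ids: tuple[str, ...]
    event_ids: tuple[str, ...] = ()
    display_condition: str = "quantitative"   # or 'scaled'

    def __post_init__(self) -> None:
        v = np.asarray(self.votes)
        if v.ndim != 2 or v.shape[1] < 2:
            raise FormatError("need a 2-D matrix with >= 2 reviewers")
        if v.shape[1] != len(self.reviewer_ids):
            raise FormatError("reviewer_ids must match the matrix width")
        if self.event_ids and len(self.event_ids) != v.shape[0]:
            raise FormatError("event_ids must match the matrix height")
        object.__setattr__(self, "votes", v.astype(bool))

    @property
    def n_events(self) -> int:
        return self.votes.shape[0]

    @property
    def n_reviewers(self) -> int:
        return self.votes.shape[1]


@dataclass(frozen=True)
class ConcordanceHistogram:
    """Fractions of events per agreement category for a reviewer panel.

    Category names follow the six-reviewer reading: 'five_agree' means all
    but one reviewer agreed, 'four_agree' all but two, 'three_indifferent' an
    exact split (possible only for even panels).  ``direction`` records, for
    each non-unanimous category, how often the majority voted positive.
    """

    unanimous_positive: float
    unanimous_negative: float
    five_agree: float
    four_agree: float
    three_indifferent: float
    n_events: int
    direction: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = (self.unanimous_positive + self.unanimous_negative
                 + self.five_agree + self.four_agree + self.three_indifferent)
        if abs(total - 1.0) > 1e-9:
            raise FormatError("category fractions must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return {
            "unanimous_positive": self.unanimous_positive,
            "unanimous_negative": self.unanimous_negative,
            "five_agree": self.five_agree,
            "four_agree": self.four_agree,
            "three_indifferent": self.three_indifferent,
        }


def classify_her2(mean_intensity: float, thresholds: Her2Thresholds | None = None) -> str:
    """Map a mean marker intensity to 'negative' / 'dim' / 'bright'.

    Boundary semantics: negative iff mean <= t_dim (the no-object encoding at
    the default t_dim = 0), bright iff mean >= t_bright, dim strictly in
    between.
    """
    thresholds = thresholds or Her2Thresholds()
    if mean_intensity < 0:
        raise FormatError("mean intensity cannot be negative")
    if mean_intensity <= thresholds.t_dim:
        return "negative"
    if mean_intensity < thresholds.t_bright:
        return "dim"
    return "bright"


def classify_population(
    mean_intensities: Sequence[float],
    true_classes: Sequence[str],
    thresholds: Her2Thresholds | None = None,
) -> tuple[float, dict[tuple[str, str], int]]:
    """Accuracy and 3x3 confusion counts against ground-truth class labels.

    Returns ``(accuracy, confusion)`` with ``confusion[(true, predicted)]``
    counts summing to the input size.
    """
    if len(mean_intensities) == 0:
        raise FormatError("empty population")
    if len(mean_intensities) != len(true_classes):
        raise FormatError("means and labels must pair up")
    confusion: dict[tuple[str, str], int] = {
        (t, p): 0 for t in CLASSES for p in CLASSES
    }
    correct = 0
    for mean, truth in zip(mean_intensities, true_classes):
        if truth not in CLASSES:
            raise FormatError(f"unknown true class {truth!r}")
        pred = classify_her2(mean, thresholds)
        confusion[(truth, pred)] += 1
        correct += truth == pred
    return correct / len(mean_intensities), confusion


def summarize_patient(
    patient_id: str, classes: Iterable[str]
) -> PatientSummary:
    """Count classes for one patient and label the heterogeneity pattern."""
    counts = Counter(classes)
    unknown = set(counts) - set(CLASSES)
    if unknown:
        raise FormatError(f"unknown classes {sorted(unknown)}")
    n_total = sum(counts.values())
    if n_total == 0:
        raise FormatError("a patient summary needs at least one event")
    n_neg, n_dim, n_bright = counts["negative"], counts["dim"], counts["bright"]
    if n_neg == 0:
        het = "all_positive"
    elif n_dim == 0 and n_bright == 0:
        het = "none_positive"
    else:
        het = "mixed"
    return PatientSummary(
        patient_id=patient_id,
        n_total=n_total,
        n_negative=n_neg,
        n_dim=n_dim,
        n_bright=n_bright,
        heterogeneity=het,
        fraction_positive=(n_dim + n_bright) / n_total,
    )


def cohort_breakdown(summaries: Sequence[PatientSummary]) -> dict:
    """Cohort totals: heterogeneity counts and pooled class percentages.

    Patients are also returned sorted by decreasing fraction of
    marker-positive events (the standard per-patient heterogeneity display
    order).
    """
    if not summaries:
        raise FormatError("empty cohort")
    het = Counter(s.heterogeneity for s in summaries)
    n_events = sum(s.n_total for s in summaries)
    pooled = {
        "negative": sum(s.n_negative for s in summaries),
        "dim": sum(s.n_dim for s in summaries),
        "bright": sum(s.n_bright for s in summaries),
    }
    ordered = sorted(summaries, key=lambda s: (-s.fraction_positive, s.patient_id))
    return {
        "n_patients": len(summaries),
        "n_events": n_events,
        "patients_all_positive": het["all_positive"],
        "patients_none_positive": het["none_positive"],
        "patients_mixed": het["mixed"],
        "event_counts": pooled,
        "event_percentages": {k: 100.0 * v / n_events for k, v in pooled.items()},
        "patients_sorted": [s.patient_id for s in ordered],
    }


def manual_auto_correlation(
    manual_counts: Sequence[float], auto_counts: Sequence[float]
) -> dict:
    """Pearson correlation between manual and automated positive counts.

    Returns r together with a 95 % confidence interval from the Fisher
    z-transform.  Zero-variance input is flagged as an undefined correlation.
    """
    x = np.asarray(manual_counts, dtype=np.float64)
    y = np.asarray(auto_counts, dtype=np.float64)
    if x.shape != y.shape or x.size < 3:
        raise FormatError("need paired vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise FormatError("undefined correlation: zero variance input")
    r, p = stats.pearsonr(x, y)
    n = x.size
    if n > 3 and abs(r) < 1:
        z = np.arctanh(r)
        half = 1.959963984540054 / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    else:
        ci = (float(r), float(r))
    return {"r": float(r), "p_value": float(p), "ci95": ci, "n": int(n)}


def _categorize_votes(positive: int, n_reviewers: int) -> tuple[str, str]:
    """Agreement category and majority direction for one event's vote split."""
    negative = n_reviewers - positive
    majority = max(positive, negative)
    direction = "positive" if positive > negative else (
        "negative" if negative > positive else "tie")
    if majority == n_reviewers:
        return ("unanimous_positive" if positive else "unanimous_negative", direction)
    if 2 * positive == n_reviewers:
        return "three_indifferent", direction
    if majority == n_reviewers - 1:
        return "five_agree", direction
    return "four_agree", direction


def concordance_histogram(matrix: ReaderScoreMatrix) -> ConcordanceHistogram:
    """Fraction of events per agreement category for a complete reviewer panel.

    For six reviewers the categories are the classic reading: 6-0 unanimous
    (split by direction), 5-1, 4-2, and the 3-3 'indifferent' tie.  Other
    panel sizes generalize by the size of the minority (0, 1, >=2, exact tie).
    """
    if matrix.n_events == 0:
        raise FormatError("empty score matrix")
    votes = matrix.votes
    counts: Counter[str] = Counter()
    direction: dict[str, Counter] = {}
    for row in votes:
        pos = int(row.sum())
        cat, majority = _categorize_votes(pos, matrix.n_reviewers)
        counts[cat] += 1
        direction.setdefault(cat, Counter())[majority] += 1
    n = matrix.n_events
    dir_fracs = {
        cat: {d: c / sum(ctr.values()) for d, c in sorted(ctr.items())}
        for cat, ctr in direction.items()
    }
    return ConcordanceHistogram(
        unanimous_positive=counts["unanimous_positive"] / n,
        unanimous_negative=counts["unanimous_negative"] / n,
        five_agree=counts["five_agree"] / n,
        four_agree=counts["four_agree"] / n,
        three_indifferent=counts["three_indifferent"] / n,
        n_events=n,
        direction=dir_fracs,
    )


def manual_rank_is_positive(rank: int) -> bool:
    """Binary positivity of an ordinal manual score (positive from 2+ up)."""
    if rank not in (0, 1, 2, 3):
        raise FormatError("ordinal rank must be in 0..3")
    return rank >= MANUAL_POSITIVE_MIN_RANK
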