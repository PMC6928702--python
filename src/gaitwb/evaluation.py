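"""Scoring detected walking bouts against interval activity labels.

Detection and reference are rasterized to binary masks (walking = positive)
and compared sample-wise. Samples within a tolerance (default 2 s) of any
reference transition are excluded from the confusion counts, absorbing
synchronization error between the sensors and the labeling source.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "CATEGORIES",
    "WALKING_CATEGORIES",
    "DEFAULT_CATEGORY_MAP",
    "ActivityLabel",
    "LabelDialect",
    "DetectionMetrics",
    "read_labels",
    "rasterize",
    "confusion_with_tolerance",
    "walking_intervals",
    "evaluate_bouts",
    "aggregate_metrics",
]

CATEGORIES = ("straight_walking", "other_walking", "non_walking")
WALKING_CATEGORIES = ("straight_walking", "other_walking")

#: Map from free-text activity names (lower-cased) to categories. Unmapped
#: names fall back to non_walking with a warning.
DEFAULT_CATEGORY_MAP = {
    "walking": "straight_walking",
    "walk": "straight_walking",
    "straight walking": "straight_walking",
    "walking on grass": "other_walking",
    "walking on stones": "other_walking",
    "walking on tarmac": "other_walking",
    "walk_other": "other_walking",
    "curved walking": "other_walking",
    "slow walking": "other_walking",
    "fast walking": "other_walking",
    "lie": "non_walking",
    "lying": "non_walking",
    "sit": "non_walking",
    "sitting": "non_walking",
    "standing": "non_walking",
    "stairs": "non_walking",
    "climbing stairs": "non_walking",
    "descending stairs": "non_walking",
    "running": "non_walking",
    "run": "non_walking",
    "jumping": "non_walking",
    "playing on swings": "non_walking",
    "swing": "non_walking",
}


@dataclass(frozen=True)
class ActivityLabel:
    """A labeled half-open interval [start, end) with an activity category."""

    start: float
    end: float
    category: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise DataError(f"label start {self.start} must precede end {self.end}")
        if self.category not in CATEGORIES:
            raise DataError(f"unknown category {self.category!r}")

    @property
    def is_walking(self) -> bool:
        return self.category in WALKING_CATEGORIES


@dataclass
class LabelDialect:
    """CSV dialect of the label export (column names, delimiter, units)."""

    delimiter: str = ","
    activity_col: str = "activity"
    start_col: str = "start"
    end_col: str = "end"
    duration_col: Optional[str] = None  # if set, end = start + duration
    time_scale: float = 1.0  # multiply times by this to obtain seconds


def read_labels(
    path,
    dialect: LabelDialect | None = None,
    category_map: dict | None = None,
) -> list[ActivityLabel]:
    """Read, categorize, sort and validate an interval label CSV.

    Activity names are mapped to the three categories through
    ``category_map`` (case-insensitive); names that already are category
    identifiers pass through; anything unmapped becomes ``non_walking``
    with a warning. Overlapping intervals raise :class:`DataError`.
    """
    dialect = dialect or LabelDialect()
    cmap = DEFAULT_CATEGORY_MAP if category_map is None else category_map
    df = pd.read_csv(path, sep=dialect.delimiter)
    for col in (dialect.activity_col, dialect.start_col):
        if col not in df.columns:
            raise DataError(f"label file lacks column {col!r}")

    labels = []
    for _, row in df.iterrows():
        name = str(row[dialect.activity_col])
        key = name.strip().lower()
        if key in CATEGORIES:
            cat = key
        elif key in cmap:
            cat = cmap[key]
        else:
            warnings.warn(f"unmapped activity {name!r} treated as non_walking",
                          stacklevel=2)
            cat = "non_walking"
        start = float(row[dialect.start_col]) * dialect.time_scale
        if dialect.duration_col is not None:
            end = start + float(row[dialect.duration_col]) * dialect.time_scale
        else:
            end = float(row[dialect.end_col]) * dialect.time_scale
        labels.append(ActivityLabel(start=start, end=end, category=cat))

    labels.sort(key=lambda lab: lab.start)
    offenders = [
        (a, b) for a, b in zip(labels, labels[1:]) if b.start < a.end - 1e-9
    ]
    if offenders:
        msg = "; ".join(
            f"[{a.start}, {a.end}) overlaps [{b.start}, {b.end})" for a, b in offenders
        )
        raise DataError(f"overlapping label intervals: {msg}")
    return labels


def rasterize(
    intervals: Sequence[tuple[float, float]],
    duration: float,
    rate: float,
) -> np.ndarray:
    """Binary mask over ``duration`` at ``rate``; sample i covers time i/rate.

    Half-open convention: sample i is 1 iff ``start <= i/rate < end`` for
    some interval. Intervals extending beyond the duration are clipped with
    a warning.
    """
    if rate <= 0:
        raise DataError("rate must be positive")
    n = int(round(duration * rate))
    mask = np.zeros(n, dtype=np.uint8)
    for start, end in intervals:
        if end <= start:
            continue
        if start < 0 or end > duration + 1e-9:
            warnings.warn(
                f"interval [{start}, {end}) clipped to [0, {duration})", stacklevel=2
            )
        i0 = max(0, int(np.ceil(start * rate - 1e-9)))
        i1 = min(n, int(np.ceil(end * rate - 1e-9)))
        mask[i0:i1] = 1
    return mask


@dataclass
class DetectionMetrics:
    """Confusion counts and derived ratios; walking is the positive class.

    A ratio whose denominator is zero is ``None`` (missing), never 0 or 1.
    ``n_excluded`` counts samples discarded by the transition tolerance.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    n_excluded: int = 0

    @staticmethod
    def _ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    @property
    def sensitivity(self) -> Optional[float]:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Optional[float]:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def accuracy(self) -> Optional[float]:
        return self._ratio(self.tp + self.tn, self.tp + self.tn + self.fp + self.fn)

    @property
    def precision(self) -> Optional[float]:
        return self._ratio(self.tp, self.tp + self.fp)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "n_excluded": self.n_excluded,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "precision": self.precision,
        }


def confusion_with_tolerance(
    pred: np.ndarray,
    ref: np.ndarray,
    rate: float,
    tolerance: float = 2.0,
) -> DetectionMetrics:
    """Sample-wise confusion with exclusion zones around reference transitions.

    Every sample within ``+- tolerance`` seconds of a reference transition
    (a sign change of the reference mask) is excluded from counting; the
    remainder is tallied into tp/tn/fp/fn.
    """
    pred = np.asarray(pred).astype(bool)
    ref = np.asarray(ref).astype(bool)
    if pred.shape != ref.shape:
        raise DataError("pred and ref masks must have equal length")
    n = ref.size

    include = np.ones(n, dtype=bool)
    if n > 1 and tolerance > 0:
        trans = np.flatnonzero(ref[1:] != ref[:-1]) + 1  # boundary before sample i
        if trans.size:
            # exclusion zones computed in integer sample space so that the
            # +- tolerance boundary is exact on the sampling grid
            tol_samples = int(np.floor(tolerance * rate + 1e-9))
            idx = np.arange(n)
            for i in trans:
                include &= np.abs(idx - i) > tol_samples

    p, r = pred[include], ref[include]
    tp = int(np.sum(p & r))
    tn = int(np.sum(~p & ~r))
    fp = int(np.sum(p & ~r))
    fn = int(np.sum(~p & r))
    return DetectionMetrics(tp=tp, tn=tn, fp=fp, fn=fn, n_excluded=int(n - include.sum()))


def walking_intervals(labels: Sequence[ActivityLabel]) -> list[tuple[float, float]]:
    """The (start, end) spans of all walking-category labels."""
    return [(lab.start, lab.end) for lab in labels if lab.is_walking]


def evaluate_bouts(
    bouts,
    labels: Sequence[ActivityLabel],
    duration: float | None = None,
    rate: float = 10.0,
    tolerance: float = 2.0,
) -> DetectionMetrics:
    """Score detected bouts against labels at ``rate`` Hz (default 10).

    ``duration`` defaults to the last label end. Bout spans and walking
    labels are rasterized and compared via :func:`confusion_with_tolerance`.
    """
    if duration is None:
        if not labels:
            raise DataError("cannot infer duration from an empty label list")
        duration = max(lab.end for lab in labels)
    pred = rasterize([(b.start, b.end) for b in bouts], duration, rate)
    ref = rasterize(walking_intervals(labels), duration, rate)
    return confusion_with_tolerance(pred, ref, rate=rate, tolerance=tolerance)


def aggregate_metrics(metrics: Sequence[DetectionMetrics]) -> dict:
    """Median [q1, q3] per ratio across subjects; missing values are skipped."""
    out = {}
    for name in ("sensitivity", "specificity", "accuracy", "precision"):
        vals = [getattr(m, name) for m in metrics]
        vals = [v for v in vals if v is not None]
        if not vals:
            out[name] = None
            continue
        arr = np.asarray(vals)
        out[name] = {
            "median": float(np.median(arr)),
            "q1": float(np.percentile(arr, 25)),
            "q3": float(np.percentile(arr, 75)),
            "n": int(arr.size),
        }
    return out
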