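"""Threshold customization from supervised laboratory gait trials.

Features of the pitch angular-velocity pattern (midswing amplitudes,
same-side and inter-side peak intervals, signal maximum) are extracted per
individual and per side from straight-walking lab trials, then turned into
detection thresholds either at the group level ("pop": group extremes, as
inclusive as possible) or at the individual level ("indiv": per-side
extremes, with the amplitude threshold renormalized to the out-of-lab
signal's 95th percentile).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .detector import ThresholdSet
from .errors import TuningError
from .io_preprocess import PitchSignal

__all__ = [
    "LabGaitFeatures",
    "PopulationFeatures",
    "extract_lab_features",
    "pop_thresholds",
    "indiv_thresholds",
    "features_to_frame",
    "features_from_frame",
]

#: Peak prominence used in lab trials, as a fraction of the trial's P95.
DEFAULT_PROMINENCE_FRACTION = 0.2

#: Percentile of the out-of-lab signal used to renormalize the indiv Th1.
OUT_LAB_PERCENTILE = 95.0


@dataclass
class LabGaitFeatures:
    """Per-subject, per-side signal features pooled across lab trials."""

    subject_id: str
    side: str
    ms_amplitudes: list = field(default_factory=list)
    same_side_intervals: list = field(default_factory=list)
    inter_side_intervals: list = field(default_factory=list)
    signal_max: float = 0.0

    def validate(self) -> None:
        if not (self.ms_amplitudes and self.same_side_intervals
                and self.inter_side_intervals):
            raise TuningError(
                f"subject {self.subject_id} side {self.side}: empty feature lists"
            )
        if min(self.same_side_intervals) <= 0 or min(self.inter_side_intervals) <= 0:
            raise TuningError(
                f"subject {self.subject_id} side {self.side}: non-positive intervals"
            )
        if min(self.ms_amplitudes) > self.signal_max:
            raise TuningError(
                f"subject {self.subject_id} side {self.side}: amplitude above signal max"
            )


@dataclass
class PopulationFeatures:
    """Lab features of all members of a group (e.g. CP or TD)."""

    group_id: str
    members: list  # of LabGaitFeatures

    def __post_init__(self) -> None:
        if not self.members:
            raise TuningError(f"group {self.group_id} has no members")


def _positive_p95(x: np.ndarray) -> float:
    pos = x[x > 0]
    if pos.size == 0:
        return 0.0
    return float(np.percentile(pos, OUT_LAB_PERCENTILE))


def _trial_peaks(sig: PitchSignal, prominence: float | None) -> tuple[np.ndarray, np.ndarray]:
    """Positive peak times and amplitudes of one lab trial."""
    x = sig.values
    if prominence is None:
        p95 = _positive_p95(x)
        if p95 <= 0:
            return np.array([]), np.array([])
        prominence = DEFAULT_PROMINENCE_FRACTION * p95
    peaks, _ = sps.find_peaks(x, prominence=prominence, height=0.0)
    return peaks / sig.sampling_rate, x[peaks]


def extract_lab_features(
    trials: list,
    subject_id: str,
    peak_prominence: float | None = None,
) -> dict:
    """Extract per-side :class:`LabGaitFeatures` from lab trial pairs.

    Parameters
    ----------
    trials
        List of ``(left, right)`` :class:`PitchSignal` pairs, one per
        straight-walking trial (slow, spontaneous and fast speeds pooled).
    subject_id
        Identifier stored in the features.
    peak_prominence
        Fixed prominence in deg/s; when ``None`` each trial uses 20% of its
        own positive-part P95. No amplitude threshold is applied: lab trials
        are supervised, so every prominent positive peak is a midswing.

    Returns
    -------
    dict
        ``{"left": LabGaitFeatures, "right": LabGaitFeatures}``.

    Raises
    ------
    TuningError
        If no peaks are found on some side in any trial.
    """
    if not trials:
        raise TuningError(f"subject {subject_id}: no lab trials provided")

    feats = {
        side: LabGaitFeatures(subject_id=subject_id, side=side)
        for side in ("left", "right")
    }
    for left, right in trials:
        per_side = {}
        for sig in (left, right):
            times, amps = _trial_peaks(sig, peak_prominence)
            per_side[sig.side] = (times, amps)
            f = feats[sig.side]
            f.ms_amplitudes.extend(amps.tolist())
            f.same_side_intervals.extend(np.diff(times).tolist())
            f.signal_max = max(f.signal_max, float(np.max(sig.values, initial=0.0)))

        # inter-side intervals: gaps between adjacent opposite-side peaks
        lt, rt = per_side["left"][0], per_side["right"][0]
        tagged = sorted(
            [(t, "left") for t in lt] + [(t, "right") for t in rt]
        )
        gaps = [
            b[0] - a[0]
            for a, b in zip(tagged, tagged[1:])
            if a[1] != b[1]
        ]
        for side in ("left", "right"):
            feats[side].inter_side_intervals.extend(gaps)

    for f in feats.values():
        if not f.ms_amplitudes:
            raise TuningError(
                f"subject {subject_id} side {f.side}: no midswing peaks found"
            )
        f.validate()
    return feats


def pop_thresholds(group: PopulationFeatures) -> ThresholdSet:
    """Group-extreme thresholds: as inclusive as any member's own extremes.

    th1 = group minimum of per-member minimal MS amplitude (both sides);
    th2 = group minimum of minimal same-side interval; th3 = group maximum
    of maximal same-side interval; th4 = group maximum of maximal
    inter-side interval.
    """
    th1 = min(min(m.ms_amplitudes) for m in group.members)
    th2 = min(min(m.same_side_intervals) for m in group.members)
    th3 = max(max(m.same_side_intervals) for m in group.members)
    th4 = max(max(m.inter_side_intervals) for m in group.members)
    return ThresholdSet(
        th1_left=th1,
        th1_right=th1,
        th2=th2,
        th3=th3,
        th4=th4,
        mode="pop",
        metadata={"group_id": group.group_id, "n_members": len(group.members)},
    )


def indiv_thresholds(
    features_left: LabGaitFeatures,
    features_right: LabGaitFeatures,
    out_lab_signal_left: PitchSignal,
    out_lab_signal_right: PitchSignal,
) -> ThresholdSet:
    """Per-individual, per-side thresholds with amplitude renormalization.

    Per side ``s``: ``th1_s = (min lab MS amplitude_s / lab signal max_s)
    x P95(positive out-of-lab signal_s)``. Temporal thresholds are the
    per-side lab extremes; the shared fields store the permissive envelope
    (smaller th2, larger th3) while per-side values are kept in metadata and
    applied during detection. th4 pools both sides' inter-side maxima.

    Raises
    ------
    TuningError
        If an out-of-lab signal has a non-positive P95 (degenerate).
    """
    features_left.validate()
    features_right.validate()

    th1 = {}
    for feats, sig in (
        (features_left, out_lab_signal_left),
        (features_right, out_lab_signal_right),
    ):
        p95 = _positive_p95(sig.values)
        if p95 <= 0:
            raise TuningError(
                f"degenerate out-of-lab signal on side {feats.side} (P95 <= 0)"
            )
        th1[feats.side] = min(feats.ms_amplitudes) / feats.signal_max * p95

    th2_l = min(features_left.same_side_intervals)
    th2_r = min(features_right.same_side_intervals)
    th3_l = max(features_left.same_side_intervals)
    th3_r = max(features_right.same_side_intervals)
    th4 = max(
        max(features_left.inter_side_intervals),
        max(features_right.inter_side_intervals),
    )
    return ThresholdSet(
        th1_left=th1["left"],
        th1_right=th1["right"],
        th2=min(th2_l, th2_r),
        th3=max(th3_l, th3_r),
        th4=th4,
        mode="indiv",
        metadata={
            "subject_id": features_left.subject_id,
            "th2_left": th2_l,
            "th2_right": th2_r,
            "th3_left": th3_l,
            "th3_right": th3_r,
        },
    )


def features_to_frame(members: list) -> pd.DataFrame:
    """Per-member feature extremes as a table (one row per subject/side)."""
    rows = []
    for f in members:
        rows.append(
            {
                "subject_id": f.subject_id,
                "side": f.side,
                "min_ms_amplitude": min(f.ms_amplitudes),
                "min_same_side_interval": min(f.same_side_intervals),
                "max_same_side_interval": max(f.same_side_intervals),
                "max_inter_side_interval": max(f.inter_side_intervals),
                "signal_max": f.signal_max,
            }
        )
    return pd.DataFrame(rows)


def features_from_frame(df: pd.DataFrame) -> list:
    """Rebuild (extremes-only) features from a table written by
    :func:`features_to_frame`; sufficient for :func:`pop_thresholds`."""
    members = []
    for _, row in df.iterrows():
        members.append(
            LabGaitFeatures(
                subject_id=str(row["subject_id"]),
                side=str(row["side"]),
                ms_amplitudes=[float(row["min_ms_amplitude"])],
                same_side_intervals=[
                    float(row["min_same_side_interval"]),
                    float(row["max_same_side_interval"]),
                ],
                inter_side_intervals=[float(row["max_inter_side_interval"])],
                signal_max=float(row["signal_max"]),
            )
        )
    return members
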