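"""Walking-bout detection from midswing peaks of the shank pitch angular velocity.

Candidate midswing (MS) peaks above an amplitude threshold are detected per
side, deduplicated within a refractory window, merged into a single stream
and grouped into walking bouts by strict left/right alternation, a maximal
same-side gap and an (adaptive) maximal inter-side gap. Thresholds are
injectable, so the same machinery runs in fixed-threshold ("init"),
group-tuned ("pop") and individually tuned ("indiv") modes.

Default thresholds of the fixed-threshold detector:

* ``th1`` = 50 deg/s  - minimal MS peak amplitude
* ``th2`` = 0.5 s     - minimal time between same-side MS (dedup window)
* ``th3`` = 1.5 s     - maximal time between same-side MS before the bout ends
* ``th4`` = 3.5 s     - maximal inter-side MS gap for the first step pair;
  afterwards ``1.5 s + mean step interval so far`` (adaptive)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from .errors import DataError, ParameterError
from .io_preprocess import PitchSignal

__all__ = [
    "ThresholdSet",
    "MidswingEvent",
    "WalkingBout",
    "TH4_ADAPTIVE_BASE",
    "find_midswing_candidates",
    "deduplicate_within_th2",
    "adaptive_th4",
    "segment_bouts",
    "detect",
    "filter_min_steps",
    "validate_bout",
    "bouts_to_frame",
]

#: Additive constant of the adaptive inter-side gap limit (seconds).
TH4_ADAPTIVE_BASE = 1.5

#: Minimum step count for a bout to enter the walking-speed stage.
SPEED_STAGE_MIN_STEPS = 4


@dataclass(frozen=True)
class MidswingEvent:
    """A side-tagged midswing peak: time (s), amplitude (deg/s), side."""

    time: float
    amplitude: float
    side: str


@dataclass
class ThresholdSet:
    """The four detection thresholds, with per-side MS amplitude limits.

    ``metadata`` may carry per-side refinements used by individually tuned
    detection: ``th2_left``/``th2_right`` (dedup windows) and
    ``th3_left``/``th3_right`` (same-side gap limits). When absent, the
    shared ``th2``/``th3`` apply to both sides.
    """

    th1_left: float = 50.0
    th1_right: float = 50.0
    th2: float = 0.5
    th3: float = 1.5
    th4: float = 3.5
    mode: str = "init"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("th1_left", "th1_right", "th2", "th3", "th4"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not self.th2 < self.th3:
            raise ParameterError("th2 must be smaller than th3")

    @classmethod
    def init_defaults(cls) -> "ThresholdSet":
        """The original fixed-threshold configuration (50, 0.5, 1.5, 3.5)."""
        return cls()

    def th1(self, side: str) -> float:
        return self.th1_left if side == "left" else self.th1_right

    def th2_for(self, side: str) -> float:
        return float(self.metadata.get(f"th2_{side}", self.th2))

    def th3_for(self, side: str) -> float:
        return float(self.metadata.get(f"th3_{side}", self.th3))

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "th1_left": float(self.th1_left),
            "th1_right": float(self.th1_right),
            "th2": float(self.th2),
            "th3": float(self.th3),
            "th4": float(self.th4),
            "metadata": {k: float(v) if isinstance(v, (int, float, np.floating)) else v
                         for k, v in self.metadata.items()},
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ThresholdSet":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            th1_left=d["th1_left"],
            th1_right=d["th1_right"],
            th2=d["th2"],
            th3=d["th3"],
            th4=d["th4"],
            mode=d.get("mode", "init"),
            metadata=d.get("metadata", {}) or {},
        )


@dataclass
class WalkingBout:
    """A maximal run of alternating left/right midswing events.

    ``start``/``end`` pad the first/last peak by half the adjacent step
    interval, since midswing occurs mid-swing and walking physically extends
    beyond the first and last peak.
    """

    events: list[MidswingEvent]
    start: float
    end: float

    @property
    def n_steps(self) -> int:
        return len(self.events)

    @property
    def n_cycles(self) -> int:
        n_left = sum(1 for e in self.events if e.side == "left")
        return min(n_left, len(self.events) - n_left)

    @property
    def first_side(self) -> str:
        return self.events[0].side


def find_midswing_candidates(signal: PitchSignal, th1: float) -> list[MidswingEvent]:
    """All local maxima of ``signal`` with amplitude strictly above ``th1``.

    Event times are placed at the sample of the maximum. Running on an
    unfiltered signal raises a warning (drift can bias amplitudes) but is
    not an error.
    """
    if not signal.filtered:
        warnings.warn("find_midswing_candidates called on an unfiltered signal",
                      stacklevel=2)
    peaks, _ = sps.find_peaks(signal.values)
    keep = peaks[signal.values[peaks] > th1]
    fs = signal.sampling_rate
    return [
        MidswingEvent(time=i / fs, amplitude=float(signal.values[i]), side=signal.side)
        for i in keep
    ]


def deduplicate_within_th2(
    events: Sequence[MidswingEvent], th2: float
) -> list[MidswingEvent]:
    """Collapse clusters of same-side peaks closer than ``th2`` seconds.

    Events are chained into clusters wherever consecutive gaps are < ``th2``;
    within each cluster only the maximum-amplitude event survives (ties keep
    the earlier event). Surviving events are therefore never closer than
    ``th2``.
    """
    if not events:
        return []
    times = np.array([e.time for e in events])
    if np.any(np.diff(times) < 0):
        raise DataError("events must be time-sorted")

    out: list[MidswingEvent] = []
    cluster = [events[0]]
    for prev, ev in zip(events, events[1:]):
        if ev.time - prev.time < th2:
            cluster.append(ev)
        else:
            out.append(max(cluster, key=lambda e: (e.amplitude, -e.time)))
            cluster = [ev]
    out.append(max(cluster, key=lambda e: (e.amplitude, -e.time)))
    return out


def adaptive_th4(
    step_intervals_so_far: Iterable[float],
    th4_initial: float = 3.5,
    base: float = TH4_ADAPTIVE_BASE,
) -> float:
    """Inter-side gap limit given the step intervals already in the bout.

    With no history (the first step pair) the fixed ``th4_initial`` applies;
    afterwards the limit is ``base + mean(step_intervals_so_far)``.
    """
    intervals = np.asarray(list(step_intervals_so_far), dtype=float)
    if intervals.size == 0:
        return th4_initial
    if np.any(intervals < 0):
        raise DataError("step intervals must be non-negative")
    return base + float(intervals.mean())


def _close_run(run: list[MidswingEvent], bouts: list[WalkingBout]) -> None:
    if len(run) < 2:
        return
    times = [e.time for e in run]
    gaps = np.diff(times)
    start = times[0] - gaps[0] / 2.0
    end = times[-1] + gaps[-1] / 2.0
    bouts.append(WalkingBout(events=list(run), start=float(start), end=float(end)))


def segment_bouts(
    ms_left: Sequence[MidswingEvent],
    ms_right: Sequence[MidswingEvent],
    thresholds: ThresholdSet,
) -> list[WalkingBout]:
    """Group deduplicated left/right midswing streams into walking bouts.

    Both streams are merged into one time-ordered stream (stable: at equal
    times left precedes right). A candidate bout grows while each appended
    event (a) alternates side with its predecessor, (b) keeps the gap to the
    previous same-side event <= th3 (per-side th3 when configured) and
    (c) keeps the gap to the previous event <= the adaptive th4. A violation
    closes the bout at the earlier event; the violating event seeds a new
    candidate. Runs of fewer than 2 events are discarded.
    """
    merged = sorted(list(ms_left) + list(ms_right), key=lambda e: e.time)

    bouts: list[WalkingBout] = []
    run: list[MidswingEvent] = []
    for ev in merged:
        if not run:
            run = [ev]
            continue
        ok = ev.side != run[-1].side
        if ok and len(run) >= 2:
            # with alternation the previous same-side event sits 2 back
            ok = (ev.time - run[-2].time) <= thresholds.th3_for(ev.side)
        if ok:
            gap = ev.time - run[-1].time
            if len(run) == 1:
                limit = thresholds.th4
            else:
                limit = adaptive_th4(
                    np.diff([e.time for e in run]), th4_initial=thresholds.th4
                )
            ok = gap <= limit
        if ok:
            run.append(ev)
        else:
            _close_run(run, bouts)
            run = [ev]
    _close_run(run, bouts)
    return bouts


def detect(
    signal_left: PitchSignal,
    signal_right: PitchSignal,
    thresholds: ThresholdSet,
) -> list[WalkingBout]:
    """Full per-side pipeline: candidates -> dedup -> bout segmentation."""
    if signal_left.sampling_rate != signal_right.sampling_rate:
        raise DataError("left and right signals must share a sampling rate")
    per_side = {}
    for sig in (signal_left, signal_right):
        cands = find_midswing_candidates(sig, thresholds.th1(sig.side))
        per_side[sig.side] = deduplicate_within_th2(
            cands, thresholds.th2_for(sig.side)
        )
    return segment_bouts(per_side["left"], per_side["right"], thresholds)


def filter_min_steps(
    bouts: Sequence[WalkingBout], min_steps: int = SPEED_STAGE_MIN_STEPS
) -> list[WalkingBout]:
    """Keep bouts with at least ``min_steps`` events (speed-stage filter)."""
    return [b for b in bouts if b.n_steps >= min_steps]


def validate_bout(bout: WalkingBout, thresholds: ThresholdSet) -> None:
    """Assert the structural invariants of a walking bout; raises AssertionError."""
    times = np.array([e.time for e in bout.events])
    sides = [e.side for e in bout.events]
    assert len(bout.events) >= 2
    assert np.all(np.diff(times) >= 0)
    for a, b in zip(sides, sides[1:]):
        assert a != b, "sides must strictly alternate"
    for ev in bout.events:
        assert ev.amplitude > thresholds.th1(ev.side)
    for i in range(2, len(times)):
        gap = times[i] - times[i - 2]
        side = sides[i]
        assert thresholds.th2_for(side) <= gap <= thresholds.th3_for(side) + 1e-12
    for i in range(1, len(times)):
        limit = (
            thresholds.th4
            if i == 1
            else adaptive_th4(np.diff(times[:i]), th4_initial=thresholds.th4)
        )
        assert times[i] - times[i - 1] <= limit + 1e-12
    assert bout.start <= times[0] and bout.end >= times[-1]


def bouts_to_frame(bouts: Sequence[WalkingBout]) -> pd.DataFrame:
    """Tabular bout summary (one row per bout) for CSV export."""
    rows = [
        {
            "bout_id": i,
            "start_s": b.start,
            "end_s": b.end,
            "n_steps": b.n_steps,
            "n_cycles": b.n_cycles,
            "first_side": b.first_side,
        }
        for i, b in enumerate(bouts)
    ]
    return pd.DataFrame(
        rows, columns=["bout_id", "start_s", "end_s", "n_steps", "n_cycles", "first_side"]
    )
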