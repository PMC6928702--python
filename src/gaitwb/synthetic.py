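"""Synthetic gait and activity-protocol generator with full ground truth.

Emits labeled shank pitch angular-velocity signals whose only claim to
realism is the feature set the detector relies on: positive Gaussian-shaped
midswing peaks with negative stance lobes, alternating between sides with
half a step period of offset, with configurable cadence, amplitude,
variability and asymmetry, plus white noise and linear drift. Confounding
periodic non-gait activities (swinging, running, stairs, sitting) can be
interleaved to reproduce the false-positive mechanisms the customized
thresholds are meant to suppress.

All randomness flows from one explicitly passed seeded generator; identical
seeds give bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import json

import numpy as np
import yaml

from .detector import MidswingEvent, WalkingBout
from .errors import ConfigError, ParameterError
from .evaluation import ActivityLabel
from .io_preprocess import PitchSignal, RawRecording

__all__ = [
    "WalkParams",
    "SubjectParams",
    "Segment",
    "GaitScenario",
    "GroundTruth",
    "simulate_walk_segment",
    "simulate_confounder",
    "simulate_protocol",
    "simulate_lab_trials",
    "default_scenario",
    "example_subject",
    "example_group_subjects",
    "ordering_scenario",
]

GAIT_ACTIVITIES = ("walk", "walk_other")
CONFOUNDER_ACTIVITIES = ("swing", "run", "sit", "stairs", "lie", "stand")

_ACTIVITY_CATEGORY = {
    "walk": "straight_walking",
    "walk_other": "other_walking",
    "swing": "non_walking",
    "run": "non_walking",
    "sit": "non_walking",
    "stairs": "non_walking",
    "lie": "non_walking",
    "stand": "non_walking",
}


@dataclass
class WalkParams:
    """Parameters of one walking segment.

    ``cadence`` is in steps/min (one side fires every ``2 * 60/cadence`` s).
    ``amp`` is the mean midswing peak amplitude of the left side in deg/s;
    the right side is scaled by ``asymmetry``. ``ms_width`` is the Gaussian
    sigma of the peak in seconds (default 0.1 x step period).
    """

    cadence: float = 110.0
    amp: float = 300.0
    amp_cv: float = 0.05
    step_time_cv: float = 0.03
    asymmetry: float = 1.0
    speed: float = 1.2
    speed_cv: float = 0.05
    ms_width: float | None = None
    stance_depth: float = 0.4

    @property
    def step_period(self) -> float:
        return 60.0 / self.cadence


@dataclass
class SubjectParams:
    """A simulated individual: base gait parameters plus the scaling used
    for the three lab speeds (slow / spontaneous / fast)."""

    subject_id: str = "sim"
    amp: float = 320.0
    asymmetry: float = 1.0
    cadence: float = 112.0
    amp_cv: float = 0.04
    step_time_cv: float = 0.03
    speed: float = 1.2
    speed_cv: float = 0.05
    amp_scale: dict = field(
        default_factory=lambda: {"slow": 0.8, "spontaneous": 1.0, "fast": 1.15}
    )
    cadence_scale: dict = field(
        default_factory=lambda: {"slow": 0.88, "spontaneous": 1.0, "fast": 1.12}
    )
    lab_noise_sd: float = 1.0

    def walk_params(self, speed_label: str = "spontaneous") -> WalkParams:
        return WalkParams(
            cadence=self.cadence * self.cadence_scale[speed_label],
            amp=self.amp * self.amp_scale[speed_label],
            amp_cv=self.amp_cv,
            step_time_cv=self.step_time_cv,
            asymmetry=self.asymmetry,
            speed=self.speed,
            speed_cv=self.speed_cv,
        )


@dataclass
class Segment:
    activity: str
    duration: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.activity not in _ACTIVITY_CATEGORY:
            raise ConfigError(f"unknown activity {self.activity!r}")
        if self.duration <= 0:
            raise ConfigError("segment durations must be positive")


@dataclass
class GaitScenario:
    """A protocol: ordered activity segments plus global signal settings."""

    segments: list
    sampling_rate: float = 100.0
    noise_sd: float = 5.0
    drift_rate: float = 0.0  # deg/s per minute
    seed: int = 0
    subject: dict = field(default_factory=dict)  # optional, for lab trials
    lab_trials_per_speed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "GaitScenario":
        try:
            segments = [
                Segment(
                    activity=s["activity"],
                    duration=float(s["duration"]),
                    params=dict(s.get("params", {}) or {}),
                )
                for s in d["segments"]
            ]
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"bad scenario description: {exc}") from exc
        return cls(
            segments=segments,
            sampling_rate=float(d.get("sampling_rate", 100.0)),
            noise_sd=float(d.get("noise_sd", 5.0)),
            drift_rate=float(d.get("drift_rate", 0.0)),
            seed=int(d.get("seed", 0)),
            subject=dict(d.get("subject", {}) or {}),
            lab_trials_per_speed=int(d.get("lab_trials_per_speed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "GaitScenario":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError("scenario YAML must contain a mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return {
            "segments": [
                {"activity": s.activity, "duration": s.duration, "params": s.params}
                for s in self.segments
            ],
            "sampling_rate": self.sampling_rate,
            "noise_sd": self.noise_sd,
            "drift_rate": self.drift_rate,
            "seed": self.seed,
            "subject": self.subject,
            "lab_trials_per_speed": self.lab_trials_per_speed,
        }


@dataclass
class GroundTruth:
    """Everything the evaluator and tests need: labels, true midswing
    events per side, true bouts, and per-bout cycle times/speeds."""

    labels: list  # of ActivityLabel
    true_ms: dict  # {"left": [MidswingEvent], "right": [MidswingEvent]}
    true_bouts: list  # of WalkingBout
    cycle_times: list  # per bout: list of times (s)
    cycle_speeds: list  # per bout: list of speeds (m/s)

    @property
    def all_cycle_times(self) -> list:
        return [t for bout in self.cycle_times for t in bout]

    @property
    def all_cycle_speeds(self) -> list:
        return [v for bout in self.cycle_speeds for v in bout]

    def to_json(self, path) -> None:
        d = {
            "labels": [
                {"start": lab.start, "end": lab.end, "category": lab.category}
                for lab in self.labels
            ],
            "true_ms": {
                side: [asdict(e) for e in evs] for side, evs in self.true_ms.items()
            },
            "true_bouts": [
                {
                    "start": b.start,
                    "end": b.end,
                    "events": [asdict(e) for e in b.events],
                }
                for b in self.true_bouts
            ],
            "cycle_times": self.cycle_times,
            "cycle_speeds": self.cycle_speeds,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            labels=[ActivityLabel(**lab) for lab in d["labels"]],
            true_ms={
                side: [MidswingEvent(**e) for e in evs]
                for side, evs in d["true_ms"].items()
            },
            true_bouts=[
                WalkingBout(
                    events=[MidswingEvent(**e) for e in b["events"]],
                    start=b["start"],
                    end=b["end"],
                )
                for b in d["true_bouts"]
            ],
            cycle_times=d["cycle_times"],
            cycle_speeds=d["cycle_speeds"],
        )


# ---------------------------------------------------------------------------
# waveform primitives


def _add_gaussians(out: np.ndarray, fs: float, centers, amps, sigma: float) -> None:
    """Add Gaussian bumps in place, evaluated only on a +-6 sigma window."""
    n = out.size
    half = int(np.ceil(6 * sigma * fs))
    for tc, a in zip(centers, amps):
        ic = int(round(tc * fs))
        i0, i1 = max(0, ic - half), min(n, ic + half + 1)
        if i0 >= i1:
            continue
        t = np.arange(i0, i1) / fs
        out[i0:i1] += a * np.exp(-0.5 * ((t - tc) / sigma) ** 2)


def _true_events(
    clean: np.ndarray, fs: float, centers, side: str
) -> list[MidswingEvent]:
    """Snap nominal peak centers to the clean signal's local maxima."""
    events = []
    n = clean.size
    for tc in centers:
        ic = int(round(tc * fs))
        i0, i1 = max(0, ic - 3), min(n, ic + 4)
        if i0 >= i1:
            continue
        idx = i0 + int(np.argmax(clean[i0:i1]))
        events.append(
            MidswingEvent(time=idx / fs, amplitude=float(clean[idx]), side=side)
        )
    return events


@dataclass
class WalkSegmentResult:
    left: np.ndarray
    right: np.ndarray
    events: dict  # {"left": [...], "right": [...]}, times relative to segment
    cycle_times: list
    cycle_speeds: list


def simulate_walk_segment(
    params: WalkParams,
    duration: float,
    fs: float,
    rng: np.random.Generator,
) -> WalkSegmentResult:
    """One straight-walking segment: clean per-side signals plus truth.

    Per side, Gaussian midswing peaks fire every ``2 x step period``,
    left/right offset by one step period, with per-step amplitude and
    timing jitter and a broad negative stance lobe between same-side peaks.
    True midswing events are recorded at the clean-signal peak samples; one
    (time, speed) pair is emitted per left cycle.
    """
    t_step = params.step_period
    t_cycle = 2.0 * t_step
    width = params.ms_width if params.ms_width is not None else 0.1 * t_step
    if t_step < 2.0 * width:
        raise ParameterError(
            f"step period {t_step:.3f} s shorter than 2 peak widths ({2 * width:.3f} s)"
        )

    n = int(round(duration * fs))
    margin = 0.4 * t_cycle
    sides = {"left": 0.3 * t_cycle, "right": 0.3 * t_cycle + t_step}
    signals, events = {}, {}
    for side, t0 in sides.items():
        nominal = np.arange(t0, duration - margin, t_cycle)
        jitter = np.clip(
            rng.normal(0.0, params.step_time_cv * t_step, nominal.size),
            -0.25 * t_step,
            0.25 * t_step,
        )
        centers = nominal + jitter
        amp_mean = params.amp * (params.asymmetry if side == "right" else 1.0)
        amps = np.clip(
            rng.normal(amp_mean, params.amp_cv * amp_mean, centers.size),
            0.5 * amp_mean,
            1.5 * amp_mean,
        )
        clean = np.zeros(n)
        _add_gaussians(clean, fs, centers, amps, width)
        # stance lobes between consecutive same-side peaks
        if centers.size >= 2:
            mids = (centers[:-1] + centers[1:]) / 2.0
            lobe_amp = -params.stance_depth * (amps[:-1] + amps[1:]) / 2.0
            # narrow enough that the lobe tails leave peak amplitudes
            # within 1% of the configured value
            lobe_sigma = 0.15 * t_cycle
            _add_gaussians(clean, fs, mids, lobe_amp, lobe_sigma)
        signals[side] = clean
        events[side] = _true_events(clean, fs, centers, side)

    n_cycles = len(events["left"])
    speeds = np.clip(
        rng.normal(params.speed, params.speed_cv * params.speed, n_cycles),
        0.1,
        None,
    )
    cycle_times = [e.time for e in events["left"]]
    return WalkSegmentResult(
        left=signals["left"],
        right=signals["right"],
        events=events,
        cycle_times=cycle_times,
        cycle_speeds=speeds.tolist(),
    )


_CONFOUNDER_DEFAULTS = {
    "sit": {"noise_sd": 3.0},
    "lie": {"noise_sd": 1.0},
    "stand": {"noise_sd": 3.0},
    "swing": {
        "period": 2.5,  # same-side period (s)
        "amplitude": 150.0,
        "offset": None,  # right delay; defaults to period / 2
        "amp_cv": 0.03,
        "time_cv": 0.005,
        "width": None,  # sigma; defaults to 0.1 x period
    },
    "run": {"step_period": 0.3, "amplitude": 450.0, "amp_cv": 0.05, "time_cv": 0.02},
    "stairs": {"cadence": 70.0, "amplitude": 130.0, "amp_cv": 0.05, "time_cv": 0.03},
}


def simulate_confounder(
    activity: str,
    duration: float,
    fs: float,
    rng: np.random.Generator,
    params: dict | None = None,
) -> tuple[np.ndarray, np.ndarray, str]:
    """Non-gait segment signals for both sides, plus the label category.

    ``swing``: bilateral high-amplitude periodic peaks with a long same-side
    period; ``run``: fast, high-amplitude alternation; ``stairs``: gait-like
    but slow alternation; ``sit``/``lie``/``stand``: low-amplitude noise.
    All are labeled ``non_walking``.
    """
    if activity not in _CONFOUNDER_DEFAULTS:
        raise ConfigError(f"unknown confounder activity {activity!r}")
    p = dict(_CONFOUNDER_DEFAULTS[activity])
    if params:
        p.update(params)

    n = int(round(duration * fs))

    if activity in ("sit", "lie", "stand"):
        left = rng.normal(0.0, p["noise_sd"], n)
        right = rng.normal(0.0, p["noise_sd"], n)
        return left, right, "non_walking"

    if activity == "swing":
        period = float(p["period"])
        offset = p["offset"] if p["offset"] is not None else period / 2.0
        width = p["width"] if p["width"] is not None else 0.1 * period
        left_c = np.arange(0.5 * period, duration - 0.5 * period, period)
        left_c = left_c + np.clip(
            rng.normal(0, p["time_cv"] * period, left_c.size),
            -0.2 * period,
            0.2 * period,
        )
        right_c = left_c + offset
        right_c = right_c[right_c < duration - 3 * width]
        out = {}
        for side, centers in (("left", left_c), ("right", right_c)):
            amps = np.clip(
                rng.normal(p["amplitude"], p["amp_cv"] * p["amplitude"], centers.size),
                0.7 * p["amplitude"],
                1.3 * p["amplitude"],
            )
            sig = np.zeros(n)
            _add_gaussians(sig, fs, centers, amps, width)
            out[side] = sig
        return out["left"], out["right"], "non_walking"

    if activity == "run":
        step = float(p["step_period"])
        width = 0.1 * step
        cycle = 2 * step
        sides_sig = []
        for k, t0 in enumerate((0.5 * step, 1.5 * step)):
            centers = np.arange(t0, duration - 2 * width, cycle)
            centers = centers + rng.normal(0, p["time_cv"] * step, centers.size)
            amps = rng.normal(p["amplitude"], p["amp_cv"] * p["amplitude"], centers.size)
            sig = np.zeros(n)
            _add_gaussians(sig, fs, centers, amps, width)
            sides_sig.append(sig)
        return sides_sig[0], sides_sig[1], "non_walking"

    # stairs: reuse the gait generator at low cadence / amplitude
    walk = simulate_walk_segment(
        WalkParams(
            cadence=float(p["cadence"]),
            amp=float(p["amplitude"]),
            amp_cv=float(p["amp_cv"]),
            step_time_cv=float(p["time_cv"]),
        ),
        duration,
        fs,
        rng,
    )
    return walk.left, walk.right, "non_walking"


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _walk_params_from(params: dict) -> WalkParams:
    allowed = set(WalkParams.__dataclass_fields__)
    bad = set(params) - allowed
    if bad:
        raise ConfigError(f"unknown walk parameters: {sorted(bad)}")
    return WalkParams(**params)


def simulate_protocol(
    scenario: GaitScenario,
) -> tuple[RawRecording, RawRecording, GroundTruth]:
    """Concatenate a scenario's segments into a pair of raw recordings.

    The first segment must be ``lie`` (it anchors the start alignment, with
    a static ~1 g acceleration norm). Tri-axial gyro channels are built by
    embedding the pitch signal through a seeded random rotation, so the PCA
    alignment stage is genuinely exercised. Labels partition the full
    duration; ground truth carries true midswing events, true bouts and
    per-bout cycle speeds.
    """
    if not scenario.segments:
        raise ConfigError("scenario has no segments")
    if scenario.segments[0].activity != "lie":
        raise ConfigError("the first scenario segment must be 'lie'")

    rng = np.random.default_rng(scenario.seed)
    fs = scenario.sampling_rate

    pitch = {"left": [], "right": []}
    labels: list[ActivityLabel] = []
    true_ms = {"left": [], "right": []}
    true_bouts: list[WalkingBout] = []
    cycle_times: list[list] = []
    cycle_speeds: list[list] = []
    accel_chunks = []
    offset = 0.0

    for seg in scenario.segments:
        n_seg = int(round(seg.duration * fs))
        seg_dur = n_seg / fs
        if seg.activity in GAIT_ACTIVITIES:
            walk = simulate_walk_segment(
                _walk_params_from(seg.params), seg_dur, fs, rng
            )
            pitch["left"].append(walk.left)
            pitch["right"].append(walk.right)
            shifted = {
                side: [
                    MidswingEvent(time=e.time + offset, amplitude=e.amplitude, side=side)
                    for e in evs
                ]
                for side, evs in walk.events.items()
            }
            for side in ("left", "right"):
                true_ms[side].extend(shifted[side])
            merged = sorted(
                shifted["left"] + shifted["right"], key=lambda e: e.time
            )
            if len(merged) >= 2:
                gaps = np.diff([e.time for e in merged])
                true_bouts.append(
                    WalkingBout(
                        events=merged,
                        start=merged[0].time - float(gaps[0]) / 2.0,
                        end=merged[-1].time + float(gaps[-1]) / 2.0,
                    )
                )
                cycle_times.append([t + offset for t in walk.cycle_times])
                cycle_speeds.append(list(walk.cycle_speeds))
        else:
            left, right, _ = simulate_confounder(
                seg.activity, seg_dur, fs, rng, seg.params
            )
            pitch["left"].append(left)
            pitch["right"].append(right)

        labels.append(
            ActivityLabel(
                start=offset,
                end=offset + seg_dur,
                category=_ACTIVITY_CATEGORY[seg.activity],
            )
        )

        if seg.activity == "lie":
            acc = np.tile([0.0, 0.0, 1.0], (n_seg, 1)) + rng.normal(
                0.0, 0.004, (n_seg, 3)
            )
        else:
            acc = np.tile([0.1, 0.15, 0.95], (n_seg, 1)) + rng.normal(
                0.0, 0.25, (n_seg, 3)
            )
        accel_chunks.append(acc)
        offset += seg_dur

    accel = np.vstack(accel_chunks)
    n_total = accel.shape[0]
    t = np.arange(n_total) / fs
    drift = scenario.drift_rate / 60.0 * t

    recordings = {}
    for side in ("left", "right"):
        x = np.concatenate(pitch[side]) + drift
        x = x + rng.normal(0.0, scenario.noise_sd, n_total)
        axes = np.column_stack(
            [
                rng.normal(0.0, 2.0, n_total),
                rng.normal(0.0, 2.0, n_total),
                x,
            ]
        )
        rot = _random_rotation(rng)
        recordings[side] = RawRecording(
            sensor_id=f"sim_{side}",
            side=side,
            sampling_rate=fs,
            gyro=axes @ rot.T,
            accel=accel,
            t0=0.0,
        )

    truth = GroundTruth(
        labels=labels,
        true_ms=true_ms,
        true_bouts=true_bouts,
        cycle_times=cycle_times,
        cycle_speeds=cycle_speeds,
    )
    return recordings["left"], recordings["right"], truth


@dataclass
class LabTruth:
    """Generator-side feature extremes for parameter-recovery tests."""

    min_amp: dict  # per side
    min_same_side_interval: dict
    max_same_side_interval: dict
    max_inter_side_interval: float
    signal_max: dict  # per side, of the emitted (noisy) signal


def simulate_lab_trials(
    subject: SubjectParams,
    n_trials_per_speed: int = 4,
    trial_duration: float = 8.0,
    fs: float = 100.0,
    seed: int | np.random.Generator = 0,
) -> tuple[list, LabTruth]:
    """Straight-walking lab trials at slow/spontaneous/fast speeds.

    Returns ``(trials, truth)`` where each trial is a ``(left, right)``
    pair of :class:`PitchSignal` and ``truth`` holds the pooled feature
    extremes computed from the generator's own events.
    """
    if n_trials_per_speed < 1:
        raise ParameterError("n_trials_per_speed must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    trials = []
    amps = {"left": [], "right": []}
    ss_int = {"left": [], "right": []}
    is_int = []
    sig_max = {"left": 0.0, "right": 0.0}

    for speed_label in ("slow", "spontaneous", "fast"):
        params = subject.walk_params(speed_label)
        for _ in range(n_trials_per_speed):
            walk = simulate_walk_segment(params, trial_duration, fs, rng)
            pair = []
            for side, clean in (("left", walk.left), ("right", walk.right)):
                noisy = clean + rng.normal(0.0, subject.lab_noise_sd, clean.size)
                pair.append(
                    PitchSignal(
                        side=side,
                        sampling_rate=fs,
                        values=noisy,
                        provenance="pca-aligned",
                        filtered=True,
                    )
                )
                evs = walk.events[side]
                amps[side].extend(e.amplitude for e in evs)
                times = [e.time for e in evs]
                ss_int[side].extend(np.diff(times).tolist())
                sig_max[side] = max(sig_max[side], float(noisy.max()))
            merged = sorted(
                walk.events["left"] + walk.events["right"], key=lambda e: e.time
            )
            is_int.extend(
                b.time - a.time
                for a, b in zip(merged, merged[1:])
                if a.side != b.side
            )
            trials.append(tuple(pair))

    truth = LabTruth(
        min_amp={s: min(v) for s, v in amps.items()},
        min_same_side_interval={s: min(v) for s, v in ss_int.items()},
        max_same_side_interval={s: max(v) for s, v in ss_int.items()},
        max_inter_side_interval=max(is_int),
        signal_max=sig_max,
    )
    return trials, truth


# ---------------------------------------------------------------------------
# presets


def default_scenario(seed: int = 0) -> GaitScenario:
    """A short mixed protocol exercising every pipeline stage."""
    return GaitScenario(
        segments=[
            Segment("lie", 5.0),
            Segment("walk", 40.0, {"cadence": 110.0, "amp": 300.0}),
            Segment("swing", 20.0, {"period": 1.2, "amplitude": 150.0, "offset": 0.6}),
            Segment("sit", 15.0),
            Segment("walk", 30.0, {"cadence": 110.0, "amp": 300.0}),
        ],
        noise_sd=4.0,
        drift_rate=1.0,
        seed=seed,
        subject={"subject_id": "sim", "amp": 300.0, "cadence": 110.0},
        lab_trials_per_speed=4,
    )


def example_subject() -> SubjectParams:
    """The reference simulated individual used in the method-ordering tests."""
    return SubjectParams(subject_id="S01", amp=320.0, cadence=112.0)


def example_group_subjects() -> list:
    """A heterogeneous group containing :func:`example_subject`.

    The weak-amplitude and slow members pull the group-extreme thresholds
    far from the reference subject's own envelope, which is what makes the
    group-tuned detector less specific than the individually tuned one.
    """
    return [
        example_subject(),
        SubjectParams(
            subject_id="S02",
            amp=160.0,
            cadence=100.0,
            amp_scale={"slow": 0.75, "spontaneous": 1.0, "fast": 1.1},
        ),
        SubjectParams(subject_id="S03", amp=250.0, cadence=85.0),
        SubjectParams(
            subject_id="S04",
            amp=280.0,
            cadence=120.0,
            cadence_scale={"slow": 0.9, "spontaneous": 1.0, "fast": 1.15},
        ),
    ]


def ordering_scenario(seed: int = 0) -> GaitScenario:
    """Out-of-lab protocol with two swing confounders chosen so that the
    fixed, group-tuned and individually tuned detectors are separated:

    * swing A (80 deg/s, 1.2 s period) passes only the fixed 50 deg/s
      amplitude threshold;
    * swing B (150 deg/s, 1.45 s period, 0.75 s inter-side offset) passes
      the fixed and group thresholds but stays below the individually
      renormalized amplitude threshold and outside the individual timing
      envelope.
    """
    subject = example_subject()
    walk = {
        "cadence": subject.cadence,
        "amp": subject.amp,
        "amp_cv": subject.amp_cv,
        "step_time_cv": subject.step_time_cv,
    }
    walk_other = dict(walk, cadence=105.0, amp=300.0)
    return GaitScenario(
        segments=[
            Segment("lie", 5.0),
            Segment("walk", 60.0, dict(walk)),
            Segment("swing", 25.0, {"period": 1.2, "amplitude": 80.0, "offset": 0.6}),
            Segment("walk_other", 30.0, walk_other),
            Segment(
                "swing", 25.0, {"period": 1.45, "amplitude": 150.0, "offset": 0.75}
            ),
            Segment("sit", 20.0),
            Segment("walk", 60.0, dict(walk)),
        ],
        noise_sd=4.0,
        drift_rate=1.0,
        seed=seed,
        subject={"subject_id": subject.subject_id},
    )
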