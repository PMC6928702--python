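import numpy as np
import pytest

from gaitwb.detector import (
    MidswingEvent,
    ThresholdSet,
    WalkingBout,
    adaptive_th4,
    bouts_to_frame,
    deduplicate_within_th2,
    detect,
    filter_min_steps,
    find_midswing_candidates,
    segment_bouts,
    validate_bout,
)
from gaitwb.errors import DataError, ParameterError
from gaitwb.io_preprocess import PitchSignal

# ---------------------------------------------------------------------------
# independent brute-force oracles


def dedup_oracle(events, th2):
    """Union-find over pairwise |dt| < th2; keep each component's argmax
    (ties: earlier event)."""
    n = len(events)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(events[j].time - events[i].time) < th2:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(events[i])
    survivors = [
        max(members, key=lambda e: (e.amplitude, -e.time))
        for members in comps.values()
    ]
    return sorted(survivors, key=lambda e: e.time)


def _window_valid(evs, th):
    """Check a contiguous run against all bout constraints from scratch."""
    times = [e.time for e in evs]
    for k in range(1, len(evs)):
        if evs[k].side == evs[k - 1].side:
            return False
        if k >= 2 and times[k] - times[k - 2] > th.th3_for(evs[k].side):
            return False
        if k == 1:
            limit = th.th4
        else:
            gaps = [times[i + 1] - times[i] for i in range(k - 1)]
            limit = 1.5 + sum(gaps) / len(gaps)
        if times[k] - times[k - 1] > limit:
            return False
    return True


def segment_oracle(ms_left, ms_right, th):
    """Greedy partition into longest valid contiguous windows, each validated
    from scratch (independent of the incremental scanner)."""
    merged = sorted(list(ms_left) + list(ms_right), key=lambda e: e.time)
    bouts = []
    i = 0
    while i < len(merged):
        j = i + 1
        while j < len(merged) and _window_valid(merged[i : j + 1], th):
            j += 1
        window = merged[i:j]
        if len(window) >= 2:
            times = [e.time for e in window]
            gaps = np.diff(times)
            bouts.append(
                (tuple(window), times[0] - gaps[0] / 2, times[-1] + gaps[-1] / 2)
            )
        i = j
    return bouts


def random_event_streams(rng, max_events=12, span=8.0):
    n = int(rng.integers(0, max_events + 1))
    times = np.sort(rng.uniform(0, span, n))
    sides = rng.choice(["left", "right"], n)
    evs = {"left": [], "right": []}
    for t, s in zip(times, sides):
        evs[s].append(MidswingEvent(float(t), float(rng.uniform(60, 300)), s))
    return evs["left"], evs["right"]


def random_thresholds(rng):
    th2 = float(rng.uniform(0.1, 0.6))
    th3 = float(rng.uniform(0.7, 2.0))
    th4 = float(rng.uniform(0.8, 3.5))
    meta = {}
    if rng.random() < 0.3:  # exercise per-side th3 path
        meta = {"th3_left": float(rng.uniform(0.7, 2.0)),
                "th3_right": float(rng.uniform(0.7, 2.0))}
    return ThresholdSet(50, 50, th2, th3, th4, metadata=meta)


# ---------------------------------------------------------------------------


class TestThresholdSet:
    def test_init_defaults(self):
        th = ThresholdSet.init_defaults()
        assert (th.th1_left, th.th1_right) == (50.0, 50.0)
        assert (th.th2, th.th3, th.th4) == (0.5, 1.5, 3.5)
        assert th.mode == "init"

    def test_pop_ordering_not_required(self):
        # the CP group extremes have th4 < th3; must be accepted
        th = ThresholdSet(109, 109, 0.64, 3.53, 1.88, mode="pop")
        assert th.th3 > th.th4

    def test_rejects_nonpositive(self):
        with pytest.raises(ParameterError):
            ThresholdSet(th1_left=0.0)

    def test_rejects_th2_not_below_th3(self):
        with pytest.raises(ParameterError):
            ThresholdSet(th2=1.5, th3=1.5)

    def test_yaml_roundtrip(self, tmp_path):
        th = ThresholdSet(120, 130, 0.8, 1.3, 0.7, mode="indiv",
                          metadata={"th2_left": 0.8, "th2_right": 0.9})
        path = tmp_path / "th.yaml"
        th.to_yaml(path)
        back = ThresholdSet.from_yaml(path)
        assert back.to_dict() == th.to_dict()


class TestFindCandidates:
    def test_all_below_threshold(self, bump_signal):
        sig = bump_signal([1.0, 2.0], [30.0, 40.0], duration=4.0)
        assert find_midswing_candidates(sig, 50.0) == []

    def test_amplitude_strictly_above(self, bump_signal):
        sig = bump_signal([1.0, 3.0], [60.0, 40.0], duration=5.0)
        events = find_midswing_candidates(sig, 50.0)
        assert len(events) == 1
        assert events[0].time == pytest.approx(1.0, abs=0.01)
        assert events[0].amplitude == pytest.approx(60.0, rel=0.01)

    def test_monotone_ramp_no_interior_maxima(self):
        sig = PitchSignal("left", 100.0, np.linspace(0, 500, 300), filtered=True)
        assert find_midswing_candidates(sig, 50.0) == []

    def test_unfiltered_warns(self, bump_signal):
        sig = bump_signal([1.0], [80.0], duration=2.0, filtered=False)
        with pytest.warns(UserWarning):
            find_midswing_candidates(sig, 50.0)

    def test_side_tagging(self, bump_signal):
        sig = bump_signal([1.0], [80.0], duration=2.0, side="right")
        events = find_midswing_candidates(sig, 50.0)
        assert events[0].side == "right"


class TestDeduplicate:
    def test_cluster_keeps_max(self):
        evs = [MidswingEvent(0.0, 80.0, "left"), MidswingEvent(0.3, 100.0, "left")]
        out = deduplicate_within_th2(evs, 0.5)
        assert len(out) == 1 and out[0].time == 0.3

    def test_spaced_unchanged(self):
        evs = [MidswingEvent(0.0, 80.0, "left"), MidswingEvent(0.6, 70.0, "left")]
        assert deduplicate_within_th2(evs, 0.5) == evs

    def test_tie_keeps_earlier(self):
        evs = [MidswingEvent(0.0, 90.0, "left"), MidswingEvent(0.2, 90.0, "left")]
        out = deduplicate_within_th2(evs, 0.5)
        assert out[0].time == 0.0

    def test_unsorted_raises(self):
        evs = [MidswingEvent(1.0, 80.0, "left"), MidswingEvent(0.0, 70.0, "left")]
        with pytest.raises(DataError):
            deduplicate_within_th2(evs, 0.5)

    def test_matches_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(0, 15))
            times = np.sort(rng.uniform(0, 5, n))
            evs = [
                MidswingEvent(float(t), float(rng.uniform(50, 200)), "left")
                for t in times
            ]
            th2 = float(rng.uniform(0.1, 1.0))
            assert deduplicate_within_th2(evs, th2) == dedup_oracle(evs, th2)

    def test_survivors_spaced(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 20))
            times = np.sort(rng.uniform(0, 4, n))
            evs = [
                MidswingEvent(float(t), float(rng.uniform(50, 200)), "left")
                for t in times
            ]
            out = deduplicate_within_th2(evs, 0.5)
            gaps = np.diff([e.time for e in out])
            assert np.all(gaps >= 0.5)


class TestAdaptiveTh4:
    def test_no_history_returns_initial(self):
        assert adaptive_th4([]) == 3.5

    def test_printed_formula(self):
        assert adaptive_th4([0.5, 0.7]) == pytest.approx(2.1)

    def test_degenerate_zero_mean(self):
        assert adaptive_th4([0.0]) == pytest.approx(1.5)

    def test_negative_interval_raises(self):
        with pytest.raises(DataError):
            adaptive_th4([-0.1])


def alternating_events(times, first="left"):
    sides = [first, "right" if first == "left" else "left"]
    evs = {"left": [], "right": []}
    for i, t in enumerate(times):
        s = sides[i % 2]
        evs[s].append(MidswingEvent(float(t), 100.0, s))
    return evs["left"], evs["right"]


class TestSegmentBouts:
    def test_empty(self):
        assert segment_bouts([], [], ThresholdSet.init_defaults()) == []

    def test_perfect_alternation_single_bout(self):
        left, right = alternating_events(np.arange(10) * 0.55)
        bouts = segment_bouts(left, right, ThresholdSet.init_defaults())
        assert len(bouts) == 1
        assert bouts[0].n_steps == 10
        assert bouts[0].n_cycles == 5

    def test_same_side_gap_splits(self):
        times = [0.0, 0.55, 1.1, 1.65, 3.1, 3.65, 4.2, 4.75]
        left, right = alternating_events(times)
        bouts = segment_bouts(left, right, ThresholdSet.init_defaults())
        assert [b.n_steps for b in bouts] == [4, 4]

    def test_singletons_discarded(self):
        left = [MidswingEvent(0.0, 100.0, "left")]
        right = [MidswingEvent(20.0, 100.0, "right")]
        assert segment_bouts(left, right, ThresholdSet.init_defaults()) == []

    def test_same_side_adjacency_ends_bout(self):
        left = [MidswingEvent(0.0, 100.0, "left"), MidswingEvent(1.0, 100.0, "left"),
                MidswingEvent(2.0, 100.0, "left")]
        right = [MidswingEvent(0.5, 100.0, "right"), MidswingEvent(2.5, 100.0, "right")]
        bouts = segment_bouts(left, right, ThresholdSet.init_defaults())
        # L(0) R(.5) L(1) | L(2) R(2.5): same-side adjacency at L(2)
        assert [b.n_steps for b in bouts] == [3, 2]

    def test_matches_oracle(self, rng):
        for _ in range(300):
            left, right = random_event_streams(rng)
            th = random_thresholds(rng)
            got = segment_bouts(left, right, th)
            want = segment_oracle(left, right, th)
            assert [tuple(b.events) for b in got] == [w[0] for w in want]
            for b, w in zip(got, want):
                assert b.start == pytest.approx(w[1])
                assert b.end == pytest.approx(w[2])

    def test_events_partition(self, rng):
        # no event appears in two bouts
        for _ in range(50):
            left, right = random_event_streams(rng)
            bouts = segment_bouts(left, right, random_thresholds(rng))
            seen = [e for b in bouts for e in b.events]
            assert len(seen) == len(set(seen))

    def test_bout_span_padding(self):
        left, right = alternating_events([1.0, 1.5, 2.0, 2.5])
        (bout,) = segment_bouts(left, right, ThresholdSet.init_defaults())
        assert bout.start == pytest.approx(0.75)
        assert bout.end == pytest.approx(2.75)

    def test_count_monotone_when_fully_covered(self, rng):
        # relaxing th3/th4 can only merge bouts, provided the baseline
        # already placed every event in a bout (singleton pairing can
        # otherwise create new bouts)
        checked = 0
        while checked < 100:
            left, right = random_event_streams(rng)
            n = len(left) + len(right)
            if n < 2:
                continue
            th = random_thresholds(rng)
            base = segment_bouts(left, right, th)
            if sum(b.n_steps for b in base) != n:
                continue
            checked += 1
            bigger = ThresholdSet(
                th.th1_left, th.th1_right, th.th2, th.th3 + 0.5, th.th4 + 1.0,
                metadata={},
            )
            assert len(segment_bouts(left, right, bigger)) <= len(base)


class TestDetect:
    def test_zero_signals(self):
        zero = PitchSignal("left", 100.0, np.zeros(1000), filtered=True)
        zero_r = PitchSignal("right", 100.0, np.zeros(1000), filtered=True)
        assert detect(zero, zero_r, ThresholdSet.init_defaults()) == []

    def test_sampling_rate_mismatch(self):
        a = PitchSignal("left", 100.0, np.zeros(100), filtered=True)
        b = PitchSignal("right", 50.0, np.zeros(100), filtered=True)
        with pytest.raises(DataError):
            detect(a, b, ThresholdSet.init_defaults())

    def test_lowering_th1_never_fewer_candidates(self, bump_signal):
        sig = bump_signal([1, 2, 3, 4], [60, 90, 120, 150], duration=6.0)
        counts = [len(find_midswing_candidates(sig, th1)) for th1 in (140, 100, 55)]
        assert counts == sorted(counts)

    def test_determinism(self, bump_signal):
        lsig = bump_signal([1.0, 2.1, 3.2], [100, 110, 105], duration=5.0, side="left")
        rsig = bump_signal([1.55, 2.65], [100, 95], duration=5.0, side="right")
        th = ThresholdSet.init_defaults()
        b1 = detect(lsig, rsig, th)
        b2 = detect(lsig, rsig, th)
        assert [b.events for b in b1] == [b.events for b in b2]
        assert [(b.start, b.end) for b in b1] == [(b.start, b.end) for b in b2]

    def test_bouts_validate(self, bump_signal):
        lsig = bump_signal([1.0, 2.1, 3.2], [100, 110, 105], duration=5.0, side="left")
        rsig = bump_signal([1.55, 2.65], [100, 95], duration=5.0, side="right")
        th = ThresholdSet.init_defaults()
        for bout in detect(lsig, rsig, th):
            validate_bout(bout, th)


class TestFilterMinSteps:
    @staticmethod
    def bout_with_steps(n):
        left, right = alternating_events(np.arange(n) * 0.55)
        (bout,) = segment_bouts(left, right, ThresholdSet.init_defaults())
        return bout

    def test_three_steps_removed(self):
        assert filter_min_steps([self.bout_with_steps(3)]) == []

    def test_four_steps_kept(self):
        bouts = [self.bout_with_steps(4)]
        assert filter_min_steps(bouts) == bouts

    def test_empty(self):
        assert filter_min_steps([]) == []


def test_bouts_to_frame_columns():
    left, right = alternating_events(np.arange(4) * 0.5)
    bouts = segment_bouts(left, right, ThresholdSet.init_defaults())
    df = bouts_to_frame(bouts)
    assert list(df.columns) == [
        "bout_id", "start_s", "end_s", "n_steps", "n_cycles", "first_side",
    ]
    assert len(df) == len(bouts)
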