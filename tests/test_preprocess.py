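import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from respiradar import (
    KalmanParams,
    PatternClass,
    RespirationTrace,
    SplitSpec,
    WindowSpec,
    embed_in_radar_frames,
    extract_respiration,
    kalman_filter,
    simulate_pattern,
    split_dataset,
    window_series,
)
from respiradar.datatypes import N_RANGE_BINS, RadarFrame, WindowSample


def kalman_bruteforce(xs, q, r, est, var):
    """Independent hand-stepped scalar random-walk Kalman recursion."""
    out = []
    for m in xs:
        var = var + q
        gain = var / (var + r)
        est = est + gain * (m - est)
        var = var * (1 - gain)
        out.append(est)
    return np.array(out)


class TestKalman:
    def test_constant_input_converges(self):
        x = np.full(1000, 5.0)
        out = kalman_filter(x, KalmanParams(q=0.01, r=0.1),
                            init_estimate=0.0, init_variance=1.0)
        assert abs(out[-1] - 5.0) < 1e-6

    def test_r_zero_trusts_measurement(self):
        x = np.array([3.0, -1.0, 7.0, 2.0])
        out = kalman_filter(x, KalmanParams(q=0.5, r=0.0))
        assert np.allclose(out, x)

    def test_hand_stepped_three_samples(self):
        # hand-computed predict/update steps for q=0.01, r=0.1, x0=0, P0=1
        out = kalman_filter([1.0, 2.0, 3.0], KalmanParams(q=0.01, r=0.1),
                            init_estimate=0.0, init_variance=1.0)
        expected = [0.9099099099099098, 1.4576423128641864, 2.0375094402953766]
        assert np.allclose(out, expected, rtol=0, atol=1e-15)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        xs=st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=100),
        q=st.floats(1e-4, 1.0),
        r=st.floats(0.0, 1.0),
    )
    def test_matches_bruteforce_recursion(self, xs, q, r):
        params = KalmanParams(q=q, r=r)
        out = kalman_filter(xs, params)
        ref = kalman_bruteforce(xs, q, r, est=xs[0], var=r + q)
        assert np.allclose(out, ref, rtol=0, atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            kalman_filter([], KalmanParams())

    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            KalmanParams(q=0.0)
        with pytest.raises(ValueError):
            KalmanParams(r=-1.0)


def _frames_from_matrix(arr: np.ndarray) -> list[RadarFrame]:
    return [RadarFrame(frame_no=i, timestamp=i / 25.0, bins=row)
            for i, row in enumerate(arr)]


class TestExtractRespiration:
    def test_roundtrip_selects_simulator_bin(self):
        trace = simulate_pattern(PatternClass.EUPNEA, 20, noise_sd=0.0, seed=2)
        frames = embed_in_radar_frames(trace, distance_cm=20.0, clutter_sd=0.0)
        extracted, sel = extract_respiration(frames, distance_cm=20.0,
                                             return_bin=True)
        assert sel == round(20.0 / 3.0)
        # the extracted series is exactly the Kalman-filtered target bin
        assert np.allclose(extracted.samples, kalman_filter(trace.samples))
        corr = np.corrcoef(extracted.samples, trace.samples)[0, 1]
        assert corr > 0.95  # smoothing introduces a small lag

    def test_constant_frames_tie_breaks_to_lowest(self):
        arr = np.ones((50, N_RANGE_BINS))
        trace, sel = extract_respiration(_frames_from_matrix(arr),
                                         distance_cm=20.0, tolerance_bins=3,
                                         return_bin=True)
        assert sel == 7 - 3  # lowest index in the candidate neighbourhood
        assert np.allclose(trace.samples, 1.0)

    def test_tolerance_gates_out_far_bin(self):
        rng = np.random.default_rng(0)
        arr = np.zeros((100, N_RANGE_BINS))
        arr[:, 8] = np.sin(np.linspace(0, 12, 100))          # near, weaker
        arr[:, 30] = 5 * rng.standard_normal(100)            # far, stronger
        _, sel = extract_respiration(_frames_from_matrix(arr),
                                     distance_cm=20.0, tolerance_bins=3,
                                     return_bin=True)
        assert sel == 8

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            extract_respiration([], distance_cm=20.0)

    def test_distance_outside_bins_rejected(self):
        arr = np.zeros((5, N_RANGE_BINS))
        with pytest.raises(ValueError):
            extract_respiration(_frames_from_matrix(arr), distance_cm=1e6)


def _trace(n: int, label=PatternClass.EUPNEA) -> RespirationTrace:
    return RespirationTrace(np.arange(n, dtype=float), fs=25.0, label=label,
                            subject_id="T")


class TestWindowing:
    @pytest.mark.parametrize("T,expected", [(660, 35), (250, 1), (262, 2)])
    def test_window_count_closed_form(self, T, expected):
        spec = WindowSpec(window_len=250, shift=12)
        wins = window_series(_trace(T), spec)
        assert len(wins) == expected

    def test_max_windows_cap_to_500(self):
        # a 10-min recording: 15000 samples -> 1230 candidates, capped at 500
        spec = WindowSpec()
        wins = window_series(_trace(15000), spec, max_windows=500)
        assert len(wins) == 500

    def test_windows_are_exact_slices(self):
        tr = _trace(700)
        spec = WindowSpec(window_len=250, shift=12)
        wins = window_series(tr, spec)
        for k, w in enumerate(wins):
            start = k * 12
            assert np.array_equal(w.values, tr.samples[start:start + 250])

    def test_label_purity(self):
        wins = window_series(_trace(700, PatternClass.MOTION), WindowSpec())
        assert all(w.label is PatternClass.MOTION for w in wins)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            window_series(_trace(100), WindowSpec())

    def test_unlabeled_trace_needs_label(self):
        tr = RespirationTrace(np.zeros(300), fs=25.0)
        with pytest.raises(ValueError):
            window_series(tr, WindowSpec())
        wins = window_series(tr, WindowSpec(), label=PatternClass.APNEA)
        assert wins[0].label is PatternClass.APNEA


def _balanced_samples(per_class: int) -> list[WindowSample]:
    return [
        WindowSample(values=np.full(250, float(i)), label=cls,
                     source_id=f"{cls.value}:{i}")
        for cls in PatternClass for i in range(per_class)
    ]


class TestSplit:
    def test_protocol_split_counts(self):
        samples = _balanced_samples(500)          # 2500 windows
        train, test = split_dataset(samples, SplitSpec(train_fraction=0.6, seed=0))
        assert (len(train), len(test)) == (1500, 1000)

    def test_disjoint_and_exhaustive(self):
        samples = _balanced_samples(10)
        train, test = split_dataset(samples, SplitSpec(seed=3))
        ids = [s.source_id for s in train] + [s.source_id for s in test]
        assert sorted(ids) == sorted(s.source_id for s in samples)
        assert len(set(s.source_id for s in train)
                   & set(s.source_id for s in test)) == 0

    def test_stratification_per_class(self):
        samples = _balanced_samples(10)
        train, _ = split_dataset(samples, SplitSpec(train_fraction=0.6, seed=1))
        counts = {cls: 0 for cls in PatternClass}
        for s in train:
            counts[s.label] += 1
        assert all(v == 6 for v in counts.values())

    def test_single_member_classes_go_to_train(self):
        samples = _balanced_samples(1)
        with pytest.warns(UserWarning):
            train, test = split_dataset(samples, SplitSpec(train_fraction=0.6))
        assert (len(train), len(test)) == (5, 0)

    def test_determinism(self):
        samples = _balanced_samples(20)
        a = split_dataset(samples, SplitSpec(seed=5))
        b = split_dataset(samples, SplitSpec(seed=5))
        assert [s.source_id for s in a[0]] == [s.source_id for s in b[0]]
        assert [s.source_id for s in a[1]] == [s.source_id for s in b[1]]

    def test_unstratified_split(self):
        samples = _balanced_samples(10)
        train, test = split_dataset(
            samples, SplitSpec(train_fraction=0.6, seed=2, stratified=False))
        assert (len(train), len(test)) == (30, 20)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([], SplitSpec())
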