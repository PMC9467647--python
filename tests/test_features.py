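"""Measurement pipeline: constructed examples, brute-force oracles and
structural invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sledfriction as sf
from sledfriction.features import (
    MIN_RELIABLE_WINDOW_MM,
    Segment,
    _prominence,
    default_static_prominence,
)
from sledfriction.io import (
    FLAG_FEWER_THAN_K_PEAKS,
    FLAG_NO_PEAKS,
    FLAG_TRUNCATED_WINDOW,
)
from conftest import sawtooth_curve


def seg_from(y, dx=0.06, start=0.0):
    y = np.asarray(y, float)
    x = start + dx * np.arange(1, len(y) + 1)
    return Segment(distance=x, force=y, start=start, end=float(x[-1]), truncated=False)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive)
# ---------------------------------------------------------------------------


def brute_extrema(y):
    """Neighbour-comparison scan with the plateau rule: collapse runs of
    equal values, compare run maxima/minima against adjacent runs,
    report the extremum at the last index of its run."""
    y = np.asarray(y, float)
    runs = []  # (value, last_index)
    for i, v in enumerate(y):
        if runs and runs[-1][0] == v:
            runs[-1] = (v, i)
        else:
            runs.append((v, i))
    out = []
    for k in range(1, len(runs) - 1):
        v, idx = runs[k]
        if runs[k - 1][0] < v > runs[k + 1][0]:
            out.append((idx, +1))
        elif runs[k - 1][0] > v < runs[k + 1][0]:
            out.append((idx, -1))
    return out


def brute_prominence(y, i):
    """Definition-level prominence: scan to the nearest higher point on
    each side, take the minimum in between, reference the higher of the
    two minima."""
    y = np.asarray(y, float)
    h = y[i]
    lo = [v for v in y[:i][::-1]]
    left = h
    for v in lo:
        if v > h:
            break
        left = min(left, v)
    right = h
    for v in y[i + 1 :]:
        if v > h:
            break
        right = min(right, v)
    return h - max(left, right)


def brute_identify(y, x, thresh, min_sep):
    """Exhaustive enumeration: prominence-qualified maxima, then keep
    greedily by height (earlier index on ties) subject to separation."""
    cands = [i for i, k in brute_extrema(y) if k > 0]
    cands = [i for i in cands if brute_prominence(y, i) >= thresh]
    kept = []
    for i in sorted(cands, key=lambda i: (-y[i], i)):
        if all(abs(x[i] - x[j]) >= min_sep * (1 - 1e-9) for j in kept):
            kept.append(i)
    return sorted(kept)


# ---------------------------------------------------------------------------
# Static peak
# ---------------------------------------------------------------------------


class TestStaticPeak:
    def test_constructed_ramp_and_drop(self):
        x = np.arange(0, 20.0, 0.06)
        y = np.where(x <= 2.0, 15.0 * x, 20.0)
        i = np.argmin(np.abs(x - 2.0))
        y[i] = 30.0
        curve = sf.ForceCurve("t", "sp", "apical", x, y)
        d, f = sf.detect_static_peak(curve)
        assert f == 30.0
        assert d == pytest.approx(x[i])

    def test_monotone_curve_raises(self):
        x = np.arange(0, 20.0, 0.06)
        curve = sf.ForceCurve("t", "sp", "apical", x, 2.0 * x)
        with pytest.raises(sf.NoStaticPeakError):
            sf.detect_static_peak(curve)

    def test_simulated_recovery_with_noise(self, config):
        p = sf.SimParams(
            static_force_true=80.0,
            loading_stiffness=40.0,
            sliding_baseline=40.0,
            event_rate=1.0,
            amplitude_log_mean=2.0,
            noise_sd=1.0,
        )
        for s in range(20):
            curve, truth = sf.simulate_curve(p, config, seed=s)
            d, f = sf.detect_static_peak(curve)
            assert abs(f - 80.0) <= 3.0 * 1.0
            assert abs(d - truth.static_peak_distance) <= config.sample_spacing + 1e-9

    def test_default_prominence_floor_is_noise_scaled(self):
        rng = np.random.default_rng(0)
        y = rng.normal(10, 0.5, 300)
        assert default_static_prominence(y) >= 3.0 * np.median(np.abs(np.diff(y)))


class TestSlidingWindow:
    def test_full_window(self, noisefree_curve, config):
        curve, truth = noisefree_curve
        seg = sf.sliding_window(curve, truth.static_peak_distance, config)
        assert seg.length_mm == pytest.approx(15.0)
        assert not seg.truncated
        assert seg.distance[0] > truth.static_peak_distance  # half-open

    def test_truncated_window(self, config):
        x = np.arange(0, 20.0 + 1e-9, 0.06)
        y = np.sin(x) + 5
        curve = sf.ForceCurve("t", "sp", "apical", x, y)
        seg = sf.sliding_window(curve, 8.0, config)
        assert seg.truncated
        assert seg.end == pytest.approx(x[-1])
        assert seg.length_mm == pytest.approx(x[-1] - 8.0)

    def test_sample_count_at_defaults(self, noisefree_curve, config):
        curve, truth = noisefree_curve
        seg = sf.sliding_window(curve, truth.static_peak_distance, config)
        assert abs(len(seg) - int(15 * 50 / 3)) <= 1

    def test_window_too_short(self, config):
        x = np.arange(0, 20.0, 0.06)
        curve = sf.ForceCurve("t", "sp", "apical", x, np.ones_like(x))
        with pytest.raises(sf.WindowTooShortError):
            sf.sliding_window(curve, 19.8, config)


class TestSlidingMean:
    def test_constant_segment(self):
        assert sf.sliding_mean(seg_from(np.full(100, 20.0))) == 20.0

    def test_symmetric_sawtooth_about_50(self):
        x, y = sawtooth_curve(n_teeth=24, base=50.0, tooth_height=10.0)
        post = x > 2.0
        seg = Segment(x[post], y[post], 2.0, float(x[-1]), False)
        assert sf.sliding_mean(seg) == pytest.approx(50.0, abs=0.2)

    def test_analytic_event_contribution(self, config):
        """Mean force = baseline + E[amplitude]/2 for back-to-back
        sawtooth events (each event's triangle spans its inter-event
        gap), within Monte-Carlo error over seeds."""
        lam, mu, sd = 1.5, 2.0, 0.3
        p = sf.SimParams(
            static_force_true=80.0,
            loading_stiffness=40.0,
            sliding_baseline=40.0,
            event_rate=lam,
            amplitude_log_mean=mu,
            amplitude_log_sd=sd,
            noise_sd=0.0,
        )
        means = []
        for s in range(100):
            curve, truth = sf.simulate_curve(p, config, seed=s)
            seg = sf.sliding_window(curve, truth.static_peak_distance, config)
            means.append(sf.sliding_mean(seg))
        expected = 40.0 + np.exp(mu + sd**2 / 2) / 2.0
        assert np.mean(means) == pytest.approx(expected, rel=0.05)


# ---------------------------------------------------------------------------
# Extrema / detrend / peaks vs oracles
# ---------------------------------------------------------------------------


class TestDetectExtrema:
    def test_enumerated_example(self):
        idx, forces, kinds = sf.detect_extrema(np.array([1.0, 3, 2, 4, 1]))
        assert list(idx) == [1, 2, 3]
        assert list(kinds) == [1, -1, 1]

    def test_monotone_empty(self):
        idx, _, _ = sf.detect_extrema(np.linspace(0, 1, 30))
        assert len(idx) == 0

    def test_plateau_collapses_to_end(self):
        idx, _, kinds = sf.detect_extrema(np.array([0.0, 1, 1, 1, 0]))
        assert list(idx) == [3] and list(kinds) == [1]

    @given(
        st.lists(
            st.integers(min_value=0, max_value=6), min_size=3, max_size=30
        )
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_bruteforce_with_plateaus(self, values):
        y = np.array(values, dtype=float)
        idx, _, kinds = sf.detect_extrema(y)
        assert list(zip(idx, kinds)) == brute_extrema(y)

    def test_alternation_property(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            y = rng.normal(size=rng.integers(3, 60))
            _, _, kinds = sf.detect_extrema(y)
            assert all(a != b for a, b in zip(kinds, kinds[1:]))


class TestDetrend:
    def test_recovers_known_drift(self):
        x = np.arange(0, 15, 0.06)
        periodic = 3.0 * np.sin(2 * np.pi * x / 0.7)
        y = 30.0 + 2.0 * x + periodic
        seg = Segment(x, y, 0.0, 15.0, False)
        _, (slope, _) = sf.detrend(seg)
        assert slope == pytest.approx(2.0, abs=0.1)

    def test_zero_drift_sawtooth(self):
        x, y = sawtooth_curve(n_teeth=24)
        post = x > 2.0
        seg = Segment(x[post], y[post], 2.0, float(x[-1]), False)
        _, (slope, _) = sf.detrend(seg)
        assert slope == pytest.approx(0.0, abs=0.05)

    def test_fallback_without_extrema(self):
        x = np.arange(0, 5, 0.06)
        y = 2.0 * x + 1
        seg = Segment(x, y, 0.0, 5.0, False)
        detrended, (slope, intercept) = sf.detrend(seg)
        assert slope == 0.0 and intercept == pytest.approx(np.mean(y))
        np.testing.assert_allclose(detrended, y - np.mean(y))

    def test_detrend_then_identify_equals_driftfree(self):
        """Identification after detrending a drifted signal matches
        identification on the drift-free copy."""
        x, y0 = sawtooth_curve(n_teeth=20, tooth_height=8.0)
        post = x > 2.0
        xs, ys = x[post], y0[post]
        drifted = ys + 1.5 * (xs - xs[0])
        seg_d = Segment(xs, drifted, 2.0, float(xs[-1]), False)
        seg_0 = Segment(xs, ys, 2.0, float(xs[-1]), False)
        det_d, _ = sf.detrend(seg_d)
        det_0, _ = sf.detrend(seg_0)
        p_d = sf.identify_peaks(det_d, xs, 3.0, 0.18)
        p_0 = sf.identify_peaks(det_0, xs, 3.0, 0.18)
        assert list(p_d) == list(p_0)


class TestIdentifyPeaks:
    def test_24_teeth_counted(self):
        x, y = sawtooth_curve(n_teeth=24, tooth_height=10.0)
        post = x > 2.0
        seg = Segment(x[post], y[post], 2.0, float(x[-1]), False)
        det, _ = sf.detrend(seg)
        peaks = sf.identify_peaks(det, seg.distance, 5.0, 0.18)
        assert len(peaks) == 24

    def test_threshold_above_teeth_gives_zero(self):
        x, y = sawtooth_curve(n_teeth=24, tooth_height=10.0)
        post = x > 2.0
        seg = Segment(x[post], y[post], 2.0, float(x[-1]), False)
        det, _ = sf.detrend(seg)
        assert len(sf.identify_peaks(det, seg.distance, 50.0, 0.18)) == 0

    def test_prominence_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            y = rng.normal(size=25)
            for i, k in brute_extrema(y):
                if k > 0:
                    assert _prominence(y, i) == pytest.approx(brute_prominence(y, i))

    def test_matches_exhaustive_enumeration(self):
        """On short random segments the identifier equals brute-force
        enumeration of prominence-qualified, separation-filtered maxima."""
        rng = np.random.default_rng(11)
        for _ in range(300):
            n = int(rng.integers(5, 31))
            y = np.round(rng.normal(size=n), 2)
            x = 0.06 * np.arange(n)
            thresh = float(rng.uniform(0.1, 2.0))
            sep = float(rng.choice([0.0, 0.06, 0.18]))
            got = list(sf.identify_peaks(y, x, thresh, sep))
            assert got == brute_identify(y, x, thresh, sep)

    # Matching tolerance: at sparse rates the rise slope near an apex is
    # shallow (~0.5 mN per sample vs 1 mN noise), so the noisy maximum
    # wanders a few samples; 0.3 mm is still far below the mean gap.
    MATCH_TOL_MM = 0.3

    def test_simulated_recall(self, config):
        """Recall >= 0.9 against ground-truth events when sensor noise is
        10% of the median event amplitude."""
        p = sf.SimParams(
            static_force_true=80.0,
            loading_stiffness=40.0,
            sliding_baseline=40.0,
            event_rate=0.7,
            amplitude_log_mean=np.log(10.0),
            amplitude_log_sd=0.4,
            noise_sd=1.0,
        )
        recalls = []
        for s in range(40):
            curve, truth = sf.simulate_curve(p, config, seed=s)
            feats = sf.extract_features(curve, config)
            ev = np.asarray(truth.event_positions)
            ev = ev[(ev > feats.window_start) & (ev <= feats.window_end)]
            det = np.asarray(feats.peak_positions)
            if len(ev) == 0:
                continue
            hits = sum(np.min(np.abs(det - e)) <= self.MATCH_TOL_MM for e in ev if len(det))
            recalls.append(hits / len(ev))
        assert np.mean(recalls) >= 0.9


class TestPeakFrequencyAndMax:
    def test_frequency_arithmetic(self):
        assert sf.peak_frequency(24, 15.0) == pytest.approx(1.6)
        assert sf.peak_frequency(0, 15.0) == 0.0

    def test_poisson_rate_recovery(self, config):
        p = sf.SimParams(
            static_force_true=80.0,
            loading_stiffness=40.0,
            sliding_baseline=40.0,
            event_rate=1.5,
            amplitude_log_mean=2.3,
            amplitude_log_sd=0.4,
            noise_sd=1.0,
        )
        ests = [
            sf.extract_features(sf.simulate_curve(p, config, seed=s)[0], config).peak_frequency
            for s in range(200)
        ]
        assert 1.4 <= float(np.mean(ests)) <= 1.6

    def test_topk_arithmetic(self):
        forces = np.arange(1.0, 16.0)  # 1..15
        seg = seg_from(np.concatenate([forces, [0.0]]))
        idx = np.arange(15)
        value, flags = sf.max_sliding_force(idx, seg, k=10)
        assert value == pytest.approx(np.mean(np.arange(6.0, 16.0)))  # 10.5
        assert not flags

    def test_shortfall_flagged(self):
        seg = seg_from(np.full(12, 2.0))
        value, flags = sf.max_sliding_force(np.arange(7), seg, k=10)
        assert value == 2.0
        assert FLAG_FEWER_THAN_K_PEAKS in flags

    def test_zero_peaks_returns_sliding_mean(self):
        seg = seg_from(np.full(12, 5.0))
        value, flags = sf.max_sliding_force(np.array([], dtype=int), seg, k=10)
        assert value == 5.0
        assert FLAG_NO_PEAKS in flags


# ---------------------------------------------------------------------------
# Full extraction
# ---------------------------------------------------------------------------


class TestExtractFeatures:
    def test_noise_free_exact_values(self, noisefree_curve, config):
        curve, _ = noisefree_curve
        f = sf.extract_features(curve, config)
        assert f.static_force == 80.0
        assert f.sliding_mean_force == pytest.approx(40.0)
        assert f.peak_frequency == 0.0
        assert f.cv_sliding == pytest.approx(0.0, abs=1e-9)

    def test_determinism(self, noisy_params, config):
        curve, _ = sf.simulate_curve(noisy_params, config, seed=5)
        assert sf.extract_features(curve, config) == sf.extract_features(curve, config)

    def test_ordering_invariant(self, noisy_params, config):
        """sliding_mean <= max_sliding <= window max whenever peaks exist."""
        for s in range(50):
            curve, _ = sf.simulate_curve(noisy_params, config, seed=s)
            f = sf.extract_features(curve, config)
            if f.n_peaks >= 1:
                assert f.sliding_mean_force <= f.max_sliding_force
                seg = sf.sliding_window(curve, f.static_peak_distance, config)
                assert f.max_sliding_force <= np.max(seg.force) + 1e-9

    def test_peak_count_consistency(self, noisy_params, config):
        curve, _ = sf.simulate_curve(noisy_params, config, seed=8)
        f = sf.extract_features(curve, config)
        assert f.peak_frequency * f.window_length == pytest.approx(f.n_peaks)

    def test_offset_invariance(self, noisy_params, config):
        """A constant force offset leaves counts untouched and shifts
        forces by the constant."""
        curve, _ = sf.simulate_curve(noisy_params, config, seed=13)
        shifted = sf.ForceCurve(
            curve.test_id, curve.species, curve.direction,
            curve.distance, curve.force + 50.0,
        )
        f0 = sf.extract_features(curve, config)
        f1 = sf.extract_features(shifted, config)
        assert f1.n_peaks == f0.n_peaks
        assert f1.peak_frequency == pytest.approx(f0.peak_frequency)
        assert f1.static_force == pytest.approx(f0.static_force + 50.0)
        assert f1.sliding_mean_force == pytest.approx(f0.sliding_mean_force + 50.0)

    def test_truncated_window_flagged(self, config):
        p = sf.SimParams(
            static_force_true=240.0,
            loading_stiffness=40.0,  # ramp needs 6 mm -> window truncated
            sliding_baseline=100.0,
            event_rate=1.0,
            amplitude_log_mean=2.3,
            noise_sd=1.0,
        )
        curve, _ = sf.simulate_curve(p, config, seed=2)
        f = sf.extract_features(curve, config)
        assert FLAG_TRUNCATED_WINDOW in f.flags
        assert f.window_length < 15.0
        assert f.window_length >= MIN_RELIABLE_WINDOW_MM

    def test_paired_anisotropy_recovery(self, config):
        """Basal/apical static ratio estimates the generative factor."""
        ratios = []
        for s in range(50):
            pa = sf.SimParams(direction="apical", anisotropy_true=3.0,
                              amplitude_log_mean=2.3, noise_sd=1.0)
            pb = sf.SimParams(direction="basal", anisotropy_true=3.0,
                              amplitude_log_mean=2.3, noise_sd=1.0)
            ca, _ = sf.simulate_curve(pa, config, seed=s)
            cb, _ = sf.simulate_curve(pb, config, seed=1000 + s)
            fa = sf.extract_features(ca, config)
            fb = sf.extract_features(cb, config)
            ratios.append(fb.static_force / fa.static_force)
        assert 2.5 <= float(np.mean(ratios)) <= 3.5
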