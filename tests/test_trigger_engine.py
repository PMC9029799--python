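"""Trigger algorithms: k-of-n scanning, dynamic state, settings grid."""

import numpy as np
import pytest

from addhrvr import (
    AlgorithmSettings,
    ConfigurationError,
    enumerate_settings,
    expected_rmssd,
    flag_decreases,
    run_algorithm,
    run_dynamic_state,
    scan_triggers,
)

from conftest import make_model, make_series


def naive_triggers(flags, n, k, silent):
    """Brute-force re-scan: re-check window and silent constraint per minute."""
    triggers = []
    for t in range(len(flags)):
        if t < n - 1:
            continue
        if sum(flags[t - n + 1 : t + 1]) < k:
            continue
        if triggers and t - triggers[-1] <= silent:
            continue
        triggers.append(t)
    return triggers


class TestSettings:
    def test_grid_count_full_range(self):
        assert len(enumerate_settings(2, 30)) == 435

    def test_smallest_grid(self):
        assert enumerate_settings(2, 2) == [(2, 1)]

    def test_partial_grid_count(self):
        # sum of (L-1) for L=2..5
        assert len(enumerate_settings(2, 5)) == 10

    def test_lexicographic_order(self):
        pairs = enumerate_settings(2, 4)
        assert pairs == sorted(pairs)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(window_length=1, window_threshold=1),
            dict(window_length=31, window_threshold=1),
            dict(window_length=5, window_threshold=5),
            dict(window_length=5, window_threshold=0),
            dict(silent_min=-1),
            dict(decrease_mult=0.0),
            dict(variant="fancy"),
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            AlgorithmSettings(**kwargs)


class TestExpectedRmssd:
    def test_linear_arithmetic(self):
        m = make_model(intercept=50, slope=-2)
        assert expected_rmssd(m, 3.0) == pytest.approx(44.0)

    def test_zero_aee_gives_intercept(self):
        m = make_model(intercept=50, slope=-2)
        assert expected_rmssd(m, 0.0) == pytest.approx(50.0)

    def test_dynamic_intercept_equal_to_static_reduces_to_static(self):
        m = make_model(intercept=50, slope=-2)
        aee = np.linspace(0, 5, 20)
        np.testing.assert_allclose(
            expected_rmssd(m, aee, dynamic_intercept=50.0),
            expected_rmssd(m, aee),
        )


class TestFlags:
    def test_far_above_expected_no_flags(self, default_settings):
        m = make_model(intercept=50, slope=0, sd=5)
        series = make_series(np.full(30, 150.0))
        flags, _ = flag_decreases(series, m, default_settings)
        assert not flags.any()

    def test_far_below_expected_all_valid_flagged(self, default_settings):
        m = make_model(intercept=50, slope=0, sd=5)
        valid = np.ones(30, bool)
        valid[3] = False
        series = make_series(np.full(30, 1.0), valid=valid)
        flags, _ = flag_decreases(series, m, default_settings)
        assert flags.sum() == 29
        assert not flags[3]

    def test_planted_subthreshold_minutes_exactly_flagged(self, default_settings):
        # threshold = 50 - 0.5*10 = 45
        m = make_model(intercept=50, slope=0, sd=10)
        rmssd = np.full(10, 48.0)
        rmssd[[2, 5, 9]] = 44.0
        series = make_series(rmssd)
        flags, trace = flag_decreases(series, m, default_settings)
        assert list(np.flatnonzero(flags)) == [2, 5, 9]
        np.testing.assert_allclose(trace, 45.0)

    def test_mismatched_participant_rejected(self, default_settings):
        m = make_model(pid="OTHER")
        with pytest.raises(ConfigurationError):
            flag_decreases(make_series([40] * 5), m, default_settings)


class TestDynamicState:
    def test_constant_at_intercept_is_fixed_point(self):
        m = make_model(intercept=50, slope=-2, mean_aee=1.0)
        series = make_series(np.full(120, 50.0), aee=np.full(120, 0.2))
        st = AlgorithmSettings(variant="dynamic", window_length=5, window_threshold=3)
        np.testing.assert_allclose(run_dynamic_state(series, m, st), 50.0)

    def test_high_aee_branch_never_absorbs_hrv(self):
        m = make_model(intercept=50, slope=-2, mean_aee=1.0)
        series = make_series(np.full(120, 90.0), aee=np.full(120, 5.0))
        st = AlgorithmSettings(variant="dynamic", window_length=5, window_threshold=3)
        np.testing.assert_allclose(run_dynamic_state(series, m, st), 50.0)

    def test_step_change_ramps_linearly_over_buffer_length(self):
        m = make_model(intercept=50, slope=-2, mean_aee=1.0)
        n, t0 = 200, 80
        rmssd = np.where(np.arange(n) < t0, 50.0, 70.0)
        series = make_series(rmssd, aee=np.full(n, 0.2))
        st = AlgorithmSettings(variant="dynamic", window_length=5, window_threshold=3)
        trace = run_dynamic_state(series, m, st)
        # lag-1 buffers: minute t uses values pushed before t
        expected = 50.0 + 20.0 * np.clip(np.arange(n) - t0, 0, 60) / 60.0
        np.testing.assert_allclose(trace, expected)

    def test_invalid_minutes_push_neutral_values(self):
        m = make_model(intercept=50, slope=-2, mean_aee=1.0)
        series = make_series(np.full(100, 70.0), aee=np.full(100, 0.2),
                             valid=np.zeros(100, bool))
        st = AlgorithmSettings(variant="dynamic", window_length=5, window_threshold=3)
        np.testing.assert_allclose(run_dynamic_state(series, m, st), 50.0)

    def test_requires_linear_model(self):
        m = make_model(kind="inverse")
        st = AlgorithmSettings(variant="dynamic", window_length=5, window_threshold=3)
        with pytest.raises(ConfigurationError):
            run_dynamic_state(make_series([40] * 10), m, st)


class TestScan:
    def test_all_flags_one_of_two_silent_20(self):
        flags = np.ones(100, bool)
        triggers = scan_triggers(flags, 2, 1, 20)
        assert list(triggers) == [1, 22, 43, 64, 85]

    def test_no_flags_no_triggers(self):
        assert len(scan_triggers(np.zeros(100, bool), 5, 4, 20)) == 0

    def test_matches_naive_rescan_on_random_inputs(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            t = int(rng.integers(5, 200))
            flags = rng.random(t) < rng.uniform(0.05, 0.6)
            n = int(rng.integers(2, 16))
            k = int(rng.integers(1, n))
            silent = int(rng.integers(0, 30))
            got = list(scan_triggers(flags, n, k, silent))
            assert got == naive_triggers(list(flags), n, k, silent)

    def test_silent_spacing_invariant(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            flags = rng.random(300) < 0.5
            trig = scan_triggers(flags, 4, 2, 17)
            if len(trig) > 1:
                assert np.diff(trig).min() > 17

    def test_causality_truncation_preserves_past_triggers(self):
        rng = np.random.default_rng(14)
        flags = rng.random(250) < 0.3
        full = scan_triggers(flags, 6, 3, 10)
        for cut in (50, 120, 200):
            part = scan_triggers(flags[:cut], 6, 3, 10)
            assert list(part) == [t for t in full if t < cut]

    def test_threshold_monotonicity_before_silencing(self):
        from addhrvr.trigger_engine import window_counts

        rng = np.random.default_rng(15)
        flags = rng.random(400) < 0.4
        counts = window_counts(flags, 8)
        for k in range(1, 7):
            hi = set(np.flatnonzero(counts >= k + 1))
            lo = set(np.flatnonzero(counts >= k))
            assert hi <= lo


class TestRunAlgorithm:
    def test_variant_model_kind_mismatch(self, default_settings):
        m = make_model(kind="inverse")
        with pytest.raises(ConfigurationError):
            run_algorithm(make_series([40] * 50), m, default_settings)
        st_inv = AlgorithmSettings(variant="inverse", window_length=5,
                                   window_threshold=4)
        with pytest.raises(ConfigurationError):
            run_algorithm(make_series([40] * 50), make_model(), st_inv)

    def test_trigger_train_invariants_on_random_series(self):
        rng = np.random.default_rng(16)
        m = make_model(intercept=50, slope=-2, sd=8, mean_aee=1.0)
        for _ in range(20):
            n = int(rng.integers(40, 200))
            aee = rng.uniform(0, 3, n)
            rmssd = np.clip(50 - 2 * aee + rng.normal(0, 8, n), 1, None)
            series = make_series(rmssd, aee=aee)
            st = AlgorithmSettings(
                variant="static",
                window_length=int(rng.integers(2, 10)),
                window_threshold=1,
                silent_min=int(rng.integers(0, 25)),
            )
            train = run_algorithm(series, m, st)
            if len(train.trigger_minutes) > 1:
                assert np.diff(train.trigger_minutes).min() > st.silent_min
            for t in train.trigger_minutes:
                window = train.decrease_flags[
                    max(0, t - st.window_length + 1) : t + 1
                ]
                assert window.sum() >= st.window_threshold

    def test_static_and_dynamic_differ_on_drifting_series(self):
        # an HRV level drift leaves the static threshold behind while the
        # dynamic intercept tracks it, changing the trigger pattern
        rng = np.random.default_rng(17)
        n = 600
        aee = np.full(n, 0.2)
        drift = np.linspace(20, -20, n)  # slow fall of the HRV level
        rmssd = np.clip(50 + drift + rng.normal(0, 2, n), 1, None)
        series = make_series(rmssd, aee=aee)
        m = make_model(intercept=50, slope=-2, sd=6, mean_aee=1.0)
        st_s = AlgorithmSettings(variant="static", window_length=6,
                                 window_threshold=4)
        st_d = AlgorithmSettings(variant="dynamic", window_length=6,
                                 window_threshold=4)
        static = set(run_algorithm(series, m, st_s).trigger_minutes)
        dynamic = set(run_algorithm(series, m, st_d).trigger_minutes)
        assert static != dynamic

    def test_inverse_variant_runs_with_inverse_model(self):
        rng = np.random.default_rng(18)
        aee = rng.uniform(0.2, 3, 300)
        rmssd = np.clip(20 + 15 / (aee + 0.1) + rng.normal(0, 3, 300), 1, None)
        series = make_series(rmssd, aee=aee)
        from addhrvr import fit_calibration

        m = fit_calibration(series, "inverse", epsilon=0.1)
        st = AlgorithmSettings(variant="inverse", window_length=5,
                               window_threshold=2)
        train = run_algorithm(series, m, st)
        assert train.decrease_flags.shape == (300,)
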