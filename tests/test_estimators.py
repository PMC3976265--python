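import numpy as np
import pytest

from spskit import (
    CONST100,
    SHORT5,
    STEP,
    UNDEFINED,
    DETECTORS,
    ESTIMATOR_IDS,
    EstimatorParams,
    GeneratorSpec,
    IteratedProblem,
    estimate_mean,
    generate_series,
    solver_step,
)
from spskit.core import SolverState, as_series

ALTERNATING = np.tile([9.0, 11.0], 50)
RAMP = np.arange(1.0, 101.0)


def brute_force_mser(x, m_min=10):
    """O(n^2) direct evaluation of the MSER statistic."""
    n = len(x)
    best_d, best_v = None, np.inf
    for d in range(0, n - m_min + 1):
        suffix = x[d:]
        v = np.sum((suffix - suffix.mean()) ** 2) / len(suffix) ** 2
        if v < best_v - 1e-15:
            best_d, best_v = d, v
    return best_d, best_v


class TestSharedConventions:
    @pytest.mark.parametrize("estimator_id", ESTIMATOR_IDS)
    def test_constant_series_detected_at_zero(self, estimator_id):
        det = DETECTORS[estimator_id](CONST100)
        assert det.found and det.truncation == 0

    @pytest.mark.parametrize("estimator_id", ESTIMATOR_IDS)
    @pytest.mark.parametrize("n", [0, 1, 3])
    def test_insufficient_data_never_raises(self, estimator_id, n):
        det = DETECTORS[estimator_id](np.full(n, 10.0))
        assert det.found is False

    @pytest.mark.parametrize("estimator_id", ESTIMATOR_IDS)
    def test_truncation_always_in_range(self, estimator_id, random_series_batch):
        for x in random_series_batch[:30]:
            det = DETECTORS[estimator_id](x)
            if det.found:
                assert 0 <= det.truncation < len(x)


class TestMSER:
    def test_step_truncated_exactly_at_step(self):
        det = DETECTORS["mser"](STEP)
        assert det.found and det.truncation == 50 and det.statistic == 0.0

    def test_too_short_series_not_found(self):
        assert DETECTORS["mser"](SHORT5).found is False

    def test_matches_brute_force_oracle(self, random_series_batch):
        for x in random_series_batch:
            d_oracle, _ = brute_force_mser(x)
            det = DETECTORS["mser"](x)
            if d_oracle < len(x) / 2:
                assert det.found and det.truncation == d_oracle
            else:
                assert det.found is False


class TestEuclidean:
    def test_step_detected_at_steady_vector_boundary(self):
        det = DETECTORS["euclidean"](STEP)
        assert det.found and 40 <= det.truncation <= 50

    def test_series_shorter_than_required_vectors(self, rng):
        assert DETECTORS["euclidean"](10 + rng.normal(0, 1, 25)).found is False

    def test_noisy_steady_series_detected_at_zero(self, rng):
        x = 10 + rng.normal(0, 0.1, 200)
        det = DETECTORS["euclidean"](x)
        assert det.found and det.truncation == 0


class TestGoodnessOfFit:
    def test_step_detected_within_one_batch(self):
        det = DETECTORS["gof"](STEP)
        assert det.found and 50 <= det.truncation <= 75

    def test_insufficient_batches(self, rng):
        assert DETECTORS["gof"](10 + rng.normal(0, 1, 30), EstimatorParams(gof_batch=25)).found is False


class TestBalancingMean:
    def test_alternating_series_balances_at_zero(self):
        det = DETECTORS["balancing"](ALTERNATING)
        assert det.found and det.truncation == 0

    def test_monotone_ramp_with_zero_tolerance(self):
        det = DETECTORS["balancing"](RAMP, EstimatorParams(balancing_delta=1e-9))
        assert det.found and det.truncation == 0  # 50 above, 50 below

    def test_matches_exhaustive_scan(self):
        x = STEP
        delta = 0.02
        expected = None
        for d in range(0, len(x) // 2 + 1):
            s = x[d:]
            m = s.mean()
            if abs((s > m).sum() - (s < m).sum()) <= delta * len(s):
                expected = d
                break
        det = DETECTORS["balancing"](x)
        assert det.found and det.truncation == expected == 50


class TestRunningMean:
    def test_step_matches_direct_scan(self):
        params = EstimatorParams(running_window=25, running_eps=0.01)
        m = np.cumsum(STEP) / np.arange(1, len(STEP) + 1)
        inc = np.abs(np.diff(m))
        expected = None
        for i in range(25, len(STEP) + 1):
            lo = max(2, i - 25 + 1)
            window = inc[lo - 2 : i - 1]
            if window.size and window.max() / (abs(m[i - 1]) + 1e-12) <= 0.01:
                expected = i - 25
                break
        det = DETECTORS["running_mean"](STEP, params)
        assert det.found and det.truncation == expected

    def test_too_short(self, rng):
        assert DETECTORS["running_mean"](10 + rng.normal(0, 1, 25)).found is False


class TestBatchMean:
    def test_step_detected_at_step_on_scan_grid(self):
        det = DETECTORS["batch_mean"](STEP)
        assert det.found and 25 <= det.truncation <= 75

    def test_small_series_unreachable(self):
        assert DETECTORS["batch_mean"](np.linspace(0, 1, 15)).found is False


class TestCrossingMean:
    def test_alternating_counts_by_direct_scan(self):
        det = DETECTORS["crossing"](ALTERNATING, EstimatorParams(crossing_count=25))
        # independent scan: running mean, signs with zero-inheritance
        m = np.cumsum(ALTERNATING) / np.arange(1, 101)
        s_prev, crosses, expected = 0.0, 0, None
        for i, v in enumerate(np.sign(ALTERNATING - m)):
            v = s_prev if v == 0 else v
            if s_prev != 0 and v != 0 and v != s_prev:
                crosses += 1
                if crosses == 25:
                    expected = i
                    break
            s_prev = v
        assert det.found and det.truncation == expected

    def test_monotone_ramp_never_crosses_enough(self):
        assert DETECTORS["crossing"](RAMP).found is False

    def test_single_observation(self):
        assert DETECTORS["crossing"](np.array([1.0])).found is False


class TestStopCrossingMean:
    def test_constant_series_no_crosses(self):
        det = DETECTORS["stop_crossing"](CONST100, EstimatorParams(stop_crossing_len=50))
        assert det.found and det.truncation == 0

    def test_alternating_always_crossing(self):
        assert DETECTORS["stop_crossing"](ALTERNATING).found is False

    def test_step_truncates_at_last_cross(self):
        det = DETECTORS["stop_crossing"](STEP)
        if det.found:
            # no crosses in the trailing 50 observations
            x = STEP[det.truncation:]
            assert det.truncation <= len(STEP) - 50


class TestSchruben:
    def test_step_detected_on_scan_grid_after_step(self):
        det = DETECTORS["schruben"](STEP)
        assert det.found and det.truncation in (60, 80)  # 50 rounded up to the 10% grid

    def test_white_noise_accepted_at_zero_at_nominal_rate(self):
        gen = np.random.default_rng(55)
        hits = 0
        for _ in range(200):
            det = DETECTORS["schruben"](gen.normal(10, 1, 1000))
            hits += det.found and det.truncation == 0
        assert 0.90 <= hits / 200 <= 1.0  # ~1 - alpha with alpha = 0.05


class TestMovingWindow:
    def test_step_matches_direct_scan(self):
        params = EstimatorParams(window_len=20, window_run=5, window_theta=0.05)
        x = STEP
        wmeans = np.convolve(x, np.ones(20) / 20, mode="valid")
        expected = None
        for j in range(4, len(wmeans)):
            run = wmeans[j - 4 : j + 1]
            if run.std(ddof=1) / (x.max() - x.min()) <= 0.05:
                expected = j - 4
                break
        det = DETECTORS["moving_window"](x, params)
        assert det.found and det.truncation == expected

    def test_too_short(self, rng):
        assert DETECTORS["moving_window"](10 + rng.normal(0, 1, 104)).found is False


class TestEstimateMean:
    @pytest.mark.parametrize(
        "series,d,expected",
        [(CONST100, 0, 10.0), (STEP, 50, 10.0), ([1, 2, 3, 4], 2, 3.5)],
    )
    def test_examples(self, series, d, expected):
        assert estimate_mean(as_series(series), d) == pytest.approx(expected)

    def test_matches_naive_sum(self, rng):
        x = rng.normal(5, 2, 500)
        for d in (0, 17, 499):
            naive = sum(x[d:]) / (500 - d)
            assert estimate_mean(x, d) == pytest.approx(naive, rel=1e-12)

    def test_empty_suffix_is_an_error(self):
        with pytest.raises(ValueError, match="empty suffix"):
            estimate_mean(CONST100, 100)


class TestSolverStep:
    def test_full_step_series_detected(self):
        p = IteratedProblem(initial=STEP)
        state = solver_step("mser", p, SolverState())
        assert state.request.more_data is False
        assert state.result == 10.0

    def test_short_series_requests_more(self):
        p = IteratedProblem(initial=SHORT5)
        state = solver_step("mser", p, SolverState())
        assert state.request.more_data is True
        assert state.result is UNDEFINED

    @pytest.mark.parametrize("estimator_id", ESTIMATOR_IDS)
    def test_empty_series_requests(self, estimator_id):
        p = IteratedProblem(initial=np.empty(0))
        assert solver_step(estimator_id, p, SolverState()).request.more_data

    def test_unknown_estimator_lists_registry(self):
        with pytest.raises(KeyError, match="mser"):
            solver_step("nope", IteratedProblem(initial=CONST100), SolverState())


class TestNoiselessRecovery:
    @pytest.mark.parametrize("bias_fraction", [0.1, 0.25, 0.4])
    @pytest.mark.parametrize("estimator_id", ["mser", "batch_mean"])
    def test_truncation_within_one_batch_of_warmup(self, bias_fraction, estimator_id):
        labeled = generate_series(
            GeneratorSpec(
                n=1000, bias_fraction=bias_fraction, trend="constant", shape="line",
                noise_low=0.0, noise_high=0.0, seed=3,
            )
        )
        det = DETECTORS[estimator_id](labeled.values)
        assert det.found
        assert abs(det.truncation - labeled.warmup_length) <= 25
        assert estimate_mean(labeled.values, det.truncation) == labeled.true_mean
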