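import itertools

import numpy as np
import pytest

from peasta.calibration import (DetectionThreshold, DilutionSeries, FailureMode,
                                call_detection, classify_probe_reliability,
                                detection_threshold, limit_of_detection,
                                select_linear_range, series_from_delta_ct)
from peasta.preprocess import dilution_delta_ct
from peasta.simulate import DilutionGenParams, generate_dilution_series


def oracle_best_window(quantities, means, cost, min_window=3):
    """Independent brute force: numpy polyfit over every contiguous window.

    Deliberately coded apart from the implementation (polyfit + manual R²
    instead of linregress) so the two routes can disagree.
    """
    logq = np.log2(np.asarray(quantities, dtype=float))
    means = np.asarray(means, dtype=float)
    n = len(means)
    best = None
    for lo, hi in itertools.combinations(range(n + 1), 2):
        hi -= 1
        if hi - lo + 1 < min_window:
            continue
        x, y = logq[lo:hi + 1], means[lo:hi + 1]
        if np.ptp(y) == 0 or np.ptp(x) == 0:
            r2 = 0.0
        else:
            coef = np.polyfit(x, y, 1)
            resid = y - np.polyval(coef, x)
            r2 = 1 - (resid ** 2).sum() / ((y - y.mean()) ** 2).sum()
        score = r2 - cost * (n - (hi - lo + 1))
        key = (score, hi - lo + 1, -lo)
        if best is None or key > best[0]:
            best = (key, lo, hi)
    return best[1], best[2], best[0][0]


def _series(means, n_rep=4, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    reps = np.array(means)[:, None] + rng.normal(0, noise, (len(means), n_rep))
    return DilutionSeries("T_P", 2.0 ** np.arange(1, len(means) + 1), reps)


class TestDetectionThreshold:
    def test_known_quantile(self):
        # z(0.99) = 2.3263; threshold = 2.3263 * 0.5
        thr = detection_threshold(0.5, alpha=0.01)
        assert thr.threshold_dct == pytest.approx(1.1632, abs=1e-3)

    def test_zero_sd_threshold_zero(self):
        thr = detection_threshold(0.0, alpha=0.01)
        assert thr.threshold_dct == 0.0
        assert call_detection(0.001, thr)

    def test_alpha_half_gives_zero(self):
        assert detection_threshold(1.0, alpha=0.5).threshold_dct == 0.0

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            detection_threshold(0.5, alpha=0.0)

    def test_monotone_in_sd_and_alpha(self):
        sds = np.linspace(0.1, 2.0, 8)
        thr = [detection_threshold(s, 0.01).threshold_dct for s in sds]
        assert all(b > a for a, b in zip(thr, thr[1:]))
        alphas = (0.001, 0.01, 0.05, 0.2)
        thr = [detection_threshold(1.0, a).threshold_dct for a in alphas]
        assert all(b < a for a, b in zip(thr, thr[1:]))

    def test_boundary_is_strict(self):
        thr = detection_threshold(0.5, alpha=0.01)
        assert not call_detection(thr.threshold_dct, thr)     # exactly at -> not detected
        assert not call_detection(0.0, thr)
        assert call_detection(1.5, thr)


class TestSelectLinearRange:
    def test_drops_the_broken_tail(self):
        # last level collapses to 0: the 5-level linear prefix wins
        fit = select_linear_range(_series([1, 2, 3, 4, 5, 0]), range_cost=0.03)
        assert (fit.lo_index, fit.hi_index) == (0, 4)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.score == pytest.approx(1.0 - 0.03)

    def test_perfect_series_keeps_full_window(self):
        fit = select_linear_range(_series(list(range(8))), range_cost=0.03)
        assert (fit.lo_index, fit.hi_index) == (0, 7)
        assert fit.n_removed == 0 and fit.r2 == pytest.approx(1.0)

    def test_flat_window_r2_defined_zero(self):
        fit = select_linear_range(_series([2, 2, 2, 2]), range_cost=0.03)
        assert fit.r2 == 0.0 and fit.slope == 0.0

    def test_override_pins_window(self):
        fit = select_linear_range(_series([1, 2, 3, 4, 5, 0]), override=(1, 3))
        assert (fit.lo_index, fit.hi_index) == (1, 3)

    def test_agrees_with_independent_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(4, 10)
            kind = rng.integers(3)
            if kind == 0:
                means = rng.normal(3, 2, n)
            elif kind == 1:   # linear with a broken flank
                means = np.arange(n) * rng.uniform(0.5, 1.5)
                k = rng.integers(0, n // 2 + 1)
                if k:
                    means[-k:] = rng.normal(0, 0.3, k)
            else:
                means = np.maximum(rng.normal(2, 1, n), 0)
            s = _series(list(means))
            fit = select_linear_range(s, range_cost=0.03)
            lo, hi, score = oracle_best_window(s.quantities, s.level_means, 0.03)
            assert (fit.lo_index, fit.hi_index) == (lo, hi)
            assert fit.score == pytest.approx(score, abs=1e-9)

    def test_recovers_true_window_at_low_noise(self):
        # series with a known linear window and a steep hook above it (mean
        # dCt [0,2,4,6,8,10,3,0]): recovery in >= 95% of 200 seeded replicates.
        # A gentle flank would not be recovered: the 0.03-per-point cost only
        # pays off when excluded levels badly break linearity.
        hits = 0
        for seed in range(200):
            params = DilutionGenParams(
                quantities=tuple(2.0 ** np.arange(8)), slope=2.0, intercept=0.0,
                linear_lo=0, linear_hi=5, noise_sd=0.1, hook=True,
                hook_decline_factor=3.5)
            ct, _ = generate_dilution_series(params, seed=seed)
            series = series_from_delta_ct(dilution_delta_ct(ct), "TARGET_P")
            fit = select_linear_range(series, range_cost=0.03)
            hits += (fit.lo_index, fit.hi_index) == (0, 5)
        assert hits >= 190


class TestLimitOfDetection:
    def _series_with_counts(self, counts, thr=1.0, n_rep=8):
        reps = np.array([[thr + 1.0] * c + [0.0] * (n_rep - c) for c in counts])
        return DilutionSeries("T_P", np.array([12.5, 25.0, 50.0, 100.0]), reps)

    def test_first_level_meeting_seven_of_eight(self):
        # ascending quantities [12.5, 25, 50, 100] detect [5, 7, 8, 8] replicates
        s = self._series_with_counts([5, 7, 8, 8])
        thr = DetectionThreshold("T_P", 1.0, 0.01)
        assert limit_of_detection(s, thr).lod_quantity == 25.0

    def test_no_level_qualifies(self):
        s = self._series_with_counts([5, 6, 6, 5])
        thr = DetectionThreshold("T_P", 1.0, 0.01)
        assert limit_of_detection(s, thr).lod_quantity is None

    def test_all_levels_pass_gives_smallest(self):
        s = self._series_with_counts([8, 8, 8, 8])
        thr = DetectionThreshold("T_P", 1.0, 0.01)
        assert limit_of_detection(s, thr).lod_quantity == 12.5

    def test_lod_non_increasing_in_alpha(self):
        params = DilutionGenParams(quantities=tuple(2.0 ** np.arange(-3, 5)),
                                   slope=1.0, intercept=1.0, noise_sd=0.4)
        ct, _ = generate_dilution_series(params, seed=7)
        series = series_from_delta_ct(dilution_delta_ct(ct), "TARGET_P")
        lods = []
        for alpha in (0.001, 0.01, 0.05, 0.2):
            thr = detection_threshold(0.5, alpha, "TARGET_P")
            lod = limit_of_detection(series, thr).lod_quantity
            lods.append(np.inf if lod is None else lod)
        assert all(b <= a for a, b in zip(lods, lods[1:]))


class TestReliability:
    THR = DetectionThreshold("T_P", 0.8, 0.01)

    def _span_series(self, means):
        # quantities 0.04 .. 10.63 cell equivalents (doubling ladder)
        q = 0.04 * 2.0 ** np.arange(len(means))
        reps = np.tile(np.asarray(means, dtype=float)[:, None], (1, 4))
        return DilutionSeries("T_P", q, reps)

    def test_linear_detected_series_reliable(self):
        s = self._span_series(np.linspace(1, 9, 9))
        fit = select_linear_range(s)
        call = classify_probe_reliability(fit, s, self.THR, 1.3)
        assert call.reliable and call.failure_mode is FailureMode.NONE

    def test_flat_zero_series_no_signal(self):
        s = self._span_series([0.0] * 9)
        fit = select_linear_range(s)
        call = classify_probe_reliability(fit, s, self.THR, 1.3)
        assert not call.reliable and call.failure_mode is FailureMode.NO_SIGNAL

    def test_saturated_series_flagged(self):
        s = self._span_series([5.0, 5.1, 5.0, 4.9, 5.0, 5.1, 5.0, 4.9, 5.0])
        fit = select_linear_range(s)
        call = classify_probe_reliability(fit, s, self.THR, 1.3)
        assert call.failure_mode is FailureMode.SATURATED

    def test_window_missing_single_cell_scale(self):
        # signal only at the top quantities; window excludes 1.3 equivalents
        means = [0, 0, 0, 0, 0, 0, 2, 4, 6]
        s = self._span_series(means)
        fit = select_linear_range(s)
        call = classify_probe_reliability(fit, s, self.THR, 1.3)
        assert not call.reliable
        assert call.failure_mode is FailureMode.RANGE_EXCLUDES_SINGLE_CELL
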