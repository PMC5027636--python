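import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from peasta.calibration import DetectionThreshold
from peasta.differential import (Direction, bh_adjust, de_between_groups,
                                 detection_proportion_test,
                                 expression_shift_test, fit_normal_model,
                                 fit_three_param_model, in_silico_gate_all)
from peasta.simulate import (BackgroundGenParams, TargetGenParams,
                             TimePointExpression, generate_single_cell_study)
from peasta.core import Analyte

from conftest import make_delta_table

THR0 = DetectionThreshold("", 0.0, 0.01)


def fisher_oracle(table):
    """Two-sided Fisher p by hypergeometric enumeration over fixed margins."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    pmf = lambda k: (math.comb(col1, k) * math.comb(n - col1, row1 - k)
                     / math.comb(n, row1))
    p_obs = pmf(a)
    return sum(pmf(k) for k in range(max(0, row1 - (n - col1)), min(row1, col1) + 1)
               if pmf(k) <= p_obs * (1 + 1e-9))


def mwu_oracle(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    u_from = lambda idx: ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
    u_obs = u_from(range(n1))
    mid = len(pooled) * n1 - n1 * (n1 + 1)  # 2 * mean U = n1*n2
    dev_obs = abs(2 * u_obs - n1 * (len(y)))
    total = hits = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(2 * u_from(idx) - n1 * len(y)) >= dev_obs - 1e-9:
            hits += 1
    return hits / total


def _two_group_table(det_a, det_b, levels_a=None, levels_b=None):
    """DeltaCtTable with one target; group A = first cells, group B = rest."""
    vals = []
    for det, levels in ((det_a, levels_a), (det_b, levels_b)):
        if levels is None:
            levels = [5.0] * sum(det)
        it = iter(levels)
        vals.extend(next(it) if d else 0.0 for d in det)
    dct = make_delta_table({"T_R": vals})
    ids = [w.well_id for w in dct.wells]
    return dct, ids[:len(det_a)], ids[len(det_a):]


class TestFisherDetection:
    def test_cross_table_exact_third(self):
        # [[2,0],[0,2]]: p = 2 / C(4,2) = 1/3
        dct, ga, gb = _two_group_table([True, True], [False, False])
        p, direction, skipped = detection_proportion_test(dct, "T_R", ga, gb, THR0,
                                                          force=True)
        assert p == pytest.approx(1 / 3)
        assert direction is Direction.DOWN

    def test_eligibility_rule(self):
        # 5 undetected in total -> not eligible -> skipped
        dct, ga, gb = _two_group_table([True] * 5 + [False] * 3,
                                       [True] * 5 + [False] * 2)
        _, _, skipped = detection_proportion_test(dct, "T_R", ga, gb, THR0)
        assert skipped
        # 11 undetected -> eligible
        dct, ga, gb = _two_group_table([True] * 2 + [False] * 6,
                                       [True] * 5 + [False] * 5)
        _, _, skipped = detection_proportion_test(dct, "T_R", ga, gb, THR0)
        assert not skipped

    def test_equal_proportions_large_n_p_near_one(self):
        dct, ga, gb = _two_group_table([True] * 30 + [False] * 30,
                                       [True] * 30 + [False] * 30)
        p, _, skipped = detection_proportion_test(dct, "T_R", ga, gb, THR0)
        assert not skipped and p == pytest.approx(1.0)

    def test_agrees_with_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            na, nb = rng.integers(2, 7), rng.integers(2, 7)
            det_a = list(rng.random(na) < rng.random())
            det_b = list(rng.random(nb) < rng.random())
            dct, ga, gb = _two_group_table(det_a, det_b)
            p, _, _ = detection_proportion_test(dct, "T_R", ga, gb, THR0, force=True)
            table = [[sum(det_a), na - sum(det_a)], [sum(det_b), nb - sum(det_b)]]
            assert p == pytest.approx(fisher_oracle(table), abs=1e-9)


class TestMannWhitneyShift:
    def test_separated_triples_exact_tenth(self):
        # {1,2,3} vs {4,5,6}: p = 2 / C(6,3) = 0.1
        dct, ga, gb = _two_group_table([True] * 3, [True] * 3,
                                       [1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        p, direction, _ = expression_shift_test(dct, "T_R", ga, gb, THR0, force=True)
        assert p == pytest.approx(0.1)
        assert direction is Direction.UP

    def test_identical_groups_p_one(self):
        dct, ga, gb = _two_group_table([True] * 8, [True] * 8,
                                       list(range(1, 9)), list(range(1, 9)))
        p, _, _ = expression_shift_test(dct, "T_R", ga, gb, THR0)
        assert p > 0.9

    def test_eligibility_rule(self):
        # 8 detected in total -> skipped
        dct, ga, gb = _two_group_table([True] * 4 + [False] * 4,
                                       [True] * 4 + [False] * 4)
        _, _, skipped = expression_shift_test(dct, "T_R", ga, gb, THR0)
        assert skipped

    def test_agrees_with_enumeration_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(40):
            na, nb = rng.integers(3, 7), rng.integers(3, 7)
            # distinct values: exact-null enumeration assumes no ties
            vals = rng.choice(np.arange(1, 40), size=na + nb, replace=False) / 2
            xa, xb = vals[:na], vals[na:]
            dct, ga, gb = _two_group_table([True] * na, [True] * nb,
                                           list(xa), list(xb))
            p, _, _ = expression_shift_test(dct, "T_R", ga, gb, THR0, force=True)
            assert p == pytest.approx(mwu_oracle(xa, xb), abs=1e-9)


class TestBhAdjust:
    def test_textbook_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_equal(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_properties(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)          # adjusted >= raw
        assert np.all(adj <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)          # order-preserving
        # re-adjusting can only push values up, never reorder them
        re_adj = bh_adjust(adj)
        assert np.all(re_adj >= adj - 1e-12)
        assert np.all(np.diff(re_adj[order]) >= -1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.001, 1), st.integers(1, 30))
    def test_fixed_points(self, p, m):
        # tied vectors are fixed points of the step-up adjustment (the general
        # operator is NOT idempotent: bh([1, .25]) = [1, .5], bh of that = [1, 1])
        tied = [p] * m
        assert np.allclose(bh_adjust(tied), tied)
        assert np.allclose(bh_adjust(bh_adjust(tied)), tied)


class TestModelFits:
    def test_normal_recovery(self):
        hits = 0
        for seed in range(40):
            vals = np.random.default_rng(seed).normal(10, 1, 2000)
            fit = fit_normal_model(vals)
            assert abs(fit.mu - 10) < 0.1
            hits += fit.gof_p > 0.01
        assert hits >= 38

    def test_constant_vector_degenerate(self):
        assert fit_normal_model([5.0] * 20).degenerate

    def test_bimodal_data_fails_gof(self):
        vals = np.r_[np.zeros(100), np.full(100, 10.0)]
        assert fit_normal_model(vals).gof_p < 0.01

    def test_three_param_recovery(self):
        rng = np.random.default_rng(0)
        vals = np.where(rng.random(2000) < 0.6, rng.normal(10, 1, 2000), 0.0)
        fit = fit_three_param_model(vals, THR0)
        assert abs(fit.pi - 0.6) < 0.03
        assert abs(fit.mu - 10) < 0.1

    def test_pi_estimator_unbiased(self):
        # bias of pi-hat below 0.01 at n=2000 over 100 seeds
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            vals = np.where(rng.random(2000) < 0.6, rng.normal(10, 1, 2000), 0.0)
            errs.append(fit_three_param_model(vals, THR0).pi - 0.6)
        assert abs(np.mean(errs)) < 0.01

    def test_all_detected_reduces_to_normal(self):
        vals = np.random.default_rng(1).normal(10, 1, 500)
        three = fit_three_param_model(vals, THR0)
        two = fit_normal_model(vals)
        assert three.pi == 1.0
        assert three.mu == pytest.approx(two.mu)
        assert three.sigma == pytest.approx(two.sigma)

    def test_all_undetected(self):
        fit = fit_three_param_model([0.0] * 20, THR0)
        assert fit.pi == 0.0 and fit.degenerate


class TestGatingScreen:
    def _thresholds(self, ids):
        return {tid: THR0 for tid in ids}

    def test_combinatorics_three_targets(self):
        rng = np.random.default_rng(2)
        dct = make_delta_table({f"T{i}_R": list(rng.integers(0, 5, 30).astype(float))
                                for i in range(3)})
        res = in_silico_gate_all(dct, self._thresholds(dct.target_ids))
        by_gate = {}
        for r in res:
            by_gate.setdefault(r.gate_target, set()).add(r.response_target)
        assert all(len(v) == 2 for v in by_gate.values())
        assert len(by_gate) == 3
        # both test kinds attempted per (gate, response)
        assert len(res) == 3 * 2 * 2

    def test_coupled_detection_found(self):
        # target B detected exactly when A is: Fisher must flag it at n=200
        rng = np.random.default_rng(3)
        det = rng.random(200) < 0.5
        a = np.where(det, rng.normal(8, 1, 200), 0.0).clip(min=0)
        b = np.where(det, rng.normal(6, 1, 200), 0.0).clip(min=0)
        c = np.where(rng.random(200) < 0.5, rng.normal(7, 1, 200), 0.0).clip(min=0)
        dct = make_delta_table({"A_R": list(a), "B_R": list(b), "C_R": list(c)})
        res = in_silico_gate_all(dct, self._thresholds(dct.target_ids))
        hit = [r for r in res if r.gate_target == "A_R" and r.response_target == "B_R"
               and r.test == "FISHER_DETECTION"][0]
        assert hit.p_adjusted < 0.01
        null = [r for r in res if r.gate_target == "A_R" and r.response_target == "C_R"
                and r.test == "FISHER_DETECTION"][0]
        assert null.p_adjusted > 0.05

    def test_fdr_under_global_null(self):
        # independent targets: average fraction of BH-significant calls <= ~alpha
        fracs = []
        for seed in range(15):
            rng = np.random.default_rng(100 + seed)
            dct = make_delta_table({
                f"T{i}_R": list(np.where(rng.random(80) < 0.5,
                                         rng.normal(8, 1, 80), 0.0).clip(min=0))
                for i in range(8)})
            res = in_silico_gate_all(dct, self._thresholds(dct.target_ids))
            run = [r for r in res if not r.skipped]
            fracs.append(np.mean([r.p_adjusted < 0.05 for r in run]))
        assert np.mean(fracs) <= 0.05 + 0.02

    def test_de_between_groups_detects_pi_shift(self):
        rng = np.random.default_rng(4)
        a = np.where(rng.random(100) < 0.1, rng.normal(8, 1, 100), 0.0).clip(min=0)
        b = np.where(rng.random(100) < 0.9, rng.normal(8, 1, 100), 0.0).clip(min=0)
        dct = make_delta_table({"T_R": list(a) + list(b)})
        ids = [w.well_id for w in dct.wells]
        res = de_between_groups(dct, ["T_R"], ids[:100], ids[100:],
                                self._thresholds(["T_R"]))
        fisher = [r for r in res if r.test == "FISHER_DETECTION"][0]
        assert fisher.p_adjusted < 1e-6
        assert fisher.direction is Direction.UP

    def test_de_between_groups_detects_level_shift(self):
        rng = np.random.default_rng(5)
        a = rng.normal(6, 1, 100).clip(min=0.1)
        b = rng.normal(9, 1, 100).clip(min=0.1)
        dct = make_delta_table({"T_R": list(a) + list(b)})
        ids = [w.well_id for w in dct.wells]
        res = de_between_groups(dct, ["T_R"], ids[:100], ids[100:],
                                self._thresholds(["T_R"]))
        mwu = [r for r in res if r.test == "MWU_LEVEL"][0]
        assert mwu.p_adjusted < 0.001
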