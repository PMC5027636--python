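import numpy as np
import pandas as pd
import pytest

from peasta import preprocess
from peasta.core import (Analyte, CtTable, SampleType, Target, WellMeta)
from peasta.simulate import (BackgroundGenParams, generate_dilution_series,
                             DilutionGenParams, generate_single_cell_study)

from conftest import coupled_pair_params, make_delta_table


def _ct_table(values, sample_types, analytes, time_points=None, quantities=None):
    """values: dict target_id -> list of Ct (np.nan = undetected)."""
    n = len(next(iter(values.values())))
    wells = []
    for i in range(n):
        st = SampleType(sample_types[i])
        wells.append(WellMeta(
            f"w{i:03d}", st,
            time_point_hr=None if time_points is None else time_points[i],
            n_cells_captured=1 if st is SampleType.CELL else 0,
            dilution_quantity=None if quantities is None else quantities[i]))
    targets = [Target(tid, Analyte(analytes[tid]), tid.rsplit("_", 1)[0])
               for tid in values]
    ct = pd.DataFrame(values, index=[w.well_id for w in wells], dtype=float)
    return CtTable(wells=wells, targets=targets, ct=ct)


class TestProteinBackground:
    def test_hand_computed_mean_and_sd(self):
        # zero-cell Cts {22, 23, sentinel, 25}: clipped to {22, 23, 24, 24}
        ct = _ct_table({"A_P": [22, 23, np.nan, 25]}, ["ZERO_CELL"] * 4,
                       {"A_P": "PROTEIN"})
        bg = preprocess.estimate_protein_background(ct)
        assert bg.mean_of("A_P") == pytest.approx(23.25)
        assert bg.sd_of("A_P") == pytest.approx(np.std([22, 23, 24, 24], ddof=1), abs=1e-9)
        assert bg.sd_of("A_P") == pytest.approx(0.957, abs=1e-3)

    def test_all_sentinel_clips_to_ceiling(self):
        ct = _ct_table({"A_P": [np.nan] * 4}, ["ZERO_CELL"] * 4, {"A_P": "PROTEIN"})
        bg = preprocess.estimate_protein_background(ct)
        assert bg.mean_of("A_P") == 24.0
        assert bg.sd_of("A_P") == 0.0

    def test_no_zero_cell_wells_directs_to_buffer(self):
        ct = _ct_table({"A_P": [20, 21]}, ["CELL", "CELL"], {"A_P": "PROTEIN"},
                       time_points=[0, 0])
        with pytest.raises(ValueError, match="lysis-buffer"):
            preprocess.estimate_protein_background(ct)


class TestBackgroundHomogeneity:
    def test_identical_groups_pool(self):
        ct = _ct_table({"A_P": [22, 23, 22, 23]}, ["ZERO_CELL"] * 4,
                       {"A_P": "PROTEIN"}, time_points=[0, 0, 24, 24])
        verdicts = preprocess.check_background_homogeneity(ct)
        assert verdicts.at["A_P", "verdict"] == "pool"

    def test_separated_zero_variance_groups_stratify(self):
        ct = _ct_table({"A_P": [20, 20, 20, 23, 23, 23]}, ["ZERO_CELL"] * 6,
                       {"A_P": "PROTEIN"}, time_points=[0, 0, 0, 24, 24, 24])
        verdicts = preprocess.check_background_homogeneity(ct)
        assert verdicts.at["A_P", "verdict"] == "stratify"

    def test_null_p_values_roughly_uniform(self):
        # groups drawn from the same normal should rarely trigger stratify
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(200):
            vals = list(rng.normal(23, 0.5, 20))
            ct = _ct_table({"A_P": vals}, ["ZERO_CELL"] * 20, {"A_P": "PROTEIN"},
                           time_points=[0] * 10 + [24] * 10)
            pvals.append(preprocess.check_background_homogeneity(ct).at["A_P", "min_p"])
        pvals = np.array(pvals)
        # mean of a uniform is 0.5; allow generous Monte-Carlo slack
        assert abs(pvals.mean() - 0.5) < 0.1
        assert (pvals < 0.05).mean() < 0.12


class TestDeltaCt:
    def test_rna_rules(self):
        ct = _ct_table({"A_R": [20, 25, np.nan]}, ["CELL"] * 3, {"A_R": "RNA"},
                       time_points=[0] * 3)
        dct = preprocess.rna_delta_ct(ct)
        assert list(dct.dct["A_R"]) == [4.0, 0.0, 0.0]

    def test_protein_rules(self):
        zc = ["ZERO_CELL"] * 4 + ["CELL"] * 3
        ct = _ct_table({"A_P": [22, 23, np.nan, 25, 20, np.nan, 23.25]}, zc,
                       {"A_P": "PROTEIN"}, time_points=[0] * 7)
        bg = preprocess.estimate_protein_background(ct)       # bg_mean = 23.25
        dct = preprocess.protein_delta_ct(ct, bg)
        cells = dct.dct["A_P"].iloc[4:]
        # Ct 20 -> 3.25; sentinel -> clipped 24 -> negative -> 0; boundary -> 0
        assert list(cells) == [3.25, 0.0, 0.0]

    def test_protein_missing_background_names_target(self):
        ct = _ct_table({"B_P": [20]}, ["CELL"], {"B_P": "PROTEIN"}, time_points=[0])
        bg = preprocess.BackgroundModel(
            stats=pd.DataFrame({"bg_mean": [23.0], "bg_sd": [0.5], "n_wells": [4]},
                               index=["A_P"]))
        with pytest.raises(ValueError, match="B_P"):
            preprocess.protein_delta_ct(ct, bg)

    def test_dilution_reference_rules(self):
        st = ["DILUTION"] * 2 + ["LYSIS_BUFFER"] * 2
        q = [1.0, 1.0, None, None]
        # A_P detected in buffer (mean 23); B_P undetected there (fallback 24)
        ct = _ct_table({"A_P": [20, 24, 23, 23], "B_P": [21, np.nan, np.nan, np.nan]},
                       st, {"A_P": "PROTEIN", "B_P": "PROTEIN"}, quantities=q)
        dct = preprocess.dilution_delta_ct(ct)
        assert list(dct.dct["A_P"]) == [3.0, 0.0]     # above reference -> 0
        assert list(dct.dct["B_P"]) == [3.0, 0.0]     # 24 - 21; sentinel -> 0

    def test_dilution_requires_buffer_wells(self):
        ct = _ct_table({"A_P": [20]}, ["DILUTION"], {"A_P": "PROTEIN"},
                       quantities=[1.0])
        with pytest.raises(ValueError, match="lysis-buffer"):
            preprocess.dilution_delta_ct(ct)


class TestCulling:
    def _dct_with_counts(self, counts, n_rna=40):
        """Each cell detects its first `count` RNAs."""
        values = {f"G{j:02d}_R": [(1.0 if j < c else 0.0) for c in counts]
                  for j in range(n_rna)}
        return make_delta_table(values)

    def test_strict_boundary_at_min_detected(self):
        dct = self._dct_with_counts([35, 34, 40])
        kept, report = preprocess.cull_cells(dct, dct.target_ids, min_detected=35)
        assert report.per_cell["culled"].tolist() == [False, True, False]
        assert len(kept.wells) == 2

    def test_monotone_in_min_detected(self):
        rng = np.random.default_rng(1)
        dct = self._dct_with_counts(list(rng.integers(0, 41, 30)))
        kept_ids = None
        for m in (30, 20, 10, 1):
            kept, _ = preprocess.cull_cells(dct, dct.target_ids, min_detected=m)
            ids = {w.well_id for w in kept.wells}
            if kept_ids is not None:
                assert kept_ids <= ids        # lowering the bar never drops a cell
            kept_ids = ids

    def test_all_culled_raises_with_summary(self):
        dct = self._dct_with_counts([1, 2, 3])
        with pytest.raises(ValueError, match="median"):
            preprocess.cull_cells(dct, dct.target_ids, min_detected=35)

    def test_report_medians(self):
        dct = self._dct_with_counts([10, 36, 38, 40])
        _, report = preprocess.cull_cells(dct, dct.target_ids, min_detected=35)
        assert report.median_before == pytest.approx(37.0)
        assert report.median_after == pytest.approx(38.0)


class TestNormalizationInvariants:
    def test_delta_ct_nonnegative_and_zero_means_undetected(self, small_study, small_dct):
        ct, truth = small_study
        dct, _ = small_dct
        assert (dct.dct.to_numpy() >= 0).all()
        # RNA: zero iff the raw reaction was undetected or past the ceiling
        rna_cols = [t.target_id for t in dct.targets_of(Analyte.RNA)]
        cells = [w.well_id for w in dct.wells]
        raw = ct.ct.loc[cells, rna_cols]
        zero = dct.dct[rna_cols] == 0
        undetected_or_late = raw.isna() | (raw >= 24.0)
        assert (zero == undetected_or_late).all().all()

    def test_zero_cell_wells_have_near_zero_protein_dct(self):
        # clipping at 0 biases background wells' mean dCt upward by < 0.5 sd
        params, bg = coupled_pair_params(0.0)
        bg = BackgroundGenParams(bg_mean_ct=bg.bg_mean_ct, bg_sd_ct=bg.bg_sd_ct,
                                 n_zero_cell_wells={0.0: 400})
        ct, _ = generate_single_cell_study(params, {0.0: 5}, bg, seed=0)
        bgm = preprocess.estimate_protein_background(ct)
        dct = preprocess.protein_delta_ct(ct, bgm)
        zwells = [w.well_id for w in ct.wells_of(SampleType.ZERO_CELL)]
        mean_dct = dct.dct.loc[zwells, "X_P"].mean()
        assert 0 <= mean_dct < 0.5 * bgm.sd_of("X_P")
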