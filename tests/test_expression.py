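"""Comparative-CT arithmetic, normalization stages, ANOVA/Tukey, masking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mosaiq.expression import (
    ComparativeCt,
    delta_ct,
    double_normalize,
    fold_change,
    fold_change_table,
    one_way_anova,
    significance_table,
    tukey_hsd,
)
from mosaiq.synthetic import CtDesign, generate_ct_table


def _ct_rows(entries):
    return pd.DataFrame(entries,
                        columns=["sample_id", "group", "day", "gene", "ct"])


class TestDeltaCt:
    def test_subtraction_against_housekeeping(self):
        table = _ct_rows([("s1", "g", 1, "geneX", 25.0),
                          ("s1", "g", 1, "18S", 10.0)])
        out = delta_ct(table)
        assert out.loc[0, "delta_ct"] == 15.0

    def test_technical_replicates_averaged_first(self):
        table = _ct_rows([("s1", "g", 1, "geneX", 24.9),
                          ("s1", "g", 1, "geneX", 25.1),
                          ("s1", "g", 1, "18S", 10.0)])
        out = delta_ct(table)
        assert out.loc[0, "delta_ct"] == pytest.approx(15.0)

    def test_sample_without_housekeeping_excluded(self, caplog):
        table = _ct_rows([("s1", "g", 1, "geneX", 25.0),
                          ("s1", "g", 1, "18S", 10.0),
                          ("s2", "g", 1, "geneX", 24.0)])
        with caplog.at_level("WARNING"):
            out = delta_ct(table)
        assert list(out["sample_id"]) == ["s1"]
        assert "s2" in caplog.text

    def test_absent_housekeeping_gene_rejected(self):
        with pytest.raises(ValueError, match="housekeeping"):
            delta_ct(_ct_rows([("s1", "g", 1, "geneX", 25.0)]))


class TestFoldChange:
    @pytest.mark.parametrize("sample,ref,expected",
                             [(15.0, 15.0, 1.0), (14.0, 15.0, 2.0),
                              (17.0, 15.0, 0.25)])
    def test_two_to_the_minus_ddct(self, sample, ref, expected):
        assert fold_change(sample, ref) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(min_value=-30, max_value=30))
    def test_self_reference_identity(self, dct):
        assert fold_change(dct, dct) == 1.0

    def test_table_uses_day_matched_reference_mean(self):
        dct = pd.DataFrame({
            "sample_id": ["r1", "r2", "s1"],
            "group": ["pure_uninduced", "pure_uninduced", "kd"],
            "day": [1, 1, 1],
            "gene": ["geneX"] * 3,
            "delta_ct": [15.5, 14.5, 13.0],
        })
        out = fold_change_table(dct)
        s1 = out[out.sample_id == "s1"]["fold_change"].iloc[0]
        assert s1 == pytest.approx(2.0 ** 2.0)  # vs reference mean 15.0


class TestDoubleNormalize:
    def _fc(self, sample_fc, pure_fc, mixed_fc):
        rows = []
        for group, fc in (("mixed_kd", sample_fc),
                          ("pure_uninduced", pure_fc),
                          ("mixed_uninduced", mixed_fc)):
            rows.append({"sample_id": f"{group}_b1", "group": group, "day": 1,
                         "gene": "geneX", "delta_ct": 0.0, "fold_change": fc,
                         "normalization_stage": "vs_reference"})
        return pd.DataFrame(rows)

    def test_sample_equal_to_both_controls_lands_on_one(self):
        out = double_normalize(self._fc(2.0, 2.0, 2.0))
        final = out[(out.normalization_stage == "vs_mixed_uninduced")
                    & (out.group == "mixed_kd")]["fold_change"]
        assert final.iloc[0] == pytest.approx(1.0)

    def test_worked_example_four_two_one(self):
        # sample 4x, pure control 2x, mixed control (post stage 1) 1x -> 2.0
        out = double_normalize(self._fc(4.0, 2.0, 2.0))
        final = out[(out.normalization_stage == "vs_mixed_uninduced")
                    & (out.group == "mixed_kd")]["fold_change"]
        assert final.iloc[0] == pytest.approx(2.0)

    def test_nonpositive_fold_change_rejected(self):
        bad = self._fc(4.0, 0.0, 1.0)
        with pytest.raises(ValueError, match="fold changes"):
            double_normalize(bad)

    def test_both_stages_present_in_output(self):
        out = double_normalize(self._fc(4.0, 2.0, 2.0))
        assert set(out["normalization_stage"]) == {
            "vs_reference", "vs_pure_uninduced", "vs_mixed_uninduced"}


class TestAnova:
    def test_hand_computed_f_statistic(self):
        res = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert res.F == pytest.approx(3.0)
        assert (res.df_between, res.df_within) == (2, 6)

    def test_identical_groups_null(self):
        res = one_way_anova([[1, 2, 3]] * 3)
        assert res.F == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_within_variance_distinct_means_degenerate(self):
        res = one_way_anova([[1, 1], [2, 2], [3, 3]])
        assert res.F == np.inf
        assert res.p_value == 0.0

    def test_single_group_directed_to_t_test(self):
        with pytest.raises(ValueError, match="t-test"):
            one_way_anova([[1, 2, 3]])


class TestTukey:
    def test_identical_groups_all_p_near_one(self):
        out = tukey_hsd([[1.0, 2.0, 3.0]] * 3)
        assert np.allclose(out["p_adj"], 1.0, atol=1e-9)

    def test_adjusted_p_at_least_pooled_unadjusted_p(self):
        """Tukey never undercuts the Fisher-LSD pairwise t on random tables."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            groups = [rng.normal(rng.uniform(-1, 1), 1.0, size=5)
                      for _ in range(4)]
            k, N = 4, 20
            msw = sum((len(g) - 1) * np.var(g, ddof=1)
                      for g in groups) / (N - k)
            out = tukey_hsd(groups)
            labels = [f"group{i}" for i in range(4)]
            for r in out.itertuples():
                i, j = labels.index(r.group_a), labels.index(r.group_b)
                se = np.sqrt(msw * (2 / 5))
                t = abs(groups[i].mean() - groups[j].mean()) / se
                p_lsd = 2 * stats.t.sf(t, N - k)
                assert r.p_adj >= p_lsd - 1e-12

    def test_planted_shift_flags_exactly_its_contrasts(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(20):
            groups = [rng.normal(0, 1, 10), rng.normal(0, 1, 10),
                      rng.normal(5, 1, 10)]
            out = tukey_hsd(groups, labels=["a", "b", "c"])
            by = {frozenset((r.group_a, r.group_b)): r.significant
                  for r in out.itertuples()}
            if (by[frozenset(("a", "c"))] and by[frozenset(("b", "c"))]
                    and not by[frozenset(("a", "b"))]):
                hits += 1
        assert hits >= 19


class TestSignificanceTable:
    def test_alpha_one_masks_nothing(self):
        table = generate_ct_table(CtDesign(seed=0))
        sig = significance_table(delta_ct(table), alpha=1.0)
        assert not sig["masked"].any()

    def test_lowering_alpha_never_unmasks(self):
        table = generate_ct_table(CtDesign(seed=1))
        dct = delta_ct(table)
        loose = significance_table(dct, alpha=0.10).set_index(
            ["gene", "day", "contrast"])
        strict = significance_table(dct, alpha=0.01).set_index(
            ["gene", "day", "contrast"])
        for idx in loose.index:
            if loose.loc[idx, "masked"]:
                assert strict.loc[idx, "masked"]

    def test_incomplete_design_skipped(self, caplog):
        table = generate_ct_table(CtDesign(seed=2))
        table = table[table.group != "mixed_kd"]
        with caplog.at_level("WARNING"):
            sig = significance_table(delta_ct(table))
        assert sig.empty
        assert "incomplete design" in caplog.text

    def test_planted_kd_effect_flagged_mixing_not(self):
        eff = {("geneX", "pure_kd"): -2.5, ("geneX", "mixed_kd"): -2.5}
        table = generate_ct_table(CtDesign(effect=eff, seed=3))
        sig = significance_table(delta_ct(table)).set_index(
            ["gene", "contrast"])
        assert sig.loc[("geneX", "kd_effect"), "significant"].all()
        assert not sig.loc[("geneX", "mixing_effect"), "significant"].any()


class TestComparativeCtModel:
    def test_end_to_end_noise_free_fold_change(self):
        design = CtDesign(replicate_sd=0.0,
                          effect={("geneX", "pure_kd"): -1.0}, seed=0)
        results = ComparativeCt(generate_ct_table(design)).fit()
        fc = results.fold_changes
        kd = fc[(fc.gene == "geneX") & (fc.group == "pure_kd")]["fold_change"]
        assert np.allclose(kd, 2.0)

    def test_final_stage_and_summary(self):
        results = ComparativeCt(generate_ct_table(CtDesign(seed=4))).fit()
        final = results.final_fold_changes()
        assert set(final["normalization_stage"]) == {"vs_mixed_uninduced"}
        assert "Comparative-CT" in results.summary()
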