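import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aidmeth.reanalysis import (
    TwoGroupExpressionModel, UnimodalMarkerError, bimodal_split,
    correlation_screen, group_differential_expression,
)
from aidmeth.simulate import simulate_expression_cohort


@pytest.fixture
def bimodal_cohort():
    return simulate_expression_cohort(130, 100, (4.0, 8.0, 0.3), seed=12)


class TestBimodalSplit:
    def test_well_separated_mixture_recovers_group_sizes(self, bimodal_cohort):
        split = bimodal_split(bimodal_cohort, "AICDA")
        truth_high = set(bimodal_cohort.attrs["high_samples"])
        assert abs(len(split.high_samples) - len(truth_high)) <= 3
        assert 4.0 < split.threshold < 8.0

    def test_fixed_threshold_below_all_values(self, bimodal_cohort):
        split = bimodal_split(bimodal_cohort, "AICDA", method="fixed", fixed_threshold=-100.0)
        assert len(split.low_samples) == 0
        assert len(split.high_samples) == bimodal_cohort.shape[1]

    def test_threshold_shift_equivariance(self, bimodal_cohort):
        shifted = bimodal_cohort.copy()
        shifted.loc["AICDA"] = shifted.loc["AICDA"] + 2.5
        a = bimodal_split(bimodal_cohort, "AICDA")
        b = bimodal_split(shifted, "AICDA")
        assert b.threshold == pytest.approx(a.threshold + 2.5, abs=0.05)
        assert set(a.high_samples) == set(b.high_samples)

    def test_unimodal_marker_raises_with_advice(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(6, 1, size=(5, 60)),
                            index=["AICDA", "a", "b", "c", "d"],
                            columns=[f"S{i}" for i in range(60)])
        with pytest.raises(UnimodalMarkerError, match="fixed"):
            bimodal_split(expr, "AICDA")

    def test_split_partitions_all_samples(self, bimodal_cohort):
        split = bimodal_split(bimodal_cohort, "AICDA")
        assert set(split.low_samples) | set(split.high_samples) == set(bimodal_cohort.columns)
        marker = bimodal_cohort.loc["AICDA"]
        assert (marker[list(split.low_samples)] < split.threshold).all()
        assert (marker[list(split.high_samples)] >= split.threshold).all()


class TestGroupDifferentialExpression:
    def test_planted_effects_exactly_recovered(self):
        planted = {f"G{i:04d}": 1.0 for i in (5, 10, 15, 20, 25)}
        expr = simulate_expression_cohort(130, 100, (4.0, 8.0, 0.3), seed=12,
                                          planted_association=planted, noise_sd=0.3)
        split = bimodal_split(expr, "AICDA")
        genes = [f"G{i:04d}" for i in range(2, 47)]
        res = TwoGroupExpressionModel(expr, split, genes=genes).fit(fdr=0.05)
        assert sorted(res.significant_genes) == sorted(planted)
        assert "Significant at BH FDR<0.05: 5" in res.summary()

    def test_null_rarely_yields_significant_genes(self):
        hits = 0
        for seed in range(20):
            expr = simulate_expression_cohort(60, 50, (4.0, 8.0, 0.4), seed=100 + seed)
            split = bimodal_split(expr, "AICDA")
            genes = [g for g in expr.index if g != "AICDA"][:45]
            table = group_differential_expression(expr, split, genes=genes)
            hits += int(table["significant"].any())
        assert hits <= 3  # BH controls FDR; most null replicates are clean

    def test_d0_zero_equals_pooled_two_sample_t(self):
        from scipy import stats
        from aidmeth.mvp import ModeratedVariancePrior

        rng = np.random.default_rng(8)
        expr = pd.DataFrame(rng.normal(5, 1, size=(10, 20)),
                            index=[f"g{i}" for i in range(10)],
                            columns=[f"S{i}" for i in range(20)])
        expr.loc["g0"] = np.r_[np.zeros(10), np.ones(10)] + rng.normal(0, 0.2, 20)
        split = bimodal_split(expr, "g0", method="fixed", fixed_threshold=0.5)
        table = group_differential_expression(
            expr, split, prior=ModeratedVariancePrior(0.0, 1.0))
        lo, hi = list(split.low_samples), list(split.high_samples)
        for g in expr.index:
            t_ref, p_ref = stats.ttest_ind(expr.loc[g, hi], expr.loc[g, lo])
            assert table.loc[g, "t"] == pytest.approx(t_ref, abs=1e-10)
            assert table.loc[g, "p"] == pytest.approx(p_ref, abs=1e-10)

    def test_label_swap_flips_sign(self, bimodal_cohort):
        split = bimodal_split(bimodal_cohort, "AICDA")
        swapped = type(split)(split.marker_gene, split.threshold,
                              split.high_samples, split.low_samples)
        genes = [g for g in bimodal_cohort.index if g != "AICDA"][:20]
        a = group_differential_expression(bimodal_cohort, split, genes=genes)
        b = group_differential_expression(bimodal_cohort, swapped, genes=genes)
        assert np.allclose(a["log2_diff"], -b["log2_diff"])
        assert np.allclose(a["p"], b["p"], atol=1e-12)

    def test_fdr_extremes(self, bimodal_cohort):
        split = bimodal_split(bimodal_cohort, "AICDA")
        genes = [g for g in bimodal_cohort.index if g != "AICDA"][:20]
        all_sig = group_differential_expression(bimodal_cohort, split, genes=genes, fdr=1.0)
        assert all_sig["significant"].all()
        none_sig = group_differential_expression(bimodal_cohort, split, genes=genes, fdr=1e-12)
        assert not none_sig["significant"].any()

    def test_absent_gene_recorded_untested(self, bimodal_cohort):
        split = bimodal_split(bimodal_cohort, "AICDA")
        model = TwoGroupExpressionModel(bimodal_cohort, split,
                                        genes=["G0002", "NOT_A_GENE"])
        assert model.untested == ["NOT_A_GENE"]
        assert len(model.fit().table) == 1


class TestCorrelationScreen:
    def test_self_and_negated_marker_give_r2_one(self):
        rng = np.random.default_rng(9)
        m = rng.normal(5, 1, 30)
        expr = pd.DataFrame({f"S{i}": [m[i], m[i], -m[i]] for i in range(30)},
                            index=["AICDA", "copy", "neg"])
        table, (lo, hi) = correlation_screen(expr, "AICDA")
        assert table.loc["copy", "r2"] == pytest.approx(1.0, abs=1e-12)
        assert table.loc["neg", "r2"] == pytest.approx(1.0, abs=1e-12)
        assert hi == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_correlation(self):
        m = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        expr = pd.DataFrame([m, y], index=["AICDA", "g"],
                            columns=[f"S{i}" for i in range(6)])
        table, _ = correlation_screen(expr, "AICDA")
        r = np.corrcoef(m, y)[0, 1]
        assert table.loc["g", "r2"] == pytest.approx(r * r, abs=1e-12)

    def test_zero_variance_gene_is_missing(self):
        expr = pd.DataFrame([[1, 2, 3, 4], [5, 5, 5, 5]], dtype=float,
                            index=["AICDA", "flat"], columns=list("abcd"))
        table, _ = correlation_screen(expr, "AICDA")
        assert np.isnan(table.loc["flat", "r2"])

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(scale=st.floats(0.1, 10), shift=st.floats(-100, 100))
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(11)
        m = rng.normal(0, 1, 20)
        y = 0.5 * m + rng.normal(0, 1, 20)
        expr = pd.DataFrame([m, y], index=["AICDA", "g"],
                            columns=[f"S{i}" for i in range(20)])
        base, _ = correlation_screen(expr, "AICDA")
        expr2 = expr.copy()
        expr2.loc["g"] = scale * expr2.loc["g"] + shift
        scaled, _ = correlation_screen(expr2, "AICDA")
        assert scaled.loc["g", "r2"] == pytest.approx(base.loc["g", "r2"], abs=1e-9)
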