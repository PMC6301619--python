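import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import polygamma

from aidmeth.io import BetaMatrix, PairedDesign
from aidmeth.mvp import (
    ModeratedVariancePrior, PairedMethylationModel, _bh_adjust, call_mvps,
    estimate_prior, moderated_paired_test, paired_differences, summarize_global,
    trigamma_inverse,
)
from aidmeth.simulate import SimulationConfig, simulate_manifest, simulate_paired_betas
from conftest import make_manifest


def brute_force_bh(p):
    """BH by its definition: sorted p * m / rank with a running minimum."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


class TestPairedDifferences:
    def test_identical_columns_give_zero(self, small_betas, four_pair_design):
        df = small_betas.values.copy()
        for _, c, t in four_pair_design.pairs:
            df[t] = df[c]
        diffs, n = paired_differences(BetaMatrix(df), four_pair_design)
        assert (diffs.to_numpy() == 0).all()
        assert (n == 4).all()

    def test_hand_computed_differences(self, small_betas, four_pair_design):
        diffs, _ = paired_differences(small_betas, four_pair_design)
        for pid in small_betas.probe_ids[:5]:
            for patient, c, t in four_pair_design.pairs:
                expected = small_betas.values.loc[pid, t] - small_betas.values.loc[pid, c]
                assert diffs.loc[pid, patient] == pytest.approx(expected, abs=1e-15)

    def test_missing_control_drops_that_pair_only(self, small_betas, four_pair_design):
        df = small_betas.values.copy()
        df.iloc[0, df.columns.get_loc(four_pair_design.control_samples[0])] = np.nan
        diffs, n = paired_differences(BetaMatrix(df), four_pair_design)
        assert n.iloc[0] == 3
        assert n.iloc[1:].eq(4).all()


class TestPrior:
    def test_trigamma_inverse_roundtrip(self):
        for x in (0.1, 1.0, 10.0):
            assert trigamma_inverse(polygamma(1, x))[0] == pytest.approx(x, abs=1e-8)

    def test_parameter_recovery_from_scaled_chisquare(self):
        rng = np.random.default_rng(42)
        d0, s0, df = 4.0, 0.01, 3
        sigma2 = d0 * s0 / rng.chisquare(d0, 10_000)
        s2 = sigma2 * rng.chisquare(df, 10_000) / df
        prior = estimate_prior(s2, np.full(10_000, float(df)))
        assert prior.d0 == pytest.approx(d0, rel=0.20)
        assert prior.s0_sq == pytest.approx(s0, rel=0.10)

    def test_constant_variances_give_infinite_d0(self):
        prior = estimate_prior(np.full(500, 0.02), np.full(500, 3.0))
        assert math.isinf(prior.d0)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_prior(np.zeros(200), np.full(200, 3.0))


class TestModeratedTest:
    def _random_diffs(self, rng, n_probes=100, n_pairs=4):
        return pd.DataFrame(rng.normal(0, 0.05, size=(n_probes, n_pairs)),
                            index=[f"cg{i}" for i in range(n_probes)],
                            columns=[f"P{j}" for j in range(n_pairs)])

    def test_d0_zero_equals_textbook_paired_t(self):
        rng = np.random.default_rng(7)
        prior = ModeratedVariancePrior(d0=0.0, s0_sq=1.0)
        for _ in range(100):
            diffs = self._random_diffs(rng, n_probes=5)
            res = moderated_paired_test(diffs, prior)
            # the paired t of (treatment, control) is the one-sample t of d
            t_ref, p_ref = stats.ttest_rel(
                diffs.to_numpy(), np.zeros_like(diffs.to_numpy()), axis=1)
            assert np.allclose(res["t_mod"], t_ref, atol=1e-10)
            assert np.allclose(res["p"], p_ref, atol=1e-10)

    def test_zero_variance_closed_form_with_moderation(self):
        diffs = pd.DataFrame([[0.1, 0.1, 0.1, 0.1]], index=["cg1"],
                             columns=list("ABCD"))
        d0, s0 = 2.0, 0.01
        res = moderated_paired_test(diffs, ModeratedVariancePrior(d0, s0))
        expected_t = 0.1 / np.sqrt(d0 * s0 / ((d0 + 3) * 4))
        assert res.loc["cg1", "delta_beta"] == pytest.approx(0.1)
        assert res.loc["cg1", "s2"] == 0.0
        assert res.loc["cg1", "t_mod"] == pytest.approx(expected_t, rel=1e-12)

    def test_zero_variance_without_moderation_gets_missing_p(self):
        diffs = pd.DataFrame([[0.1, 0.1, 0.1], [0.0, 0.1, 0.2]],
                             index=["cg1", "cg2"], columns=list("ABC"))
        res = moderated_paired_test(diffs, ModeratedVariancePrior(0.0, 1.0))
        assert np.isnan(res.loc["cg1", "p"])
        assert np.isfinite(res.loc["cg2", "p"])
        assert np.isfinite(res.loc["cg2", "adj_p"])

    def test_infinite_d0_uses_normal_reference(self):
        diffs = pd.DataFrame([[0.05, 0.06, 0.04, 0.05]], index=["cg1"],
                             columns=list("ABCD"))
        prior = ModeratedVariancePrior(math.inf, 0.001)
        res = moderated_paired_test(diffs, prior)
        t = res.loc["cg1", "t_mod"]
        assert t == pytest.approx(0.05 / np.sqrt(0.001 / 4), rel=1e-9)
        assert res.loc["cg1", "p"] == pytest.approx(2 * stats.norm.sf(abs(t)), rel=1e-9)

    def test_t_monotone_in_effect_size(self):
        prior = ModeratedVariancePrior(2.0, 0.01)
        base = np.array([0.0, 0.01, -0.01, 0.0])
        tvals = []
        for shift in (0.02, 0.05, 0.1, 0.2):
            diffs = pd.DataFrame([base + shift], index=["cg"], columns=list("ABCD"))
            tvals.append(abs(moderated_paired_test(diffs, prior)["t_mod"].iloc[0]))
        assert tvals == sorted(tvals)

    def test_direction_matches_sign(self):
        diffs = pd.DataFrame([[0.1, 0.2], [-0.1, -0.2]], index=["a", "b"],
                             columns=list("AB"))
        res = moderated_paired_test(diffs, ModeratedVariancePrior(1.0, 0.01))
        assert res.loc["a", "direction"] == "hyper"
        assert res.loc["b", "direction"] == "hypo"


class TestBH:
    def test_worked_example(self):
        adj = _bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, 0.04)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
                    min_size=1, max_size=200))
    def test_matches_brute_force_definition(self, pvals):
        p = np.asarray(pvals)
        assert np.allclose(_bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=500)
        assert (_bh_adjust(p) >= p - 1e-15).all()


class TestCallMvps:
    def test_threshold_one_returns_everything(self):
        res = pd.DataFrame({"p": [0.5, 0.9], "delta_beta": [0.1, -0.1]})
        assert len(call_mvps(res, 1.0)) == 2

    def test_direction_counts(self):
        res = pd.DataFrame({"p": [0.01, 0.01, 0.2], "delta_beta": [0.1, -0.1, 0.3]})
        called = call_mvps(res, 0.05)
        assert called.attrs["n_hyper"] == 1
        assert called.attrs["n_hypo"] == 1


class TestSummarizeGlobal:
    def test_constant_matrix(self, four_pair_design):
        man = make_manifest(list(range(100, 700, 100)),
                            features=["Body"] * 3 + ["TSS200"] * 3)
        cols = [s for pair in four_pair_design.pairs for s in pair[1:]]
        df = pd.DataFrame(0.5, index=man.df.index, columns=cols)
        out = summarize_global(BetaMatrix(df), man, four_pair_design)
        body = out[(out["category"] == "Body") & (out["group"] == "control")].iloc[0]
        assert body["mean"] == 0.5 == body["median"]
        assert body["sum"] == pytest.approx(0.5 * 3 * 4)  # 3 probes x 4 samples

    def test_quartiles_match_hand_computation(self):
        man = make_manifest(list(range(100, 700, 100)))
        vals = np.array([0.1, 0.2, 0.3, 0.6, 0.8, 0.9])
        df = pd.DataFrame({"s1": vals}, index=man.df.index)
        out = summarize_global(BetaMatrix(df), man)
        row = out[(out["category"] == "ALL")].iloc[0]
        assert row["min"] == 0.1 and row["max"] == 0.9
        assert row["q1"] == pytest.approx(np.percentile(vals, 25))
        assert row["median"] == pytest.approx(0.45)
        assert row["sum"] == pytest.approx(vals.sum())

    def test_null_simulation_groups_agree(self):
        cfg = SimulationConfig(n_probes=2000, seed=13)
        man = simulate_manifest(cfg)
        betas, design = simulate_paired_betas(cfg, man)
        out = summarize_global(betas, man, design)
        wide = out.pivot_table(index="category", columns="group", values="mean")
        assert np.allclose(wide["control"], wide["treatment"], atol=0.02)


class TestModelFacade:
    def test_fit_and_summary(self):
        cfg = SimulationConfig(n_probes=1000, seed=14)
        man = simulate_manifest(cfg)
        betas, design = simulate_paired_betas(cfg, man)
        res = PairedMethylationModel(betas, design, man).fit()
        assert res.nobs == 1000
        text = res.summary()
        assert "MVPs at p<0.05" in text and "Prior df" in text
        ann = res.annotated_table()
        assert {"chrom", "pos", "genes", "feature"}.issubset(ann.columns)

    def test_mvalue_scale_reports_beta_effects(self):
        cfg = SimulationConfig(n_probes=500, seed=15)
        man = simulate_manifest(cfg)
        betas, design = simulate_paired_betas(cfg, man)
        res_b = PairedMethylationModel(betas, design, man, scale="beta").fit()
        res_m = PairedMethylationModel(betas, design, man, scale="mvalue").fit()
        pd.testing.assert_series_equal(res_b.table["delta_beta"],
                                       res_m.table["delta_beta"])
        assert not np.allclose(res_b.table["t_mod"], res_m.table["t_mod"])
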