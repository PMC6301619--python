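"""Per-probe paired differential methylation with empirical-Bayes moderation.

The model: for probe *i* with paired differences d_i (treatment - control
beta, one entry per patient with both samples observed), the per-probe
variance s_i^2 is shrunk toward a prior (d0, s0^2) estimated by matching the
first two moments of log s^2 to a scaled-F distribution:

    s~_i^2 = (d0 * s0^2 + (n_i - 1) * s_i^2) / (d0 + n_i - 1)
    t_i    = mean(d_i) / sqrt(s~_i^2 / n_i)

with t_i referred to a t distribution on d0 + n_i - 1 degrees of freedom
(standard normal when d0 is infinite).  Raw p-values are thresholded to call
methylation variable positions (MVPs); Benjamini-Hochberg adjusted p-values
are reported alongside.

The module exposes both the low-level operations and a statsmodels-style
facade: ``PairedMethylationModel(betas, design).fit()`` returns a
:class:`MethylationResults` carrying the per-probe table, the prior, a
``summary()`` and the downstream DMR / candidate-gene calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .io import BetaMatrix, Manifest, PairedDesign, ValidationError

__all__ = [
    "ModeratedVariancePrior",
    "paired_differences",
    "trigamma_inverse",
    "estimate_prior",
    "moderated_paired_test",
    "call_mvps",
    "summarize_global",
    "PairedMethylationModel",
    "MethylationResults",
]


@dataclass(frozen=True)
class ModeratedVariancePrior:
    """Hyper-parameters of the scaled inverse chi-square variance prior.

    ``d0`` (prior degrees of freedom) may be ``math.inf``, in which case
    every probe's variance is replaced by ``s0_sq`` and the reference
    distribution is standard normal.  ``d0 == 0`` disables moderation.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be >= 0")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be > 0")


def paired_differences(
    betas: BetaMatrix, design: PairedDesign
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-probe treatment-minus-control difference vectors.

    A patient contributes to a probe only if both its samples are observed.
    Returns ``(diffs, n_pairs)`` where ``diffs`` is probes x patients (NaN
    where a pair is incomplete) and ``n_pairs`` counts complete pairs per
    probe.  Probes with fewer than 2 complete pairs are flagged by
    ``n_pairs < 2`` and must be excluded from testing.
    """
    design.validate_against(betas)
    ctrl = betas.values[design.control_samples].to_numpy(dtype=float)
    trt = betas.values[design.treatment_samples].to_numpy(dtype=float)
    diffs = pd.DataFrame(trt - ctrl, index=betas.values.index, columns=design.patients)
    n_pairs = diffs.notna().sum(axis=1)
    return diffs, n_pairs


def trigamma_inverse(y: float | np.ndarray, tol: float = 1e-10, max_iter: int = 75) -> np.ndarray:
    """Solve trigamma(x) = y by the standard Newton iteration on 1/x scale."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if (y <= 0).any():
        raise ValueError("trigamma_inverse requires y > 0")
    x = 0.5 + 1.0 / y  # asymptotic start: trigamma(x) ~ 1/x + 1/(2x^2)
    for _ in range(max_iter):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if np.max(np.abs(dif) / x) < tol:
            break
    return x


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> ModeratedVariancePrior:
    """Estimate (d0, s0^2) by moment matching on log sample variances.

    Follows the classical empirical-Bayes recipe: with z = log s^2,
    e = z - digamma(df/2) + log(df/2) has mean log s0^2 + digamma(d0/2)
    - log(d0/2) and excess variance trigamma(d0/2) beyond the sampling term
    trigamma(df/2); the latter is inverted numerically.  When the observed
    dispersion of e does not exceed the sampling term, d0 is infinite.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (df >= 1)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        raise ValueError("need at least 2 probes with df >= 1")
    if np.all(s2 <= 0):
        raise ValueError("degenerate input: all sample variances are zero")
    # guard zeros the way limma does: offset by a small fraction of the median
    floor = 1e-12 * np.median(s2[s2 > 0])
    z = np.log(np.maximum(s2, floor))
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    excess = e_var - np.mean(polygamma(1, df / 2.0))
    if excess <= 0:
        return ModeratedVariancePrior(d0=math.inf, s0_sq=float(np.exp(e_mean)))
    d0 = float(2.0 * trigamma_inverse(excess)[0])
    s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModeratedVariancePrior(d0=d0, s0_sq=s0_sq)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs excluded and propagated."""
    p = np.asarray(p, dtype=float)
    adj = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return adj


def moderated_paired_test(
    diffs: pd.DataFrame,
    prior: ModeratedVariancePrior,
    delta_beta: pd.Series | None = None,
) -> pd.DataFrame:
    """Moderated paired t-test per probe.

    Parameters
    ----------
    diffs
        Probe x patient difference vectors (NaN = incomplete pair).  Probes
        with fewer than 2 complete pairs are dropped.
    prior
        Variance-moderation hyper-parameters from :func:`estimate_prior`.
    delta_beta
        Optional beta-scale effect to report when ``diffs`` is on another
        scale (e.g. M-values); defaults to the row mean of ``diffs``.

    Returns a frame with columns delta_beta, n_pairs, s2, t_mod, df_total,
    p, adj_p, direction.  Zero-variance probes with ``d0 == 0`` get missing
    p and are excluded from the BH adjustment.
    """
    if prior is None:
        raise ValueError("a ModeratedVariancePrior is required")
    arr = diffs.to_numpy(dtype=float)
    n = np.sum(~np.isnan(arr), axis=1)
    keep = n >= 2
    arr, n = arr[keep], n[keep]
    index = diffs.index[keep]

    mean_d = np.nanmean(arr, axis=1)
    s2 = np.nanvar(arr, axis=1, ddof=1)
    s2[s2 <= 1e-28] = 0.0  # identical replicates: rounding noise is not variance
    d0, s0 = prior.d0, prior.s0_sq

    if math.isinf(d0):
        s2_tilde = np.full_like(s2, s0)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_tilde = (d0 * s0 + (n - 1) * s2) / (d0 + n - 1)
        df_total = d0 + n - 1.0

    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = mean_d / np.sqrt(s2_tilde / n)

    p = np.full(t_mod.shape, np.nan)
    finite = np.isfinite(t_mod)
    if math.isinf(d0):
        p[finite] = 2.0 * stats.norm.sf(np.abs(t_mod[finite]))
    else:
        p[finite] = 2.0 * stats.t.sf(np.abs(t_mod[finite]), np.broadcast_to(df_total, t_mod.shape)[finite])

    effect = np.nanmean(arr, axis=1) if delta_beta is None else delta_beta.loc[index].to_numpy(float)
    out = pd.DataFrame(
        {
            "delta_beta": effect,
            "n_pairs": n.astype(int),
            "s2": s2,
            "t_mod": t_mod,
            "df_total": np.broadcast_to(df_total, t_mod.shape),
            "p": p,
            "adj_p": _bh_adjust(p),
            "direction": np.where(effect > 0, "hyper", "hypo"),
        },
        index=index,
    )
    out.index.name = "probe_id"
    return out


def call_mvps(results: pd.DataFrame, p_threshold: float = 0.05) -> pd.DataFrame:
    """Subset of probes with raw p below the threshold.

    Direction counts (hyper = delta_beta > 0, hypo = delta_beta < 0) are
    attached as ``.attrs['n_hyper'] / ['n_hypo']``.
    """
    if not (0 < p_threshold <= 1):
        raise ValueError("p_threshold must lie in (0, 1]")
    called = results[results["p"] < p_threshold].copy()
    called.attrs["n_hyper"] = int((called["delta_beta"] > 0).sum())
    called.attrs["n_hypo"] = int((called["delta_beta"] < 0).sum())
    return called


def summarize_global(
    betas: BetaMatrix, manifest: Manifest, design: PairedDesign | None = None
) -> pd.DataFrame:
    """Per-category beta summaries: min, Q1, median, mean, Q3, max, sum.

    Categories: ALL probes, each gene-feature category and each CGI
    category, summarised per sample group (control / treatment when a
    design is given, otherwise one pooled 'all' group).
    """
    mdf = manifest.df.reindex(betas.values.index)
    if mdf["pos"].isna().any():
        raise ValidationError("manifest does not cover every probe in the matrix")
    if design is not None:
        groups = {"control": design.control_samples, "treatment": design.treatment_samples}
    else:
        groups = {"all": betas.sample_ids}

    def _stats(vals: np.ndarray) -> dict[str, float]:
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            return {k: np.nan for k in ("min", "q1", "median", "mean", "q3", "max", "sum")}
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        return {
            "min": vals.min(), "q1": q1, "median": med, "mean": vals.mean(),
            "q3": q3, "max": vals.max(), "sum": vals.sum(),
        }

    categories: list[tuple[str, np.ndarray]] = [("ALL", np.ones(len(mdf), dtype=bool))]
    for feat in sorted(mdf["feature"].unique()):
        categories.append((feat, (mdf["feature"] == feat).to_numpy()))
    for cgi in sorted(mdf["cgi_relation"].unique()):
        categories.append((cgi, (mdf["cgi_relation"] == cgi).to_numpy()))

    rows = []
    for group, samples in groups.items():
        sub = betas.values[samples].to_numpy(dtype=float)
        for name, mask in categories:
            rows.append({"group": group, "category": name, "n_probes": int(mask.sum()),
                         **_stats(sub[mask].ravel())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model facade


class PairedMethylationModel:
    """Paired differential-methylation model over a beta matrix.

    Parameters
    ----------
    betas
        Normalized probe x sample beta values.
    design
        Per-patient (control, treatment) pairing.
    manifest
        Optional probe annotations; required for the positional (DMR) and
        gene-level calls on the results object.
    scale
        ``"beta"`` tests the beta-scale differences directly (default);
        ``"mvalue"`` tests log2(beta/(1-beta)) differences while still
        reporting beta-scale effect sizes.
    """

    def __init__(
        self,
        betas: BetaMatrix,
        design: PairedDesign,
        manifest: Manifest | None = None,
        scale: str = "beta",
    ):
        if scale not in ("beta", "mvalue"):
            raise ValueError("scale must be 'beta' or 'mvalue'")
        design.validate_against(betas)
        self.betas = betas
        self.design = design
        self.manifest = manifest
        self.scale = scale

    @classmethod
    def from_dataframe(
        cls, values: pd.DataFrame, design: PairedDesign, manifest: Manifest | None = None,
        scale: str = "beta",
    ) -> "PairedMethylationModel":
        return cls(BetaMatrix(values), design, manifest, scale)

    def fit(self, prior: ModeratedVariancePrior | None = None) -> "MethylationResults":
        """Estimate the variance prior (unless given) and run the moderated test."""
        beta_diffs, n_pairs = paired_differences(self.betas, self.design)
        if self.scale == "mvalue":
            vals = self.betas.values.clip(1e-6, 1 - 1e-6)
            m = np.log2(vals / (1 - vals))
            ctrl = m[self.design.control_samples].to_numpy(float)
            trt = m[self.design.treatment_samples].to_numpy(float)
            test_diffs = pd.DataFrame(trt - ctrl, index=m.index, columns=self.design.patients)
        else:
            test_diffs = beta_diffs
        testable = n_pairs >= 2
        if prior is None:
            s2 = test_diffs[testable].var(axis=1, ddof=1, skipna=True).to_numpy()
            df = (n_pairs[testable] - 1).to_numpy(float)
            prior = estimate_prior(s2, df)
        delta = beta_diffs.mean(axis=1, skipna=True)
        table = moderated_paired_test(test_diffs[testable], prior, delta_beta=delta)
        return MethylationResults(self, table, prior,
                                  n_excluded=int((~testable).sum()))


class MethylationResults:
    """Fit results: per-probe moderated statistics plus downstream calls."""

    def __init__(self, model: PairedMethylationModel, table: pd.DataFrame,
                 prior: ModeratedVariancePrior, n_excluded: int = 0):
        self.model = model
        self.table = table
        self.prior = prior
        self.n_excluded = n_excluded

    @property
    def nobs(self) -> int:
        return len(self.table)

    def call_mvps(self, p_threshold: float = 0.05) -> pd.DataFrame:
        return call_mvps(self.table, p_threshold)

    def call_dmrs(self, p_threshold: float = 0.05, window_bp: int = 1000, min_mvps: int = 3):
        from .dmr import call_dmrs

        if self.model.manifest is None:
            raise ValueError("a manifest is required for DMR calling")
        return call_dmrs(self.call_mvps(p_threshold), self.model.manifest,
                         window_bp=window_bp, min_mvps=min_mvps, p_max=p_threshold)

    def candidate_genes(self, p_threshold: float = 0.05, window_bp: int = 1000,
                        min_mvps: int = 3, min_hypo_regulatory: int = 2):
        from .dmr import select_candidates

        dmrs = self.call_dmrs(p_threshold, window_bp, min_mvps)
        return select_candidates(dmrs, self.model.manifest,
                                 min_hypo_regulatory=min_hypo_regulatory)

    def annotated_table(self) -> pd.DataFrame:
        """The MVP table joined with chrom/pos/genes/feature from the manifest."""
        if self.model.manifest is None:
            return self.table.copy()
        mdf = self.model.manifest.df.reindex(self.table.index)
        out = self.table.copy()
        out.insert(0, "chrom", mdf["chrom"])
        out.insert(1, "pos", mdf["pos"])
        out["genes"] = [";".join(sorted(g)) if isinstance(g, frozenset) else "" for g in mdf["genes"]]
        out["feature"] = mdf["feature"]
        return out

    def summary(self, p_thresholds: tuple[float, ...] = (0.05, 0.001)) -> str:
        lines = [
            "Paired differential methylation (empirical-Bayes moderated t)",
            "=" * 62,
            f"Probes tested:        {self.nobs}",
            f"Probes excluded (<2 complete pairs): {self.n_excluded}",
            f"Patients (pairs):     {len(self.model.design)}",
            f"Test scale:           {self.model.scale}",
            f"Prior df (d0):        {self.prior.d0:.4g}",
            f"Prior variance (s0^2): {self.prior.s0_sq:.4g}",
        ]
        for thr in p_thresholds:
            called = self.call_mvps(thr)
            lines.append(
                f"MVPs at p<{thr}:    {len(called)} "
                f"({called.attrs['n_hyper']} hyper / {called.attrs['n_hypo']} hypo)"
            )
        sig = self.table["adj_p"] < 0.05
        lines.append(f"Probes at BH FDR<0.05: {int(sig.sum())}")
        return "\n".join(lines)
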