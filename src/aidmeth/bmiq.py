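"""Beta-mixture quantile normalization (BMIQ) of Infinium Type II probes.

The two Infinium probe chemistries report beta values on different dynamic
ranges: Type II probes are compressed toward 0.5 relative to Type I.  BMIQ
corrects this per sample by fitting a three-state beta mixture
(unmethylated / hemimethylated / methylated) separately to the Type I and
Type II probes, then mapping each Type II probe onto the Type I scale:

* U-state probes are matched by lower-tail beta-CDF quantiles of the Type II
  U component onto the Type I U component;
* M-state probes likewise via upper-tail quantiles;
* H-state probes are carried by a monotone dilation — an affine map of the
  observed H range onto the gap between the transformed U maximum and the
  transformed M minimum.

Type I probes pass through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import betaln, digamma

from .io import Manifest

__all__ = ["BetaMixtureFit", "fit_beta_mixture", "bmiq_normalize", "normalize_matrix"]

EPS = 1e-6  # nudge for beta values at exactly 0 or 1 (beta density support)


@dataclass
class BetaMixtureFit:
    """A fitted K-state beta mixture.

    States are relabelled in order of increasing mean, so for K=3 the
    conventional U (unmethylated), H (hemimethylated), M (methylated)
    interpretation holds: ``mean_U < mean_H < mean_M``.
    """

    weights: np.ndarray          # (K,) mixing proportions, sums to 1
    shapes: np.ndarray           # (K, 2) beta shape pairs (a_k, b_k)
    state_of: np.ndarray         # per-value max-posterior state index
    loglik: float
    loglik_trace: np.ndarray     # per-iteration log-likelihood
    converged: bool

    @property
    def means(self) -> np.ndarray:
        a, b = self.shapes[:, 0], self.shapes[:, 1]
        return a / (a + b)

    def cdf(self, x: np.ndarray, state: int) -> np.ndarray:
        a, b = self.shapes[state]
        return stats.beta.cdf(x, a, b)

    def ppf(self, q: np.ndarray, state: int) -> np.ndarray:
        a, b = self.shapes[state]
        return stats.beta.ppf(q, a, b)


def _clip_unit(values: np.ndarray) -> np.ndarray:
    return np.clip(values, EPS, 1.0 - EPS)


def _weighted_beta_mle(x: np.ndarray, w: np.ndarray, start: tuple[float, float]) -> tuple[float, float]:
    """Maximise the weighted beta log-likelihood for one mixture component.

    Sufficient statistics: N = sum(w), S1 = sum(w ln x), S2 = sum(w ln(1-x)).
    """
    n = w.sum()
    s1 = float(w @ np.log(x))
    s2 = float(w @ np.log1p(-x))

    def negloglik(theta):
        a, b = np.exp(theta)
        val = n * betaln(a, b) - (a - 1.0) * s1 - (b - 1.0) * s2
        da = n * (digamma(a) - digamma(a + b)) - s1
        db = n * (digamma(b) - digamma(a + b)) - s2
        # chain rule through the log parametrisation
        return val, np.array([da * a, db * b])

    theta0 = np.log(np.clip(start, 1e-2, 1e4))
    res = optimize.minimize(negloglik, theta0, jac=True, method="L-BFGS-B",
                            bounds=[(np.log(1e-3), np.log(1e6))] * 2)
    a, b = np.exp(res.x)
    return float(a), float(b)


def _moment_shapes(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted method-of-moments beta shape estimate (EM start values)."""
    n = w.sum()
    m = float(w @ x) / n
    v = float(w @ (x - m) ** 2) / n
    v = max(v, 1e-6)
    common = m * (1.0 - m) / v - 1.0
    common = max(common, 1e-2)
    return max(m * common, 1e-2), max((1.0 - m) * common, 1e-2)


def fit_beta_mixture(
    values: np.ndarray,
    n_states: int = 3,
    tol: float = 1e-4,
    max_iter: int = 200,
    seed: int | None = None,
) -> BetaMixtureFit:
    """Fit a beta mixture by EM with deterministic threshold initialisation.

    Values at exactly 0 or 1 are nudged inward by ``EPS``.  Initial state
    assignment uses fixed beta thresholds (< 0.25 -> U, > 0.75 -> M, else H)
    rather than random starts, so the default fit is deterministic; ``seed``
    is accepted for interface stability and only matters for future
    multi-start extensions.

    Raises
    ------
    ValueError
        For fewer than 30 usable values or degenerate (constant) data.
    """
    x = _clip_unit(np.asarray(values, dtype=float))
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if x.size < 30:
        raise ValueError(f"need at least 30 values to fit a beta mixture, got {x.size}")
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate data: all values are (numerically) equal")
    if n_states not in (1, 2, 3):
        raise ValueError("n_states must be 1, 2 or 3")

    # deterministic init by fixed thresholds
    if n_states == 1:
        resp = np.ones((x.size, 1))
    elif n_states == 2:
        resp = np.zeros((x.size, 2))
        resp[x <= 0.5, 0] = 1.0
        resp[x > 0.5, 1] = 1.0
    else:
        resp = np.zeros((x.size, 3))
        resp[x < 0.25, 0] = 1.0
        resp[(x >= 0.25) & (x <= 0.75), 1] = 1.0
        resp[x > 0.75, 2] = 1.0
    # guard: a state with no initial members gets a diffuse share
    empty = resp.sum(axis=0) < 2
    if empty.any():
        resp[:, empty] = 0.05
        resp /= resp.sum(axis=1, keepdims=True)

    weights = resp.mean(axis=0)
    shapes = np.array([_moment_shapes(x, resp[:, k]) for k in range(n_states)])

    trace: list[float] = []
    converged = False
    loglik = -np.inf
    for _ in range(max_iter):
        # M step: exact weighted MLE per component
        shapes = np.array([
            _weighted_beta_mle(x, resp[:, k], tuple(shapes[k])) for k in range(n_states)
        ])
        weights = resp.sum(axis=0) / x.size
        # E step
        log_dens = np.column_stack([
            stats.beta.logpdf(x, a, b) + np.log(max(w, 1e-300))
            for (a, b), w in zip(shapes, weights)
        ])
        m = log_dens.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_dens - m).sum(axis=1))
        new_loglik = float(lse.sum())
        resp = np.exp(log_dens - lse[:, None])
        trace.append(new_loglik)
        if np.isfinite(loglik) and abs(new_loglik - loglik) < tol * (abs(loglik) + 1.0):
            converged = True
            loglik = new_loglik
            break
        loglik = new_loglik

    # relabel states by increasing component mean
    order = np.argsort(shapes[:, 0] / shapes.sum(axis=1))
    shapes = shapes[order]
    weights = weights[order]
    resp = resp[:, order]
    return BetaMixtureFit(
        weights=weights,
        shapes=shapes,
        state_of=resp.argmax(axis=1),
        loglik=loglik,
        loglik_trace=np.asarray(trace),
        converged=converged,
    )


def bmiq_normalize(
    sample_betas: pd.Series,
    manifest: Manifest,
    tol: float = 1e-4,
    max_iter: int = 200,
    seed: int | None = None,
    min_state_count: int = 5,
) -> pd.Series:
    """Normalize one sample's Type II betas onto the Type I scale.

    Parameters
    ----------
    sample_betas
        Per-probe beta values for a single sample, indexed by probe id.
    manifest
        Probe annotations supplying the Infinium design type.

    Returns a Series aligned with the input; Type I probes are bit-identical
    to the input, Type II probes are transformed, and all outputs lie in
    [0, 1].  Missing values pass through as missing.
    """
    design = manifest.df["design_type"].reindex(sample_betas.index)
    if design.isna().any():
        missing = sample_betas.index[design.isna()][:5].tolist()
        raise ValueError(f"probes absent from manifest: {missing}")

    out = sample_betas.copy()
    obs = sample_betas.notna()
    is1 = (design == "I") & obs
    is2 = (design == "II") & obs
    if is1.sum() < 30 or is2.sum() < 30:
        raise ValueError("need at least 30 observed Type I and 30 Type II probes")

    fit1 = fit_beta_mixture(sample_betas[is1].to_numpy(), tol=tol, max_iter=max_iter, seed=seed)
    x2 = _clip_unit(sample_betas[is2].to_numpy())
    fit2 = fit_beta_mixture(x2, tol=tol, max_iter=max_iter, seed=seed)

    counts = np.bincount(fit2.state_of, minlength=3)
    if (counts < min_state_count).any():
        raise ValueError(
            f"too few Type II probes per mixture state (counts {counts.tolist()}, "
            f"need >= {min_state_count}); provide a larger input"
        )

    state = fit2.state_of
    y = np.empty_like(x2)

    # U: match lower-tail quantiles of the Type II U component onto Type I U
    u_mask = state == 0
    q = np.clip(fit2.cdf(x2[u_mask], 0), 1e-12, 1 - 1e-12)
    y[u_mask] = fit1.ppf(q, 0)

    # M: match upper-tail quantiles
    m_mask = state == 2
    a2, b2 = fit2.shapes[2]
    a1, b1 = fit1.shapes[2]
    q = np.clip(stats.beta.sf(x2[m_mask], a2, b2), 1e-12, 1 - 1e-12)
    y[m_mask] = stats.beta.isf(q, a1, b1)

    # H: monotone dilation of the H range onto the gap between the
    # transformed U maximum and transformed M minimum
    h_mask = state == 1
    if h_mask.any():
        h = x2[h_mask]
        h_lo, h_hi = h.min(), h.max()
        gap_lo = y[u_mask].max() if u_mask.any() else h_lo
        gap_hi = y[m_mask].min() if m_mask.any() else h_hi
        if gap_hi <= gap_lo or h_hi <= h_lo:
            y[h_mask] = h  # degenerate gap: leave H probes on their own scale
        else:
            y[h_mask] = gap_lo + (h - h_lo) / (h_hi - h_lo) * (gap_hi - gap_lo)

    out.loc[is2[is2].index] = np.clip(y, 0.0, 1.0)
    return out


def normalize_matrix(betas, manifest: Manifest, skip: bool = False, **kwargs):
    """Apply :func:`bmiq_normalize` column-wise to a :class:`~aidmeth.io.BetaMatrix`.

    With ``skip=True`` the matrix passes through unchanged (ablation mode).
    """
    from .io import BetaMatrix

    if skip:
        return BetaMatrix(betas.values.copy())
    cols = {s: bmiq_normalize(betas.values[s], manifest, **kwargs) for s in betas.sample_ids}
    return BetaMatrix(pd.DataFrame(cols, columns=betas.values.columns))
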