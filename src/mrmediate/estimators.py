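"""Causal-effect estimators and diagnostics for two-sample MR.

All estimators consume a :class:`~mrmediate.harmonize.HarmonizedSet` and
return an :class:`MREstimate`.  Per-SNP causal estimates are Wald ratios
``beta_out / beta_exp`` with first-order standard errors
``se_out / |beta_exp|``.  The headline estimator is the multiplicative
random-effects inverse-variance-weighted (IVW) mean of the ratios; MR-Egger
regression and the weighted median serve as pleiotropy-robust supplements,
with Cochran's Q, the Egger intercept, and leave-one-out re-estimation as
diagnostics.

Confidence intervals are ``beta ± 1.96·se`` and p-values are two-sided
normal throughout, matching the convention of the published tables this
package reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import DataError, DomainError
from .harmonize import HarmonizedSet

Z95 = 1.96


@dataclass
class MREstimate:
    """One method's causal estimate with its uncertainty and diagnostics."""

    method: str
    beta: float
    se: float
    lci: float
    uci: float
    pval: float
    n_snp: int
    exposure: str = "exposure"
    outcome: str = "outcome"
    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 1.0 if beta == 0 else 5e-324
    # floor keeps extreme z-scores inside the (0, 1] p-value domain
    return float(max(2.0 * stats.norm.sf(abs(beta) / se), 1e-300))


def _estimate(method, beta, se, n_snp, h: HarmonizedSet, **diag) -> MREstimate:
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        lci=float(beta - Z95 * se),
        uci=float(beta + Z95 * se),
        pval=_normal_p(beta, se),
        n_snp=int(n_snp),
        exposure=h.exposure_name,
        outcome=h.outcome_name,
        **diag,
    )


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float) -> tuple[float, float]:
    """Single-SNP causal estimate: ratio and its first-order SE."""
    if beta_exp == 0:
        raise DomainError("wald_ratio: exposure effect is zero")
    return beta_out / beta_exp, se_out / abs(beta_exp)


def _ratios(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    if np.any(h.beta_exp == 0):
        raise DomainError("per-SNP ratios undefined: some exposure effects are exactly zero")
    return h.beta_out / h.beta_exp, h.se_out / np.abs(h.beta_exp)


def ivw(h: HarmonizedSet, effects_model: str = "random") -> MREstimate:
    """Inverse-variance-weighted meta-analysis of the per-SNP Wald ratios.

    ``effects_model="random"`` (the default and the headline method) uses
    the multiplicative random-effects model: the fixed-effects SE is
    inflated by ``sqrt(Q/df)`` when Cochran's Q exceeds its degrees of
    freedom, and never deflated below the fixed-effects SE.
    """
    if effects_model not in ("fixed", "random"):
        raise ValueError(f"unknown effects model {effects_model!r}")
    if h.n_snp < 1:
        raise DataError("ivw: empty harmonized set")
    ratios, ratio_ses = _ratios(h)
    w = 1.0 / ratio_ses**2
    beta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))
    diag: dict = {}
    se = se_fixed
    if h.n_snp >= 2:
        q = float(np.sum(w * (ratios - beta) ** 2))
        df = h.n_snp - 1
        diag = {"q_stat": q, "q_df": df, "q_pval": float(stats.chi2.sf(q, df))}
        if effects_model == "random":
            se = se_fixed * max(1.0, np.sqrt(q / df))
    return _estimate(f"ivw_{effects_model}", beta, se, h.n_snp, h, **diag)


def egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger: weighted regression of outcome on exposure effects with a
    free intercept.

    Exposure effects are first oriented non-negative (flipping the paired
    outcome effects), the identifying convention for Egger regression.  The
    slope estimates the causal effect; the intercept estimates the average
    directional pleiotropy.  Standard errors come from the unscaled WLS
    covariance inflated by ``max(1, sqrt(Q_residual/(J-2)))``.
    """
    if h.n_snp < 3:
        raise DataError(f"egger: needs at least 3 SNPs, got {h.n_snp}")
    sign = np.where(h.beta_exp < 0, -1.0, 1.0)
    x = h.beta_exp * sign
    y = h.beta_out * sign
    if np.allclose(x, x[0]):
        raise DataError("egger: no variance in exposure effects (degenerate design)")
    w = 1.0 / h.se_out**2
    model = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    scale = float(model.scale)  # residual Q / (J - 2)
    se_unscaled = np.sqrt(np.diag(model.normalized_cov_params))
    inflation = max(1.0, np.sqrt(scale))
    intercept, slope = model.params
    se_int, se_slope = se_unscaled * inflation
    est = _estimate(
        "egger",
        slope,
        se_slope,
        h.n_snp,
        h,
        q_stat=scale * (h.n_snp - 2),
        q_df=h.n_snp - 2,
        q_pval=float(stats.chi2.sf(scale * (h.n_snp - 2), h.n_snp - 2)),
        egger_intercept=float(intercept),
        egger_intercept_se=float(se_int),
        egger_intercept_pval=_normal_p(intercept, se_int),
    )
    return est


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with linear interpolation at cumulative weight 0.5."""
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, v))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    The estimate is the per-SNP ratio at cumulative inverse-variance weight
    0.5 (interpolated); it is consistent when fewer than half the weights
    come from invalid instruments.  The SE is the standard deviation of the
    estimate over ``n_boot`` replicates in which each ratio is resampled
    from ``Normal(ratio_j, ratio_se_j²)`` (seeded, hence reproducible).
    """
    if h.n_snp < 3:
        raise DataError(f"weighted_median: needs at least 3 SNPs, got {h.n_snp}")
    ratios, ratio_ses = _ratios(h)
    weights = 1.0 / ratio_ses**2
    beta = _weighted_median(ratios, weights)
    rng = np.random.default_rng(seed)
    draws = rng.normal(ratios, ratio_ses, size=(n_boot, h.n_snp))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = _weighted_median(draws[b], weights)
    se = float(np.std(boots, ddof=1))
    return _estimate("weighted_median", beta, se, h.n_snp, h)


def cochran_q(h: HarmonizedSet) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic over the per-SNP ratios.

    Returns ``(Q, df, p)`` with ``df = J - 1`` and a chi-square upper-tail
    p-value.  Excess Q signals pleiotropy or model misfit.
    """
    if h.n_snp < 2:
        raise DataError(f"cochran_q: needs at least 2 SNPs, got {h.n_snp}")
    est = ivw(h, effects_model="fixed")
    return est.q_stat, est.q_df, est.q_pval


@dataclass
class LeaveOneOutEntry:
    """Random-effects IVW estimate with one SNP omitted."""

    omitted_snp_id: str
    estimate: MREstimate
    influential: bool


def leave_one_out(h: HarmonizedSet) -> list[LeaveOneOutEntry]:
    """Re-estimate random-effects IVW omitting each SNP in turn.

    Entries are ordered by ``snp_id`` (the harmonized-set order).  An entry
    is flagged ``influential`` when omitting its SNP flips the sign of the
    estimate or moves the p-value across 0.05 relative to the full set.
    """
    if h.n_snp < 3:
        raise DataError(f"leave_one_out: needs at least 3 SNPs, got {h.n_snp}")
    full = ivw(h, effects_model="random")
    out = []
    for i in range(h.n_snp):
        est = ivw(h.without(i), effects_model="random")
        influential = (np.sign(est.beta) != np.sign(full.beta)) or (
            (est.pval < 0.05) != (full.pval < 0.05)
        )
        out.append(LeaveOneOutEntry(str(h.snp_ids[i]), est, bool(influential)))
    return out
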