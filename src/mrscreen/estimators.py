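"""Causal-effect estimators and classical sensitivity statistics.

Implements the two-sample MR estimator suite from its defining
formulas: per-SNP Wald ratios with first-order standard errors,
fixed/random-effects inverse-variance-weighted (IVW) pooling with
Cochran's Q and I², MR-Egger weighted regression with its intercept
pleiotropy test, the weighted-median estimator with a parametric
bootstrap SE, leave-one-out re-estimation, odds-ratio reporting and
a binary-outcome power approximation.

Conventions fixed here and documented in docs/methods.md:

* Wald-ratio variance is first order (σ_j = σ_Yj/|β_Xj|; exposure
  uncertainty enters the random-effects inflation, not σ_j itself).
* Random-effects IVW is multiplicative: SE_random = SE_fixed ·
  max(1, sqrt(Q/(J−1))); the random model is selected when the Q-test
  p-value falls below ``alpha`` (J ≥ 2), else the fixed model.
* Egger inference uses a t distribution on J−2 df with the same
  multiplicative overdispersion floor; IVW inference is normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .instruments import DegenerateInstrumentError, InstrumentSet

Z975 = 1.959964  # normal 97.5% point as conventionally printed


@dataclass
class MREstimate:
    """One method's causal estimate with CI, p and heterogeneity diagnostics."""

    method: str  # wald | ivw | egger | weighted_median
    model: str  # fixed | random | not_applicable
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_snps: int
    Q: float = float("nan")
    q_p: float = float("nan")
    i2: float = float("nan")
    egger_intercept: float = float("nan")
    egger_intercept_se: float = float("nan")
    egger_intercept_p: float = float("nan")

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)


@dataclass
class SensitivitySuite:
    """All sensitivity analyses computed from one instrument set."""

    ivw: MREstimate
    egger: MREstimate | None = None
    weighted_median: MREstimate | None = None
    presso: object | None = None  # PressoResult; typed loosely to avoid a cycle
    leave_one_out: list[tuple[str, MREstimate]] = field(default_factory=list)
    power: float = float("nan")
    flags: list[str] = field(default_factory=list)


def wald_ratios(iset: InstrumentSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP ratio estimates θ̂_j = β_Yj/β_Xj and first-order SEs σ_Yj/|β_Xj|."""
    if np.any(iset.beta_exp == 0.0):
        j = int(np.argmax(iset.beta_exp == 0.0))
        raise DegenerateInstrumentError(
            f"zero exposure effect for {iset.variant_id[j]}: Wald ratio undefined"
        )
    theta = iset.beta_out / iset.beta_exp
    sigma = iset.se_out / np.abs(iset.beta_exp)
    return theta, sigma


def _heterogeneity(theta: np.ndarray, sigma: np.ndarray, pooled: float, df: int):
    w = 1.0 / sigma**2
    q = float(np.sum(w * (theta - pooled) ** 2))
    q_p = float(stats.chi2.sf(q, df)) if df >= 1 else float("nan")
    i2 = max(0.0, (q - df) / q) if (df >= 1 and q > 0) else 0.0
    return q, q_p, i2


def ivw(iset: InstrumentSet, alpha: float = 0.05) -> MREstimate:
    """Inverse-variance-weighted estimate with fixed/random model selection."""
    theta, sigma = wald_ratios(iset)
    j = theta.size
    if j == 0:
        raise DegenerateInstrumentError("IVW needs at least one instrument")
    w = 1.0 / sigma**2
    pooled = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    if j >= 2:
        q, q_p, i2 = _heterogeneity(theta, sigma, pooled, j - 1)
        inflation = max(1.0, math.sqrt(q / (j - 1)))
    else:
        q, q_p, i2 = 0.0, float("nan"), float("nan")
        inflation = 1.0
    use_random = j >= 2 and not math.isnan(q_p) and q_p < alpha
    se = se_fixed * inflation if use_random else se_fixed
    p = float(2.0 * stats.norm.sf(abs(pooled / se)))
    half = Z975 * se
    return MREstimate(
        method="ivw",
        model="random" if use_random else "fixed",
        beta=pooled,
        se=se,
        ci_low=pooled - half,
        ci_high=pooled + half,
        p=p,
        n_snps=j,
        Q=q,
        q_p=q_p,
        i2=i2,
    )


def egger(iset: InstrumentSet, alpha: float = 0.05) -> MREstimate | None:
    """MR-Egger weighted regression with free intercept (None when J < 3).

    Instruments are first oriented so every exposure effect is
    non-negative (flipping both βX and βY, i.e. recoding the effect
    allele), then βY is regressed on βX with weights 1/σ_Yj².  The
    slope is the causal estimate; the intercept is the average
    directional pleiotropic effect.  Inference is t on J−2 df with the
    multiplicative overdispersion floor max(1, sqrt(RSS/(J−2))).
    """
    j = iset.n_snps
    if j < 3:
        return None
    flip = np.sign(iset.beta_exp)
    flip[flip == 0] = 1.0
    x = iset.beta_exp * flip
    y = iset.beta_out * flip
    w = 1.0 / iset.se_out**2

    sw = np.sum(w)
    sx = np.sum(w * x)
    sy = np.sum(w * y)
    sxx = np.sum(w * x * x)
    sxy = np.sum(w * x * y)
    denom = sw * sxx - sx * sx
    if denom <= 0:
        return None  # degenerate design (all βX equal)
    slope = float((sw * sxy - sx * sy) / denom)
    intercept = float((sy - slope * sx) / sw)

    resid = y - intercept - slope * x
    rss = float(np.sum(w * resid**2))
    df = j - 2
    phi = max(1.0, rss / df)  # overdispersion floored at 1
    var_slope = phi * sw / denom
    var_int = phi * sxx / denom
    se_slope = math.sqrt(var_slope)
    se_int = math.sqrt(var_int)

    tdist = stats.t(df)
    p_slope = float(2.0 * tdist.sf(abs(slope / se_slope)))
    p_int = float(2.0 * tdist.sf(abs(intercept / se_int)))
    q, q_p, i2 = rss, float(stats.chi2.sf(rss, df)), max(0.0, (rss - df) / rss) if rss > 0 else 0.0
    tcrit = float(tdist.ppf(0.975))
    return MREstimate(
        method="egger",
        model="not_applicable",
        beta=slope,
        se=se_slope,
        ci_low=slope - tcrit * se_slope,
        ci_high=slope + tcrit * se_slope,
        p=p_slope,
        n_snps=j,
        Q=q,
        q_p=q_p,
        i2=i2,
        egger_intercept=intercept,
        egger_intercept_se=se_int,
        egger_intercept_p=p_int,
    )


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median: breakpoints s_j = cum(w̃)_j − w̃_j/2."""
    order = np.argsort(theta, kind="stable")
    th = theta[order]
    wn = w[order] / np.sum(w)
    s = np.cumsum(wn) - 0.5 * wn
    if 0.5 <= s[0]:
        return float(th[0])
    if 0.5 >= s[-1]:
        return float(th[-1])
    return float(np.interp(0.5, s, th))


def weighted_median(
    iset: InstrumentSet, n_boot: int = 1000, seed: int = 0, alpha: float = 0.05
) -> MREstimate | None:
    """Weighted-median estimator (None when J < 3).

    Valid when at least half the total weight comes from valid
    instruments.  The SE is the standard deviation of the estimate over
    ``n_boot`` parametric-bootstrap replicates drawing β_Xj*, β_Yj*
    from normals centred at the observed values with their SEs.
    """
    j = iset.n_snps
    if j < 3:
        return None
    theta, sigma = wald_ratios(iset)
    w = 1.0 / sigma**2
    est = _weighted_median(theta, w)

    rng = np.random.default_rng(seed)
    bx = rng.normal(iset.beta_exp, iset.se_exp, size=(n_boot, j))
    by = rng.normal(iset.beta_out, iset.se_out, size=(n_boot, j))
    bx[bx == 0.0] = np.finfo(float).tiny
    boots = np.empty(n_boot)
    for k in range(n_boot):
        th_k = by[k] / bx[k]
        w_k = (bx[k] / iset.se_out) ** 2
        boots[k] = _weighted_median(th_k, w_k)
    se = float(np.std(boots, ddof=1))
    p = float(2.0 * stats.norm.sf(abs(est / se))) if se > 0 else (1.0 if est == 0 else 0.0)
    half = Z975 * se
    return MREstimate(
        method="weighted_median",
        model="not_applicable",
        beta=est,
        se=se,
        ci_low=est - half,
        ci_high=est + half,
        p=p,
        n_snps=j,
    )


def leave_one_out(iset: InstrumentSet, alpha: float = 0.05) -> list[tuple[str, MREstimate]]:
    """IVW re-estimates dropping each instrument in turn (empty when J < 2)."""
    j = iset.n_snps
    if j < 2:
        return []
    out = []
    for drop in range(j):
        mask = np.ones(j, dtype=bool)
        mask[drop] = False
        out.append((str(iset.variant_id[drop]), ivw(iset.subset(mask), alpha)))
    return out


def wald_summary(beta: float, se: float, alpha: float = 0.05) -> dict:
    """Odds-ratio reporting: OR = exp(β), Wald CI on the log scale, normal p."""
    if se <= 0:
        raise ValueError("se must be positive")
    z = float(stats.norm.ppf(1.0 - alpha / 2.0)) if alpha != 0.05 else Z975
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return {
        "odds_ratio": math.exp(beta),
        "ci_low": math.exp(beta - z * se),
        "ci_high": math.exp(beta + z * se),
        "p": p,
    }


def mr_power(
    n_outcome: int,
    case_fraction: float,
    r2_sum: float,
    beta: float,
    alpha: float = 0.05,
) -> float:
    """Two-sided power for a binary outcome via the non-centrality
    λ = |β|·sqrt(N·R²·K(1−K))."""
    if not (0.0 < case_fraction < 1.0):
        raise ValueError("case_fraction must lie in (0,1)")
    if not (0.0 < r2_sum < 1.0):
        raise ValueError("r2_sum must lie in (0,1)")
    lam = abs(beta) * math.sqrt(n_outcome * r2_sum * case_fraction * (1.0 - case_fraction))
    z = float(stats.norm.ppf(1.0 - alpha / 2.0))
    return float(stats.norm.sf(z - lam) + stats.norm.cdf(-z - lam))


__all__ = [
    "MREstimate",
    "SensitivitySuite",
    "Z975",
    "egger",
    "ivw",
    "leave_one_out",
    "mr_power",
    "wald_ratios",
    "wald_summary",
    "weighted_median",
]
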