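"""Causal-effect estimators and pleiotropy diagnostics for two-sample MR.

Given harmonized per-variant effect pairs (β_Xj, β_Yj) the estimators here
combine the per-variant Wald ratios θ_j = β_Yj / β_Xj into a causal slope:

* ``ivw`` — the inverse-variance-weighted estimate, equivalently a weighted
  regression of β_Y on β_X through the origin with first-order weights
  w_j = β_Xj² / se_Yj².  The multiplicative random-effects flavour inflates
  the fixed-effect standard error by sqrt(Q/df) floored at 1, where Q is
  Cochran's heterogeneity statistic; an additive (DerSimonian–Laird) variant
  is available behind a flag.
* ``egger`` — the same regression with a free intercept; the intercept
  estimates average directional pleiotropy and the slope is a
  pleiotropy-robust causal estimate under the InSIDE assumption.
* ``weighted_median`` — the weight-interpolated median of the Wald ratios,
  consistent when at least half the total weight comes from valid
  instruments; its standard error comes from a parametric bootstrap.

Estimates are on the scale (outcome units per exposure unit), here log-OR
per mm Hg; ``scale_to_or`` re-expresses them as odds ratios per k-unit
*decrease* in the exposure (k = 10 for SBP, 5 for DBP, 0.5 for SD-scale
exposures).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .harmonize import HarmonizedInstrument

DEFAULT_LEVEL = 0.95


class InsufficientInstrumentsError(ValueError):
    pass


@dataclass(frozen=True)
class MREstimate:
    method: str
    theta_hat: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_variants: int
    level: float = DEFAULT_LEVEL


@dataclass(frozen=True)
class HeterogeneityResult:
    Q: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class EggerResult:
    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_p: float


@dataclass(frozen=True)
class ScaledResult:
    """Odds ratios per k-unit *decrease* in the exposure."""

    or_point: float
    or_low: float
    or_high: float
    k: float
    note: str = "OR per k-unit decrease in exposure"


def _as_arrays(hs: Sequence[HarmonizedInstrument] | pd.DataFrame):
    if isinstance(hs, pd.DataFrame):
        return (
            hs["beta_exp"].to_numpy(float),
            hs["se_exp"].to_numpy(float),
            hs["beta_out"].to_numpy(float),
            hs["se_out"].to_numpy(float),
        )
    return (
        np.array([h.beta_exp for h in hs], float),
        np.array([h.se_exp for h in hs], float),
        np.array([h.beta_out for h in hs], float),
        np.array([h.se_out for h in hs], float),
    )


def _normal_ci(theta: float, se: float, level: float):
    z = sps.norm.ppf(0.5 + level / 2)
    return theta - z * se, theta + z * se


def _normal_p(theta: float, se: float) -> float:
    if se == 0:
        return 0.0 if theta != 0 else 1.0
    return float(2 * sps.norm.sf(abs(theta) / se))


def wald_ratio(h: HarmonizedInstrument, level: float = DEFAULT_LEVEL) -> MREstimate:
    """Single-variant causal estimate: θ = β_Y/β_X, se = se_Y/|β_X|
    (first-order delta method, exposure sampling error ignored)."""
    if h.beta_exp == 0:
        raise InsufficientInstrumentsError(f"{h.rsid}: beta_exp is 0")
    theta = h.beta_out / h.beta_exp
    se = h.se_out / abs(h.beta_exp)
    lo, hi = _normal_ci(theta, se, level)
    return MREstimate("wald_ratio", theta, se, lo, hi, _normal_p(theta, se), 1, level)


def ivw(
    hs: Sequence[HarmonizedInstrument] | pd.DataFrame,
    random_effects: bool = True,
    additive: bool = False,
    level: float = DEFAULT_LEVEL,
) -> tuple[MREstimate, HeterogeneityResult]:
    """Inverse-variance-weighted causal estimate plus Cochran's Q.

    With w_j = β_Xj²/se_Yj² and θ_j = β_Yj/β_Xj:
    θ̂ = Σ w_j θ_j / Σ w_j;  fixed-effect se = (Σ w_j)^(-1/2);
    Q = Σ w_j (θ_j − θ̂)², df = J−1.  The default random-effects model is
    multiplicative (se inflated by max(1, sqrt(Q/df))); ``additive=True``
    uses DerSimonian–Laird between-variant variance instead.
    """
    bx, _, by, sy = _as_arrays(hs)
    J = len(bx)
    if J < 2:
        raise InsufficientInstrumentsError("IVW needs >= 2 instruments; use wald_ratio")
    theta_j = by / bx
    w = bx**2 / sy**2
    theta = float(np.sum(w * theta_j) / np.sum(w))
    se_fe = float(np.sum(w) ** -0.5)
    Q = float(np.sum(w * (theta_j - theta) ** 2))
    df = J - 1
    het = HeterogeneityResult(Q, df, float(sps.chi2.sf(Q, df)))

    if not random_effects:
        se = se_fe
    elif additive:
        # DerSimonian–Laird: tau² from Q, re-weight
        c = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (Q - df) / c)
        w_re = 1.0 / (1.0 / w + tau2)
        theta = float(np.sum(w_re * theta_j) / np.sum(w_re))
        se = float(np.sum(w_re) ** -0.5)
    else:
        se = se_fe * max(1.0, np.sqrt(Q / df))

    method = "ivw_mre" if random_effects and not additive else (
        "ivw_dl" if random_effects else "ivw_fe"
    )
    lo, hi = _normal_ci(theta, se, level)
    return (
        MREstimate(method, theta, se, lo, hi, _normal_p(theta, se), J, level),
        het,
    )


def egger(
    hs: Sequence[HarmonizedInstrument] | pd.DataFrame,
    level: float = DEFAULT_LEVEL,
    t_dist: bool = False,
) -> EggerResult:
    """MR-Egger regression: weighted fit of β_Y on β_X with free intercept.

    Instruments are first oriented so every β_X >= 0 (both betas flipped
    where needed; the fit is invariant to the unflipped gauge only up to
    the intercept, so the conventional positive-exposure orientation is
    imposed).  Weights are 1/se_Y².  Standard errors are inflated by the
    weighted residual standard deviation with J−2 df, floored at 1.  Wald
    tests use normal quantiles by default; ``t_dist=True`` switches to
    t(J−2).
    """
    bx, _, by, sy = _as_arrays(hs)
    J = len(bx)
    if J < 3:
        raise InsufficientInstrumentsError("MR-Egger needs >= 3 instruments")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    if np.ptp(bx) == 0:
        raise InsufficientInstrumentsError("zero variance in exposure betas")
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(J), bx])
    XtW = X.T * w
    cov_unscaled = np.linalg.inv(XtW @ X)
    coef = cov_unscaled @ (XtW @ by)
    resid = by - X @ coef
    phi = float(np.sum(w * resid**2) / (J - 2))
    cov = cov_unscaled * max(1.0, phi)
    se_int, se_slope = np.sqrt(np.diag(cov))
    a0, slope = float(coef[0]), float(coef[1])

    if t_dist:
        q = sps.t.ppf(0.5 + level / 2, J - 2)
        p_slope = float(2 * sps.t.sf(abs(slope) / se_slope, J - 2))
        p_int = float(2 * sps.t.sf(abs(a0) / se_int, J - 2))
    else:
        q = sps.norm.ppf(0.5 + level / 2)
        p_slope = _normal_p(slope, se_slope)
        p_int = _normal_p(a0, se_int)

    est = MREstimate(
        "egger", slope, float(se_slope),
        slope - q * se_slope, slope + q * se_slope,
        p_slope, J, level,
    )
    return EggerResult(est, a0, float(se_int), p_int)


def egger_heterogeneity(hs) -> HeterogeneityResult:
    """Rucker's Q': weighted residual sum of squares about the Egger fit,
    chi-square with J-2 df."""
    bx, _, by, sy = _as_arrays(hs)
    J = len(bx)
    res = egger(hs)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    resid = by - res.intercept - res.slope.theta_hat * bx
    Q = float(np.sum(resid**2 / sy**2))
    df = J - 2
    return HeterogeneityResult(Q, df, float(sps.chi2.sf(Q, df)))


def weighted_median_point(theta_j: np.ndarray, w: np.ndarray) -> float:
    """Weight-interpolated median of ordered ratio estimates.

    With sorted θ_(1) <= ... <= θ_(J) and running weight sums S_j, the
    cumulative percentile of θ_(j) is p_j = (S_j − w_j/2)/S_J; the estimate
    interpolates θ linearly across p at 0.5.
    """
    order = np.argsort(theta_j, kind="stable")
    t = theta_j[order]
    ww = w[order]
    S = np.cumsum(ww)
    p = (S - ww / 2) / S[-1]
    return float(np.interp(0.5, p, t))


def weighted_median(
    hs: Sequence[HarmonizedInstrument] | pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = DEFAULT_LEVEL,
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap se.

    Weights are the inverse-variance weights β_X²/se_Y² of the ratio
    estimates.  The bootstrap resamples θ_j ~ Normal(θ_j, se_j²) with
    se_j = se_Yj/|β_Xj| and takes the standard deviation of the recomputed
    medians; the seed is mandatory so results are reproducible.
    """
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    bx, _, by, sy = _as_arrays(hs)
    J = len(bx)
    if J < 3:
        raise InsufficientInstrumentsError("weighted median needs >= 3 instruments")
    theta_j = by / bx
    se_j = sy / np.abs(bx)
    w = bx**2 / sy**2
    theta = weighted_median_point(theta_j, w)

    rng = np.random.default_rng(seed)
    draws = rng.normal(theta_j, se_j, size=(n_boot, J))
    boots = np.array([weighted_median_point(d, w) for d in draws])
    se = float(boots.std(ddof=1))
    lo, hi = _normal_ci(theta, se, level)
    return MREstimate("weighted_median", theta, se, lo, hi, _normal_p(theta, se), J, level)


def scale_to_or(est: MREstimate, k: float, level: float | None = None) -> ScaledResult:
    """Re-express a log-OR-per-unit slope as an OR per k-unit *decrease*.

    or_point = exp(−k·θ̂); CI bounds map exp(−k·(θ̂ ± z·se)) and are
    re-ordered.  The negation encodes the convention of reporting effects
    of exposure reduction (e.g. per 10 mm Hg lower SBP).
    """
    level = est.level if level is None else level
    z = sps.norm.ppf(0.5 + level / 2)
    point = float(np.exp(-k * est.theta_hat))
    b1 = float(np.exp(-k * (est.theta_hat - z * est.se)))
    b2 = float(np.exp(-k * (est.theta_hat + z * est.se)))
    lo, hi = min(b1, b2), max(b1, b2)
    return ScaledResult(point, lo, hi, k)


def sd_scale(est: MREstimate, half_sd: bool = True) -> ScaledResult:
    """Scale an SD-unit exposure estimate to a half-SD (or full-SD) decrease."""
    k = 0.5 if half_sd else 1.0
    out = scale_to_or(est, k)
    return ScaledResult(out.or_point, out.or_low, out.or_high, k,
                        note="OR per half-SD decrease" if half_sd else "OR per SD decrease")


def bonferroni_flag(pvalues: Sequence[float], alpha: float) -> list[bool]:
    """Strict comparison against a Bonferroni-corrected threshold."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    return [p < alpha for p in pvalues]
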