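"""Univariable two-sample MR estimators and instrument diagnostics.

All estimators consume an :class:`~mrscreen.types.InstrumentSet` of
harmonized per-variant effects (beta_exp, se_exp, beta_out, se_out).
The primary analysis is the random-effects inverse-variance weighted
(IVW) estimator; MR-Egger, the weighted median and MR-PRESSO serve as
pleiotropy-robust sensitivity analyses, MR-Steiger tests directionality
and the F-statistic / relative-bias pair quantifies instrument strength
and sample-overlap bias.

Conventions: normal reference distribution for Wald-ratio, IVW and
weighted-median p-values; t with k-2 df for Egger; random-effects
uncertainty by multiplicative overdispersion (SE scaled by
sqrt(max(1, Q/(k-1)))) as in the standard two-sample MR tooling.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import (
    ConfigurationError,
    DirectionalityResult,
    InstrumentSet,
    InsufficientInstrumentsError,
    MREstimate,
    StrengthResult,
)

_Z95 = stats.norm.ppf(0.975)


def _two_sided_normal_p(z: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def _ratios(inst: InstrumentSet) -> Tuple[np.ndarray, np.ndarray]:
    """Per-variant Wald ratios and their first-order delta-method SEs."""
    bx, sy, by = inst.beta_exp, inst.se_out, inst.beta_out
    if np.any(bx == 0):
        raise ConfigurationError("zero exposure beta: Wald ratio undefined")
    return by / bx, sy / np.abs(bx)


def wald_ratio(
    beta_exp: float, se_exp: float, beta_out: float, se_out: float
) -> MREstimate:
    """Single-instrument causal estimate beta_out / beta_exp.

    The SE is the first-order delta-method approximation se_out/|beta_exp|,
    which ignores the exposure-side uncertainty.
    """
    if beta_exp == 0:
        raise ConfigurationError("Wald ratio undefined for beta_exp = 0")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return MREstimate(
        method="wald_ratio",
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - _Z95 * se),
        ci_high=float(beta + _Z95 * se),
        pval=_two_sided_normal_p(beta / se),
        n_snps=1,
    )


def heterogeneity(inst: InstrumentSet) -> Tuple[float, float]:
    """Cochran's Q over per-variant ratios and the I^2 percentage.

    Q = sum_j w_j (ratio_j - beta_fixed)^2 with w_j = 1/se_ratio_j^2 and
    beta_fixed the fixed-effect IVW estimate; I^2 = max(0, (Q-(k-1))/Q)*100.
    """
    if len(inst) < 2:
        raise InsufficientInstrumentsError("heterogeneity needs >= 2 instruments")
    r, se_r = _ratios(inst)
    w = 1.0 / se_r**2
    beta_fixed = float(np.sum(w * r) / np.sum(w))
    Q = float(np.sum(w * (r - beta_fixed) ** 2))
    k = len(r)
    i2 = max(0.0, (Q - (k - 1)) / Q) * 100.0 if Q > 0 else 0.0
    return Q, i2


def ivw_random_effects(inst: InstrumentSet) -> MREstimate:
    """Random-effects IVW estimate: weighted regression through the origin.

    beta = sum w_j bX_j bY_j / sum w_j bX_j^2 with w_j = 1/se_out_j^2.
    The fixed-effect SE is inflated by sqrt(max(1, Q/(k-1))) so that
    under-dispersion never shrinks the interval.
    """
    k = len(inst)
    if k < 2:
        raise InsufficientInstrumentsError(
            "IVW needs >= 2 instruments; use wald_ratio for a single instrument"
        )
    bx, by, sy = inst.beta_exp, inst.beta_out, inst.se_out
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by) / denom)
    se_fixed = float(np.sqrt(1.0 / denom))
    Q, i2 = heterogeneity(inst)
    se = se_fixed * np.sqrt(max(1.0, Q / (k - 1)))
    return MREstimate(
        method="ivw_re",
        beta=beta,
        se=float(se),
        ci_low=float(beta - _Z95 * se),
        ci_high=float(beta + _Z95 * se),
        pval=_two_sided_normal_p(beta / se),
        n_snps=k,
        Q=Q,
        i2=i2,
    )


def ivw_fixed_effects(inst: InstrumentSet) -> MREstimate:
    """Fixed-effect IVW (no overdispersion inflation)."""
    est = ivw_random_effects(inst)
    k = est.n_snps
    se = est.se / np.sqrt(max(1.0, est.Q / (k - 1)))
    return MREstimate(
        method="ivw_fe",
        beta=est.beta,
        se=float(se),
        ci_low=float(est.beta - _Z95 * se),
        ci_high=float(est.beta + _Z95 * se),
        pval=_two_sided_normal_p(est.beta / se),
        n_snps=k,
        Q=est.Q,
        i2=est.i2,
    )


def egger(inst: InstrumentSet) -> MREstimate:
    """MR-Egger: weighted regression of beta_out on beta_exp with intercept.

    Instruments are oriented so all beta_exp >= 0 before fitting (the
    intercept is only meaningful under that orientation).  A non-zero
    intercept indicates directional horizontal pleiotropy; its p-value
    and the slope's use a t reference with k-2 df.  SEs carry the
    multiplicative overdispersion factor sqrt(max(1, RSS_w/(k-2))).
    """
    k = len(inst)
    if k < 3:
        raise InsufficientInstrumentsError("MR-Egger needs >= 3 instruments")
    bx, by, sy = inst.beta_exp.copy(), inst.beta_out.copy(), inst.se_out
    flip = bx < 0
    bx[flip] *= -1
    by[flip] *= -1
    w = 1.0 / sy**2
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    # statsmodels scales the covariance by RSS_w/(k-2); use the unscaled
    # covariance with the one-sided inflation max(1, RSS_w/(k-2)) instead
    scale = float(fit.scale)
    unscaled_se = np.sqrt(np.diag(fit.normalized_cov_params))
    icept, slope = float(fit.params[0]), float(fit.params[1])
    se_icept = float(unscaled_se[0]) * np.sqrt(max(1.0, scale))
    se_slope = float(unscaled_se[1]) * np.sqrt(max(1.0, scale))
    tdist = stats.t(df=k - 2)
    p_slope = float(min(1.0, 2.0 * tdist.sf(abs(slope / se_slope))))
    p_icept = float(min(1.0, 2.0 * tdist.sf(abs(icept / se_icept))))
    Q, i2 = heterogeneity(inst)
    return MREstimate(
        method="egger",
        beta=slope,
        se=se_slope,
        ci_low=float(slope - _Z95 * se_slope),
        ci_high=float(slope + _Z95 * se_slope),
        pval=p_slope,
        n_snps=k,
        Q=Q,
        i2=i2,
        egger_intercept=icept,
        egger_intercept_se=se_icept,
        egger_intercept_pval=p_icept,
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Midpoint-convention weighted median with linear interpolation.

    Sort the ratios; with cumulative weights S_j the breakpoints are
    p_j = (S_j - w_j/2)/S_total; the estimate interpolates the ratio at
    p = 0.5.
    """
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order]
    S = np.cumsum(w)
    p = (S - 0.5 * w) / S[-1]
    if 0.5 <= p[0]:
        return float(r[0])
    if 0.5 >= p[-1]:
        return float(r[-1])
    return float(np.interp(0.5, p, r))


def weighted_median(
    inst: InstrumentSet, n_boot: int = 1000, seed: Optional[int] = None
) -> MREstimate:
    """Weighted-median estimator, consistent when >=50% of weight is valid.

    The point estimate is the 0.5 quantile of the inverse-variance
    weighted distribution of per-variant Wald ratios; the SE comes from
    a seeded parametric bootstrap resampling each ratio from
    normal(ratio, se_ratio) with weights held fixed.
    """
    k = len(inst)
    if k < 3:
        raise InsufficientInstrumentsError("weighted median needs >= 3 instruments")
    r, se_r = _ratios(inst)
    w = 1.0 / se_r**2
    beta = _weighted_median_point(r, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        rb = rng.normal(r, se_r)
        boots[b] = _weighted_median_point(rb, w)
    se = float(np.std(boots, ddof=1))
    return MREstimate(
        method="weighted_median",
        beta=float(beta),
        se=se,
        ci_low=float(beta - _Z95 * se),
        ci_high=float(beta + _Z95 * se),
        pval=_two_sided_normal_p(beta / se) if se > 0 else 1.0,
        n_snps=k,
    )


def _loo_ivw_betas(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW estimates, vectorized."""
    s_xy = np.sum(w * bx * by)
    s_xx = np.sum(w * bx**2)
    return (s_xy - w * bx * by) / (s_xx - w * bx**2)


def presso(
    inst: InstrumentSet,
    n_sim: int = 1000,
    seed: Optional[int] = None,
    outlier_alpha: float = 0.05,
) -> Tuple[float, np.ndarray, Optional[MREstimate]]:
    """MR-PRESSO global pleiotropy test and outlier-corrected estimate.

    The observed residual sum of squares of leave-one-out IVW
    predictions is compared against ``n_sim`` parametric simulations
    under the no-pleiotropy model (outcome betas redrawn around the
    leave-one-out fitted values with the observed SEs).  Per-variant
    contributions give outlier p-values, Bonferroni-corrected across
    variants at ``outlier_alpha``.  The corrected estimate (IVW on
    non-outliers) is returned only when at least one outlier is flagged.

    Returns (global_pval, outlier_flags, corrected_or_None).
    """
    k = len(inst)
    if k < 4:
        raise InsufficientInstrumentsError("MR-PRESSO needs >= 4 instruments")
    bx, by, sy = inst.beta_exp, inst.beta_out, inst.se_out
    w = 1.0 / sy**2
    beta_loo = _loo_ivw_betas(bx, by, w)
    obs_contrib = w * (by - beta_loo * bx) ** 2
    obs_rss = float(np.sum(obs_contrib))

    rng = np.random.default_rng(seed)
    by_sim = rng.normal(beta_loo * bx, sy, size=(n_sim, k))
    s_xy = by_sim @ (w * bx)
    s_xx = float(np.sum(w * bx**2))
    beta_loo_sim = (s_xy[:, None] - (w * bx) * by_sim) / (s_xx - w * bx**2)
    contrib_sim = w * (by_sim - beta_loo_sim * bx) ** 2
    rss_sim = contrib_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= obs_rss)) / (1 + n_sim))
    p_var = (1 + np.sum(contrib_sim >= obs_contrib, axis=0)) / (1 + n_sim)
    flags = p_var < outlier_alpha / k

    corrected = None
    if flags.any() and (~flags).sum() >= 2:
        sub = InstrumentSet(
            inst.exposure_id, inst.outcome_id, inst.df.loc[~flags].copy()
        )
        corrected = ivw_random_effects(sub)
        corrected.method = "presso_corrected"
    return global_p, flags, corrected


def steiger(
    inst: InstrumentSet, n_exposure: int, n_outcome: int
) -> DirectionalityResult:
    """MR-Steiger directionality test.

    Per-variant correlations come from the t-statistic transform
    r = t/sqrt(t^2 + n - 2); instrument r^2 is summed per trait (binary
    outcomes are taken on the observed log-odds scale).  The causal
    direction is called correct when the instruments explain more
    variance in the exposure than in the outcome; the p-value compares
    the two Fisher-z-transformed summed correlations.
    """
    if n_exposure <= 3 or n_outcome <= 3:
        raise ConfigurationError("Steiger needs sample sizes > 3")
    tx = inst.beta_exp / inst.se_exp
    ty = inst.beta_out / inst.se_out
    rx2 = np.sum(tx**2 / (tx**2 + n_exposure - 2))
    ry2 = np.sum(ty**2 / (ty**2 + n_outcome - 2))
    rx = np.sqrt(min(rx2, 1.0))
    ry = np.sqrt(min(ry2, 1.0))
    z = (np.arctanh(min(rx, 0.999999)) - np.arctanh(min(ry, 0.999999))) / np.sqrt(
        1.0 / (n_exposure - 3) + 1.0 / (n_outcome - 3)
    )
    return DirectionalityResult(
        r2_exposure=float(rx2),
        r2_outcome=float(ry2),
        correct_direction=bool(rx2 > ry2),
        steiger_pval=_two_sided_normal_p(z),
    )


def instrument_strength(inst: InstrumentSet, phi: float = 0.0) -> StrengthResult:
    """Instrument F-statistics and the sample-overlap relative bias phi/F.

    Per-variant F = (beta_exp/se_exp)^2; the set-level F is their mean.
    ``phi`` is the proportion of overlapping samples between the
    exposure and outcome GWAS.
    """
    if not 0.0 <= phi <= 1.0:
        raise ConfigurationError(f"phi must be in [0, 1], got {phi}")
    per_f = (inst.beta_exp / inst.se_exp) ** 2
    f_set = float(np.mean(per_f))
    rel_bias = phi / f_set if f_set > 0 else float("inf") * (phi or 0.0)
    if phi == 0.0:
        rel_bias = 0.0
    return StrengthResult(
        f_statistic=f_set, per_variant_f=per_f, relative_bias=float(rel_bias)
    )


def relative_bias(phi: float, f_statistic: float) -> float:
    """Sample-overlap relative bias: phi * 1/F."""
    if not 0.0 <= phi <= 1.0:
        raise ConfigurationError(f"phi must be in [0, 1], got {phi}")
    if phi == 0.0:
        return 0.0
    return phi / f_statistic


def estimates_to_frame(records) -> pd.DataFrame:
    """Flatten (exposure_id, outcome_id, MREstimate) triples to a table."""
    rows = []
    for exposure_id, outcome_id, est in records:
        d = {"exposure_id": exposure_id, "outcome_id": outcome_id}
        d.update(est.to_dict())
        rows.append(d)
    return pd.DataFrame(rows)


def estimates_from_frame(df: pd.DataFrame):
    """Inverse of :func:`estimates_to_frame`."""
    out = []
    for _, row in df.iterrows():
        est = MREstimate(
            method=row["method"],
            beta=row["beta"],
            se=row["se"],
            ci_low=row["ci_low"],
            ci_high=row["ci_high"],
            pval=row["pval"],
            n_snps=int(row["n_snps"]),
            Q=row["Q"],
            i2=row["i2"],
            egger_intercept=row["egger_intercept"],
            egger_intercept_se=row["egger_intercept_se"],
            egger_intercept_pval=row["egger_intercept_pval"],
        )
        out.append((row["exposure_id"], row["outcome_id"], est))
    return out
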