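"""Multivariable MR: joint exposures and conditional instrument strength.

Estimates the direct effect of each exposure on the outcome, holding
the other exposures fixed, by inverse-variance weighted regression of
the outcome betas on the matrix of exposure betas (no intercept).
Conditional F-statistics follow the Q-based construction: each
exposure's instrument effects are regressed on the other exposures'
effects and the residual heterogeneity, weighted by the delta-method
variance under the supplied phenotypic correlation, is converted to an
F-scale statistic.  F > 10 is the conventional adequate-strength bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import (
    CollinearExposuresError,
    ConfigurationError,
    InsufficientInstrumentsError,
    MREstimate,
)

_Z95 = stats.norm.ppf(0.975)


@dataclass
class MVInstrumentSet:
    """Harmonized instruments for E >= 1 exposures against one outcome.

    ``beta_exp``/``se_exp`` are (k, E) arrays (one column per exposure);
    ``beta_out``/``se_out`` are length-k vectors.
    """

    outcome_id: str
    exposure_ids: List[str]
    variant_ids: List[str]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray

    def __post_init__(self) -> None:
        self.beta_exp = np.atleast_2d(np.asarray(self.beta_exp, float))
        self.se_exp = np.atleast_2d(np.asarray(self.se_exp, float))
        if self.beta_exp.shape[0] == 1 and len(self.variant_ids) > 1:
            self.beta_exp = self.beta_exp.T
            self.se_exp = self.se_exp.T
        self.beta_out = np.asarray(self.beta_out, float)
        self.se_out = np.asarray(self.se_out, float)
        k, E = self.beta_exp.shape
        if E != len(self.exposure_ids):
            raise ConfigurationError("beta_exp columns must match exposure_ids")
        if k != len(self.variant_ids) or len(self.beta_out) != k:
            raise ConfigurationError("row count mismatch in MVInstrumentSet")
        if np.any(~np.isfinite(self.beta_exp)):
            raise ConfigurationError("missing exposure betas are not allowed")
        if np.any(self.se_exp <= 0) or np.any(self.se_out <= 0):
            raise ConfigurationError("all standard errors must be positive")
        if k < E + 1:
            raise InsufficientInstrumentsError(
                f"multivariable MR needs at least E+1 = {E + 1} variants, got {k}"
            )

    @property
    def n_exposures(self) -> int:
        return len(self.exposure_ids)

    def __len__(self) -> int:
        return len(self.variant_ids)

    def to_frame(self) -> pd.DataFrame:
        """Wide table: one beta/se column pair per exposure."""
        data = {"variant_id": self.variant_ids}
        for e, eid in enumerate(self.exposure_ids):
            data[f"beta_{eid}"] = self.beta_exp[:, e]
            data[f"se_{eid}"] = self.se_exp[:, e]
        data["beta_out"] = self.beta_out
        data["se_out"] = self.se_out
        return pd.DataFrame(data)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, outcome_id: str, exposure_ids: List[str]
    ) -> "MVInstrumentSet":
        return cls(
            outcome_id=outcome_id,
            exposure_ids=exposure_ids,
            variant_ids=df["variant_id"].tolist(),
            beta_exp=np.column_stack([df[f"beta_{e}"] for e in exposure_ids]),
            se_exp=np.column_stack([df[f"se_{e}"] for e in exposure_ids]),
            beta_out=df["beta_out"].to_numpy(float),
            se_out=df["se_out"].to_numpy(float),
        )


def _check_rank(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearExposuresError(
            "exposure beta matrix is rank deficient (collinear exposures)"
        )


def mvmr_ivw(inst: MVInstrumentSet) -> List[MREstimate]:
    """Random-effects multivariable IVW: one direct effect per exposure.

    Weighted least squares of beta_out on the exposure beta columns with
    weights 1/se_out^2 and no intercept; SEs carry the multiplicative
    overdispersion factor sqrt(max(1, Q/(k-E))) from the multivariable
    heterogeneity statistic.
    """
    X = inst.beta_exp
    _check_rank(X)
    k, E = X.shape
    w = 1.0 / inst.se_out**2
    fit = sm.WLS(inst.beta_out, X, weights=w).fit()
    resid = inst.beta_out - X @ fit.params
    Q = float(np.sum(w * resid**2))
    dof = k - E
    scale = float(fit.scale)  # = Q / (k - E)
    unscaled_se = np.sqrt(np.diag(fit.normalized_cov_params))
    i2 = max(0.0, (Q - dof) / Q) * 100.0 if Q > 0 else 0.0
    out = []
    for e in range(E):
        beta = float(fit.params[e])
        se = float(unscaled_se[e]) * np.sqrt(max(1.0, scale))
        z = beta / se
        out.append(
            MREstimate(
                method="mvmr_ivw",
                beta=beta,
                se=se,
                ci_low=beta - _Z95 * se,
                ci_high=beta + _Z95 * se,
                pval=float(min(1.0, 2.0 * stats.norm.sf(abs(z)))),
                n_snps=k,
                Q=Q,
                i2=i2,
            )
        )
    return out


def mvmr_egger(inst: MVInstrumentSet) -> List[MREstimate]:
    """Multivariable MR-Egger: weighted LS with an intercept.

    Instruments are oriented so the first exposure's betas are all
    non-negative before fitting; the shared intercept (directional
    pleiotropy) is attached to every returned estimate.
    """
    X = inst.beta_exp.copy()
    y = inst.beta_out.copy()
    flip = X[:, 0] < 0
    X[flip] *= -1
    y[flip] *= -1
    _check_rank(X)
    k, E = X.shape
    if k < E + 2:
        raise InsufficientInstrumentsError("multivariable Egger needs >= E+2 variants")
    w = 1.0 / inst.se_out**2
    Xc = sm.add_constant(X)
    fit = sm.WLS(y, Xc, weights=w).fit()
    scale = float(fit.scale)
    unscaled_se = np.sqrt(np.diag(fit.normalized_cov_params))
    infl = np.sqrt(max(1.0, scale))
    tdist = stats.t(df=k - E - 1)
    icept = float(fit.params[0])
    se_icept = float(unscaled_se[0]) * infl
    p_icept = float(min(1.0, 2.0 * tdist.sf(abs(icept / se_icept))))
    out = []
    for e in range(E):
        beta = float(fit.params[e + 1])
        se = float(unscaled_se[e + 1]) * infl
        out.append(
            MREstimate(
                method="mvmr_egger",
                beta=beta,
                se=se,
                ci_low=beta - _Z95 * se,
                ci_high=beta + _Z95 * se,
                pval=float(min(1.0, 2.0 * tdist.sf(abs(beta / se)))),
                n_snps=k,
                egger_intercept=icept,
                egger_intercept_se=se_icept,
                egger_intercept_pval=p_icept,
            )
        )
    return out


def conditional_f(
    inst: MVInstrumentSet, exposure_correlation: Optional[np.ndarray] = None
) -> List[float]:
    """Conditional F-statistic per exposure (Q-based construction).

    For exposure e, its instrument betas are regressed on the remaining
    exposures' betas; the residual heterogeneity
    Q_e = sum_j w_j (beta_ej - fitted_j)^2, with delta-method weights
    from the exposures' SEs and their phenotypic correlation matrix
    (identity when not supplied), is scaled to F_e = Q_e / (k - E + 1).
    Orthogonal, individually strong exposures give F close to the
    unconditional mean-F; collinear exposures give F near 0.
    """
    X = inst.beta_exp
    S = inst.se_exp
    k, E = X.shape
    if exposure_correlation is None:
        C = np.eye(E)
    else:
        C = np.asarray(exposure_correlation, float)
        if C.shape != (E, E) or not np.allclose(C, C.T, atol=1e-8):
            raise ConfigurationError("exposure correlation must be symmetric ExE")
        if np.any(np.diag(C) != 1.0) or np.linalg.eigvalsh(C).min() < -1e-8:
            raise ConfigurationError("exposure correlation must be PSD with unit diagonal")
    if E == 1:
        per_f = (X[:, 0] / S[:, 0]) ** 2
        return [float(np.mean(per_f))]
    out = []
    for e in range(E):
        others = [o for o in range(E) if o != e]
        Xo = X[:, others]
        if np.linalg.matrix_rank(Xo) < len(others):
            raise ConfigurationError(
                "singular weighting: other exposures' betas are collinear"
            )
        # initial coefficients via unweighted LS, then one delta-method reweight
        g, *_ = np.linalg.lstsq(Xo, X[:, e], rcond=None)
        for _ in range(2):
            var = S[:, e] ** 2
            for i, o in enumerate(others):
                var = var + g[i] ** 2 * S[:, o] ** 2
                var = var - 2.0 * g[i] * C[e, o] * S[:, e] * S[:, o]
            for i, o1 in enumerate(others):
                for j, o2 in enumerate(others):
                    if i != j:
                        var = var + g[i] * g[j] * C[o1, o2] * S[:, o1] * S[:, o2]
            var = np.maximum(var, 1e-300)
            wq = 1.0 / var
            WX = Xo * wq[:, None]
            try:
                g = np.linalg.solve(Xo.T @ WX, WX.T @ X[:, e])
            except np.linalg.LinAlgError as exc:
                raise ConfigurationError(f"singular weighting: {exc}") from exc
        resid = X[:, e] - Xo @ g
        Q_e = float(np.sum(wq * resid**2))
        out.append(Q_e / (k - E + 1))
    return out
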