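"""Summary-statistics fine-mapping with the sum-of-single-effects model.

Fits L additive single-effect components to a region's z-scores and LD
matrix by iterative Bayesian stepwise selection: each component is a
Bayesian single-effect regression on the residual z-scores (other
components subtracted through the LD matrix), giving a posterior
distribution alpha_l over which variant carries that effect.  Per-variant
posterior inclusion probability is PIP_j = 1 - prod_l (1 - alpha_lj);
each component yields a level-``coverage`` credible set (smallest variant
set with summed alpha >= coverage), discarded when its within-set LD
purity falls below a threshold.

The model works on the z-score scale with unit residual variance — the
standard regression-with-summary-statistics approximation
z ~ N(R * zeta, R).
"""

from __future__ import annotations

from typing import List, Optional, Union

import numpy as np
from scipy import optimize
from scipy.special import logsumexp

from .types import (
    ConfigurationError,
    CredibleSet,
    FineMapResult,
    LDPanel,
    MRScreenError,
    RegionAssociations,
)


class NumericalConditioningError(MRScreenError):
    """The LD matrix is not positive semi-definite after regularization."""


def _log_bf(z_res: np.ndarray, W: float) -> np.ndarray:
    """Wakefield log Bayes factors with unit observation variance."""
    r = W / (W + 1.0)
    return 0.5 * np.log1p(-r) + 0.5 * z_res**2 * r


def _optimize_prior_variance(z_res: np.ndarray, log_pi: np.ndarray) -> float:
    """Maximize the single-effect marginal likelihood over the prior variance.

    Returns the maximizing W >= 0 (0 means the component carries no
    signal at this iteration).
    """
    def neg_loglik(logW: float) -> float:
        return -float(logsumexp(log_pi + _log_bf(z_res, np.exp(logW))))

    hi = max(float(np.max(z_res**2)), 1.0) * 2.0
    res = optimize.minimize_scalar(
        neg_loglik, bounds=(np.log(1e-6), np.log(hi)), method="bounded",
        options={"xatol": 1e-6},
    )
    W = float(np.exp(res.x))
    # accept only if better than the null model (W = 0, loglik = 0)
    if -res.fun <= 0.0:
        return 0.0
    return W


def finemap_susie(
    region: RegionAssociations,
    ld: LDPanel,
    L: int = 5,
    coverage: float = 0.95,
    prior_sd: Union[float, str] = "auto",
    max_iter: int = 100,
    tol: float = 1e-6,
    purity_threshold: float = 0.5,
    ridge: float = 1e-6,
) -> FineMapResult:
    """Fine-map a region: per-variant PIPs and level-``coverage`` credible sets.

    Parameters
    ----------
    region
        Marginal associations (beta, se) for the region's variants.
    ld
        Signed LD correlations covering all region variants.
    L
        Maximum number of causal variants modelled (default 5).
    prior_sd
        ``"auto"`` estimates each component's prior effect variance by
        maximizing its single-effect likelihood (a component whose
        estimate is 0 is treated as null and yields no credible set);
        a float fixes the prior SD on the trait's effect scale, converted
        per variant through its standard error.
    purity_threshold
        Minimum absolute within-set LD correlation for a credible set to
        be reported.

    Raises
    ------
    NumericalConditioningError
        When the LD matrix remains non-PSD after the ridge
        regularization; increase ``ridge``.
    """
    if L < 1:
        raise ConfigurationError("L must be >= 1")
    ids = list(region.df.index)
    p = len(ids)
    R = ld.subset(ids).r.copy()
    R[np.diag_indices(p)] += ridge
    eigmin = float(np.linalg.eigvalsh(R).min())
    if eigmin < -1e-8:
        raise NumericalConditioningError(
            f"LD matrix min eigenvalue {eigmin:.3e} after ridge {ridge}; "
            "add a larger ridge"
        )
    z = region.z
    se = region.df["se"].to_numpy(float)
    log_pi = np.full(p, -np.log(p))

    fixed_W = None
    if prior_sd != "auto":
        fixed_W = (float(prior_sd) / se) ** 2  # per-variant, z-score scale

    alpha = np.full((L, p), 1.0 / p)
    mu = np.zeros((L, p))
    active = np.zeros(L, dtype=bool)
    pip_prev = np.zeros(p)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for l in range(L):
            b_others = (alpha * mu).sum(axis=0) - alpha[l] * mu[l]
            z_res = z - R @ b_others
            if fixed_W is not None:
                W = fixed_W
                active[l] = True
            else:
                W = _optimize_prior_variance(z_res, log_pi)
                active[l] = W > 0.0
                if W == 0.0:
                    alpha[l] = 1.0 / p
                    mu[l] = 0.0
                    continue
            lbf = _log_bf(z_res, W)
            la = log_pi + lbf
            alpha[l] = np.exp(la - logsumexp(la))
            shrink = W / (W + 1.0)
            mu[l] = shrink * z_res
        pip = 1.0 - np.prod(1.0 - alpha, axis=0)
        if np.max(np.abs(pip - pip_prev)) < tol:
            converged = True
            break
        pip_prev = pip

    pip = 1.0 - np.prod(1.0 - alpha, axis=0)
    sets: List[CredibleSet] = []
    seen = set()
    for l in range(L):
        if not active[l]:
            continue
        order = np.argsort(-alpha[l], kind="mergesort")
        csum = np.cumsum(alpha[l][order])
        size = int(np.searchsorted(csum, coverage) + 1)
        size = min(size, p)
        members = order[:size]
        attained = float(csum[size - 1])
        if attained < coverage:
            continue  # component too diffuse to reach the target coverage
        sub = R[np.ix_(members, members)]
        min_abs = float(np.min(np.abs(sub))) if size > 1 else 1.0
        if min_abs < purity_threshold:
            continue
        key = tuple(sorted(int(m) for m in members))
        if key in seen:
            continue
        seen.add(key)
        sets.append(
            CredibleSet(
                variant_ids=[ids[int(m)] for m in members],
                coverage=attained,
                min_abs_corr=min_abs,
            )
        )
    return FineMapResult(
        variant_ids=ids,
        pip=pip,
        credible_sets=sets,
        L=L,
        coverage=coverage,
        purity_threshold=purity_threshold,
        converged=converged,
        n_iter=n_iter,
    )


def pip_frame(result: FineMapResult):
    """Per-variant PIP table with credible-set membership labels."""
    import pandas as pd

    cs_label = {}
    for i, cs in enumerate(result.credible_sets, start=1):
        for v in cs.variant_ids:
            cs_label[v] = i
    return pd.DataFrame(
        {
            "variant_id": result.variant_ids,
            "pip": result.pip,
            "credible_set": [cs_label.get(v, 0) for v in result.variant_ids],
        }
    )
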