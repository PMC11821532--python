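"""Bayesian colocalization of two traits in a genomic region.

Enumerates the five hypotheses of the single-causal-variant model —
H0 (neither trait associated), H1/H2 (only one trait), H3 (both traits,
distinct causal variants), H4 (both traits, one shared causal variant) —
from per-variant Wakefield approximate Bayes factors, with all
hypothesis arithmetic in log space so strong regions cannot overflow.

Defaults follow the conventional priors p1 = p2 = 1e-4, p12 = 1e-5 and
effect-size prior SDs of 0.15 (quantitative, per-SD) and 0.2 (binary,
log-odds).
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .types import ColocResult, ConfigurationError, EmptyInputError, RegionAssociations

DEFAULT_PRIOR_SD = {"quantitative": 0.15, "binary": 0.2}


def wakefield_abf(beta, se, prior_sd: float):
    """Log approximate Bayes factor for association versus the null.

    With z = beta/se, V = se^2, W = prior_sd^2 and r = W/(W+V):
    log ABF = 0.5*log(1-r) + 0.5*z^2*r.  Positive values favour
    association; beta = 0 gives the (negative) null evidence
    0.5*log(1-r).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0) or prior_sd <= 0:
        raise ConfigurationError("se and prior_sd must be positive")
    z = beta / se
    V = se**2
    W = prior_sd**2
    r = W / (W + V)
    return 0.5 * np.log1p(-r) + 0.5 * z**2 * r


def _log_diff_exp(log_a: float, log_b: float) -> float:
    """log(exp(log_a) - exp(log_b)) for log_a >= log_b, -inf-safe."""
    if log_b == -np.inf:
        return log_a
    if log_b >= log_a:
        return -np.inf
    return log_a + np.log1p(-np.exp(log_b - log_a))


def coloc_abf(
    a: RegionAssociations,
    b: RegionAssociations,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd_a: float | None = None,
    prior_sd_b: float | None = None,
) -> ColocResult:
    """Five-hypothesis colocalization posterior for two traits.

    Variants are intersected on id; per-variant log ABFs are combined
    into hypothesis sums (H3's sum over ordered distinct pairs is
    computed as the product of the marginal sums minus the shared-pair
    sum, all in log space) and normalized with the supplied priors.
    PP.H4 is the posterior probability of one shared causal variant.
    """
    for p in (p1, p2, p12):
        if not 0 < p < 1:
            raise ConfigurationError("priors must be in (0, 1)")
    common = [v for v in a.df.index if v in set(b.df.index)]
    if not common:
        raise EmptyInputError("no shared variants between the two traits")
    da, db = a.df.loc[common], b.df.loc[common]
    sd_a = prior_sd_a if prior_sd_a is not None else DEFAULT_PRIOR_SD[a.trait_type]
    sd_b = prior_sd_b if prior_sd_b is not None else DEFAULT_PRIOR_SD[b.trait_type]
    l1 = wakefield_abf(da["beta"].to_numpy(), da["se"].to_numpy(), sd_a)
    l2 = wakefield_abf(db["beta"].to_numpy(), db["se"].to_numpy(), sd_b)

    lsum1 = logsumexp(l1)
    lsum2 = logsumexp(l2)
    lsum12 = logsumexp(l1 + l2)
    # sum over i != j of exp(l1_i + l2_j) = (sum e^l1)(sum e^l2) - sum e^(l1+l2)
    lh3_core = _log_diff_exp(lsum1 + lsum2, lsum12)

    lH0 = 0.0
    lH1 = np.log(p1) + lsum1
    lH2 = np.log(p2) + lsum2
    lH3 = np.log(p1) + np.log(p2) + lh3_core
    lH4 = np.log(p12) + lsum12
    logs = np.array([lH0, lH1, lH2, lH3, lH4])
    post = np.exp(logs - logsumexp(logs))
    post /= post.sum()
    return ColocResult(
        pp_h0=float(post[0]),
        pp_h1=float(post[1]),
        pp_h2=float(post[2]),
        pp_h3=float(post[3]),
        pp_h4=float(post[4]),
        p1=p1,
        p2=p2,
        p12=p12,
        n_variants=len(common),
    )


def coloc_to_frame(result: ColocResult):
    """One-row table of a colocalization posterior (round-trippable)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "pp_h0": result.pp_h0,
                "pp_h1": result.pp_h1,
                "pp_h2": result.pp_h2,
                "pp_h3": result.pp_h3,
                "pp_h4": result.pp_h4,
                "p1": result.p1,
                "p2": result.p2,
                "p12": result.p12,
                "n_variants": result.n_variants,
            }
        ]
    )
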