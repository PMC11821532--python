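"""Core containers shared across the package.

GWAS summary statistics are held as pandas DataFrames wrapped in light
dataclasses that enforce the row-level invariants once, on construction,
so downstream numerics can assume clean inputs (positive standard errors,
valid p-values, unique variant identifiers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")

#: Columns every summary-statistics table carries, in canonical order.
SUMSTAT_COLUMNS = [
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
    "eaf",
    "n",
]


class MRScreenError(Exception):
    """Base class for package errors."""


class ConfigurationError(MRScreenError):
    """A parameter or column mapping is invalid."""


class EmptyInputError(MRScreenError):
    """An operation received no usable rows."""


class DuplicateVariantError(MRScreenError):
    """A summary-statistics table contains a repeated variant id."""


class NoLDInformationError(MRScreenError):
    """The LD panel has no entry for a query variant (distinct from 'no proxy')."""


class InsufficientInstrumentsError(MRScreenError):
    """An estimator was called with fewer instruments than it requires."""


class CollinearExposuresError(MRScreenError):
    """The multivariable exposure design matrix is rank deficient."""


def _validate_sumstat_row(row: pd.Series) -> Optional[str]:
    """Return a reason string if the row violates an invariant, else None."""
    if not np.isfinite(row["beta"]):
        return "non-finite beta"
    if not (np.isfinite(row["se"]) and row["se"] > 0):
        return "se not positive"
    if not (np.isfinite(row["pval"]) and 0.0 < row["pval"] <= 1.0):
        return "pval outside (0, 1]"
    ea, oa = str(row["effect_allele"]), str(row["other_allele"])
    if ea == oa:
        return "effect allele equals other allele"
    if not (set(ea) <= VALID_ALLELES and set(oa) <= VALID_ALLELES):
        return "allele not in {A,C,G,T}"
    eaf = row["eaf"]
    if not (pd.isna(eaf) or 0.0 <= eaf <= 1.0):
        return "eaf outside [0, 1]"
    if not row["position"] > 0:
        return "non-positive position"
    return None


@dataclass
class TraitSummaryStats:
    """One trait's GWAS summary statistics.

    ``df`` is indexed by variant id with columns :data:`SUMSTAT_COLUMNS`.
    Effects are per-SD for quantitative traits and log-odds for binary
    traits; that convention is carried, not checked.
    """

    trait_id: str
    trait_type: Literal["quantitative", "binary"]
    df: pd.DataFrame
    sample_size: int = 0

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ConfigurationError(f"unknown trait_type {self.trait_type!r}")
        if self.df.index.has_duplicates:
            dups = self.df.index[self.df.index.duplicated()].unique().tolist()
            raise DuplicateVariantError(
                f"duplicate variant ids in {self.trait_id}: {dups[:5]}"
            )
        missing = [c for c in SUMSTAT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigurationError(f"missing columns {missing}")
        if self.sample_size == 0 and len(self.df):
            self.sample_size = int(self.df["n"].max())

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.df.index

    def loc(self, variant_id: str) -> pd.Series:
        return self.df.loc[variant_id]

    def subset(self, variant_ids) -> "TraitSummaryStats":
        ids = [v for v in variant_ids if v in self.df.index]
        return TraitSummaryStats(
            self.trait_id, self.trait_type, self.df.loc[ids].copy(), self.sample_size
        )


@dataclass
class LDPanel:
    """Signed pairwise LD correlations for an ordered variant list."""

    variant_ids: list
    r: np.ndarray

    def __post_init__(self) -> None:
        self.variant_ids = list(self.variant_ids)
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.variant_ids)
        if self.r.shape != (m, m):
            raise ConfigurationError(
                f"LD matrix shape {self.r.shape} does not match {m} variants"
            )
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ConfigurationError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise ConfigurationError("LD matrix diagonal is not 1")
        if np.any(np.abs(self.r) > 1 + 1e-8):
            raise ConfigurationError("LD entries outside [-1, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def index(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise NoLDInformationError(f"{variant_id} absent from LD panel") from None

    def r_of(self, a: str, b: str) -> float:
        return float(self.r[self.index(a), self.index(b)])

    def r2(self, a: str, b: str) -> float:
        return self.r_of(a, b) ** 2

    def subset(self, variant_ids) -> "LDPanel":
        idx = [self.index(v) for v in variant_ids]
        return LDPanel(list(variant_ids), self.r[np.ix_(idx, idx)])


@dataclass
class GeneAnnotation:
    """Protein-coding gene anchor used to define the cis window."""

    protein_id: str
    chromosome: str
    tss: int

    def __post_init__(self) -> None:
        if self.tss <= 0:
            raise ConfigurationError(f"TSS must be positive, got {self.tss}")


@dataclass
class InstrumentSet:
    """Harmonized exposure/outcome effect pairs for a set of instruments.

    ``df`` is indexed by variant id with columns beta_exp, se_exp,
    beta_out, se_out, eaf; alleles are already aligned so both betas
    refer to the same effect allele.  ``log`` records every
    harmonization action (flips, drops, proxies) as dicts.
    """

    exposure_id: str
    outcome_id: str
    df: pd.DataFrame
    log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for col in ("beta_exp", "se_exp", "beta_out", "se_out"):
            if col not in self.df.columns:
                raise ConfigurationError(f"InstrumentSet missing column {col}")
        if len(self.df):
            if (self.df["se_exp"] <= 0).any() or (self.df["se_out"] <= 0).any():
                raise ConfigurationError("instrument standard errors must be positive")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def beta_exp(self) -> np.ndarray:
        return self.df["beta_exp"].to_numpy(float)

    @property
    def se_exp(self) -> np.ndarray:
        return self.df["se_exp"].to_numpy(float)

    @property
    def beta_out(self) -> np.ndarray:
        return self.df["beta_out"].to_numpy(float)

    @property
    def se_out(self) -> np.ndarray:
        return self.df["se_out"].to_numpy(float)


@dataclass
class MREstimate:
    """A Mendelian-randomization effect estimate with diagnostics.

    ``beta`` is on the exposure's effect scale (log-odds for binary
    outcomes); ``i2`` is the percentage-scale heterogeneity statistic.
    Egger fits also carry the intercept and its p-value.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    Q: float = float("nan")
    i2: float = float("nan")
    egger_intercept: float = float("nan")
    egger_intercept_se: float = float("nan")
    egger_intercept_pval: float = float("nan")

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "n_snps": self.n_snps,
            "Q": self.Q,
            "i2": self.i2,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_pval": self.egger_intercept_pval,
        }


@dataclass
class DirectionalityResult:
    """MR-Steiger directionality check."""

    r2_exposure: float
    r2_outcome: float
    correct_direction: bool
    steiger_pval: float


@dataclass
class StrengthResult:
    """Instrument strength and sample-overlap bias diagnostics.

    relative_bias = phi / F: the expected bias of the MR estimate toward
    the observational association when a fraction phi of the exposure and
    outcome samples overlap.
    """

    f_statistic: float
    per_variant_f: np.ndarray
    relative_bias: float


@dataclass
class RegionAssociations:
    """One trait's associations inside a genomic region, for coloc/fine-mapping.

    ``df`` is indexed by variant id, sorted by position, with columns
    beta, se, eaf, n (position carried as a column).
    """

    trait_id: str
    trait_type: Literal["quantitative", "binary"]
    df: pd.DataFrame
    chromosome: str = ""
    start: int = 0
    end: int = 0

    def __post_init__(self) -> None:
        if (self.df["se"] <= 0).any():
            raise ConfigurationError("region standard errors must be positive")
        if "position" in self.df.columns and len(self.df) > 1:
            pos = self.df["position"].to_numpy()
            if not np.all(np.diff(pos) >= 0):
                self.df = self.df.sort_values("position")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def z(self) -> np.ndarray:
        return self.df["beta"].to_numpy(float) / self.df["se"].to_numpy(float)


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    H0 no association; H1/H2 only trait 1/2 associated; H3 both, distinct
    causal variants; H4 both, one shared causal variant.
    """

    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float
    p1: float
    p2: float
    p12: float
    n_variants: int

    def posteriors(self) -> np.ndarray:
        return np.array([self.pp_h0, self.pp_h1, self.pp_h2, self.pp_h3, self.pp_h4])


@dataclass
class CredibleSet:
    """A level-``coverage`` credible set from one single-effect component."""

    variant_ids: list
    coverage: float
    min_abs_corr: float


@dataclass
class FineMapResult:
    """Per-variant posterior inclusion probabilities and credible sets."""

    variant_ids: list
    pip: np.ndarray
    credible_sets: list
    L: int
    coverage: float
    purity_threshold: float
    converged: bool
    n_iter: int

    def pip_of(self, variant_id: str) -> float:
        return float(self.pip[self.variant_ids.index(variant_id)])
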