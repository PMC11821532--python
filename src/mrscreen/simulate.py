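"""Synthetic GWAS summary statistics with known causal ground truth.

Generates desk-scale analogues of the inputs to a two-step MR mediation
screen: a polygenic exposure (body-mass-index-like, n ~ 681k), a panel
of circulating-protein GWAS (n ~ 36k) whose levels respond to the
exposure with per-protein effect theta1 under configurable pleiotropy
regimes, a directionally concordant second adiposity trait, cis-pQTL
regions with AR(1) LD and planted causal variants, and binary disease
outcomes (effective n ~ 628k) that respond to mediator proteins with
effect theta2 and to the exposure directly.

Everything is simulated directly at the summary level: true marginal
effects are propagated through the LD matrix (marginal z = R @ zeta) and
observed effects add sampling noise with covariance R/n.  Sample overlap
between two GWAS is emulated by correlating their per-variant sampling
errors with coefficient phi, which reproduces the bias mechanism behind
relative bias = phi/F.  All generators are pure functions of
(parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .types import (
    ConfigurationError,
    GeneAnnotation,
    LDPanel,
    RegionAssociations,
    TraitSummaryStats,
)

ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]

PLEIOTROPY_REGIMES = ("none", "balanced", "directional")
CIS_SCENARIOS = ("shared", "distinct", "null")


@dataclass
class ProteinTruth:
    """Ground-truth causal parameters for one synthetic protein."""

    protein_id: str
    theta1: float  # exposure -> protein (per-SD)
    theta2: float  # protein -> outcome (log-odds per SD)
    pleiotropy: str = "none"
    cis_scenario: str = "null"
    chromosome: str = "2"
    tss: int = 50_000_000
    category: str = "null"

    def __post_init__(self) -> None:
        if self.pleiotropy not in PLEIOTROPY_REGIMES:
            raise ConfigurationError(f"unknown pleiotropy regime {self.pleiotropy!r}")
        if self.cis_scenario not in CIS_SCENARIOS:
            raise ConfigurationError(f"unknown cis scenario {self.cis_scenario!r}")


@dataclass
class SyntheticTruth:
    """Full parameterization of a synthetic screen dataset.

    The defaults emulate the study conditions of a BMI -> proteome ->
    cardiometabolic-disease screen: GWAS sample sizes of the consortium
    inputs, 100 genome-wide exposure instruments, per-SD effect sizes
    theta1 = 0.3 and theta2 = 0.2 for true mediators, and a
    risk-increasing direct exposure -> outcome effect.
    """

    seed: int = 0
    n_instruments: int = 100
    n_exposure: int = 681_275
    n_protein: int = 35_559
    n_concordance: int = 454_633
    n_outcome: int = 628_000  # effective n of a large case-control GWAS
    gamma_sd: float = 0.015  # SD of standardized instrument effects
    balanced_pleio_sd: float = 0.004
    directional_pleio_mean: float = 0.005
    directional_pleio_sd: float = 0.002
    concordance_scale: float = 0.9
    concordance_noise_sd: float = 0.002
    theta_exposure_outcome: float = 0.4  # log-odds per SD of exposure
    phi: float = 0.0  # sample-overlap fraction between exposure and outcomes
    cis_n_variants: int = 200
    cis_rho: float = 0.6
    cis_block_size: int = 25
    cis_z_protein: float = 10.0
    proteins: List[ProteinTruth] = field(default_factory=list)

    def protein(self, protein_id: str) -> ProteinTruth:
        for p in self.proteins:
            if p.protein_id == protein_id:
                return p
        raise KeyError(protein_id)

    def to_manifest(self) -> str:
        """Key-value text manifest; regenerating from it reproduces the data."""
        lines = []
        for k in (
            "seed n_instruments n_exposure n_protein n_concordance n_outcome "
            "gamma_sd balanced_pleio_sd directional_pleio_mean directional_pleio_sd "
            "concordance_scale concordance_noise_sd theta_exposure_outcome phi "
            "cis_n_variants cis_rho cis_block_size cis_z_protein"
        ).split():
            lines.append(f"{k}={getattr(self, k)}")
        for p in self.proteins:
            lines.append(
                f"protein={p.protein_id},{p.theta1},{p.theta2},{p.pleiotropy},"
                f"{p.cis_scenario},{p.chromosome},{p.tss},{p.category}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_manifest(cls, text: str) -> "SyntheticTruth":
        ints = {"seed", "n_instruments", "n_exposure", "n_protein", "n_concordance",
                "n_outcome", "cis_n_variants", "cis_block_size"}
        kwargs: Dict = {}
        proteins = []
        for line in text.strip().splitlines():
            key, _, val = line.partition("=")
            if key == "protein":
                pid, t1, t2, pleio, scen, chrom, tss, cat = val.split(",")
                proteins.append(
                    ProteinTruth(pid, float(t1), float(t2), pleio, scen,
                                 chrom, int(tss), cat)
                )
            else:
                kwargs[key] = int(val) if key in ints else float(val)
        kwargs["seed"] = int(kwargs["seed"])
        return cls(proteins=proteins, **kwargs)


def simulate_ld_panel(
    n_variants: int,
    rho: float,
    block_size: int = 25,
    seed: int = 0,
    variant_ids: Optional[List[str]] = None,
) -> LDPanel:
    """Block-diagonal AR(1) LD panel: r = rho^|i-j| within each block.

    Positive semi-definite by construction; rho = 0 gives the identity.
    The seed is accepted for interface uniformity (the construction is
    deterministic).
    """
    if not abs(rho) < 1:
        raise ConfigurationError("|rho| must be < 1")
    if variant_ids is None:
        variant_ids = [f"v{i}" for i in range(n_variants)]
    r = np.zeros((n_variants, n_variants))
    for start in range(0, n_variants, block_size):
        stop = min(start + block_size, n_variants)
        idx = np.arange(start, stop)
        dist = np.abs(idx[:, None] - idx[None, :])
        r[np.ix_(idx, idx)] = rho**dist
    np.fill_diagonal(r, 1.0)
    return LDPanel(variant_ids, r)


def _allele_scaling(eaf: np.ndarray) -> np.ndarray:
    """Per-allele scale factor 1/sqrt(2 f (1-f)) for standardized effects."""
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf))


def _sumstat_frame(
    variant_ids, chromosome, positions, eaf, beta, se, n
) -> pd.DataFrame:
    z = beta / se
    from scipy import stats

    pval = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    alleles = [ALLELE_PAIRS[i % len(ALLELE_PAIRS)] for i in range(len(variant_ids))]
    df = pd.DataFrame(
        {
            "chromosome": chromosome,
            "position": np.asarray(positions, dtype=np.int64),
            "effect_allele": [a for a, _ in alleles],
            "other_allele": [b for _, b in alleles],
            "beta": beta,
            "se": se,
            "pval": pval,
            "eaf": eaf,
            "n": int(n),
        },
        index=pd.Index(variant_ids, name="variant_id"),
    )
    return df


def simulate_step1_panel(
    truth: SyntheticTruth,
) -> Tuple[TraitSummaryStats, TraitSummaryStats, List[TraitSummaryStats]]:
    """Exposure, concordance-trait and protein-panel GWAS at the
    exposure's instrument variants.

    Instrument standardized effects gamma_j ~ N(0, gamma_sd^2); each
    protein's marginal standardized effect is theta1 * gamma_j + alpha_j
    with alpha_j drawn per its pleiotropy regime (none: 0; balanced:
    mean-0 normal; directional: nonzero-mean normal).  Observed betas
    are drawn around the truth with SE = scale/sqrt(n); the exposure and
    protein sampling errors are correlated with coefficient phi to
    emulate overlapping samples.
    """
    rng = np.random.default_rng(truth.seed)
    J = truth.n_instruments
    ids = [f"rs{j + 1}" for j in range(J)]
    positions = 1_000_000 + 2_000_000 * np.arange(J)
    eaf = rng.uniform(0.1, 0.9, size=J)
    s = _allele_scaling(eaf)
    gamma = rng.normal(0.0, truth.gamma_sd, size=J)

    se_x = s / np.sqrt(truth.n_exposure)
    eps_x = rng.standard_normal(J)
    beta_x = gamma * s + eps_x * se_x
    exposure = TraitSummaryStats(
        "exposure", "quantitative",
        _sumstat_frame(ids, "1", positions, eaf, beta_x, se_x, truth.n_exposure),
        truth.n_exposure,
    )

    gamma_c = truth.concordance_scale * gamma + rng.normal(
        0.0, truth.concordance_noise_sd, size=J
    )
    se_c = s / np.sqrt(truth.n_concordance)
    beta_c = gamma_c * s + rng.standard_normal(J) * se_c
    concordance = TraitSummaryStats(
        "concordance", "quantitative",
        _sumstat_frame(ids, "1", positions, eaf, beta_c, se_c, truth.n_concordance),
        truth.n_concordance,
    )

    panel = []
    for prot in truth.proteins:
        if prot.pleiotropy == "none":
            alpha = np.zeros(J)
        elif prot.pleiotropy == "balanced":
            alpha = rng.normal(0.0, truth.balanced_pleio_sd, size=J)
        else:
            # directional pleiotropy acts relative to the exposure-increasing
            # allele: a fixed-mean offset in an arbitrary allele coding would
            # average out once instruments are oriented on the exposure
            alpha = np.sign(gamma) * rng.normal(
                truth.directional_pleio_mean, truth.directional_pleio_sd, size=J
            )
        se_p = s / np.sqrt(truth.n_protein)
        eps_p = truth.phi * eps_x + np.sqrt(1.0 - truth.phi**2) * rng.standard_normal(J)
        beta_p = (prot.theta1 * gamma + alpha) * s + eps_p * se_p
        panel.append(
            TraitSummaryStats(
                prot.protein_id, "quantitative",
                _sumstat_frame(ids, "1", positions, eaf, beta_p, se_p, truth.n_protein),
                truth.n_protein,
            )
        )
    return exposure, concordance, panel


def simulate_cis_region(
    truth: SyntheticTruth,
    protein_id: str,
    disease_scenario: Optional[str] = None,
    seed: Optional[int] = None,
    noise: bool = True,
) -> Tuple[RegionAssociations, RegionAssociations, LDPanel]:
    """A cis-pQTL region for one protein and the matched disease region.

    The protein has one causal variant at the stated z (default 10);
    under ``shared`` the same variant drives the disease with effect
    ratio theta2, under ``distinct`` a causal variant in a different LD
    block (mutual r = 0) drives the disease at the analogous z, under
    ``null`` the disease has no signal.  Marginal effects are the LD
    rotation of the joint effects (z_marginal = R @ zeta) plus noise
    with covariance R.
    """
    prot = truth.protein(protein_id)
    scenario = disease_scenario if disease_scenario is not None else prot.cis_scenario
    if scenario not in CIS_SCENARIOS:
        raise ConfigurationError(f"unknown scenario {scenario!r}")
    pidx = truth.proteins.index(prot)
    rng = np.random.default_rng(
        seed if seed is not None else truth.seed + 100_003 * (pidx + 1)
    )
    M = truth.cis_n_variants
    ids = [f"{protein_id}_cis{i}" for i in range(M)]
    half_span = 250_000
    positions = prot.tss - half_span + (
        np.arange(M) * (2 * half_span // max(M - 1, 1))
    )
    ld = simulate_ld_panel(M, truth.cis_rho, truth.cis_block_size,
                           variant_ids=ids)
    R = ld.r
    Lc = np.linalg.cholesky(R + 1e-10 * np.eye(M))
    eaf = rng.uniform(0.1, 0.9, size=M)
    s = _allele_scaling(eaf)

    causal = truth.cis_block_size // 2  # middle of the first block
    zeta_p = np.zeros(M)
    zeta_p[causal] = truth.cis_z_protein
    z_p = R @ zeta_p + (Lc @ rng.standard_normal(M) if noise else 0.0)
    se_p = s / np.sqrt(truth.n_protein)
    beta_p = z_p * se_p

    # disease causal effect implied by theta2 on the standardized scale
    b_causal_protein = truth.cis_z_protein / np.sqrt(truth.n_protein)
    z_d_causal = prot.theta2 * b_causal_protein * np.sqrt(truth.n_outcome)
    zeta_d = np.zeros(M)
    if scenario == "shared":
        zeta_d[causal] = z_d_causal
    elif scenario == "distinct":
        other = min(truth.cis_block_size + truth.cis_block_size // 2, M - 1)
        zeta_d[other] = z_d_causal if prot.theta2 != 0 else 8.0
    z_d = R @ zeta_d + (Lc @ rng.standard_normal(M) if noise else 0.0)
    se_d = s / np.sqrt(truth.n_outcome)
    beta_d = z_d * se_d

    region_p = RegionAssociations(
        protein_id, "quantitative",
        pd.DataFrame(
            {"beta": beta_p, "se": se_p, "eaf": eaf, "n": truth.n_protein,
             "position": positions},
            index=pd.Index(ids, name="variant_id"),
        ),
        chromosome=prot.chromosome,
        start=int(positions[0]),
        end=int(positions[-1]),
    )
    region_d = RegionAssociations(
        "outcome", "binary",
        pd.DataFrame(
            {"beta": beta_d, "se": se_d, "eaf": eaf, "n": truth.n_outcome,
             "position": positions},
            index=pd.Index(ids, name="variant_id"),
        ),
        chromosome=prot.chromosome,
        start=int(positions[0]),
        end=int(positions[-1]),
    )
    return region_p, region_d, ld


@dataclass
class ScreenDataset:
    """Everything the end-to-end screen consumes, plus the truth manifest."""

    truth: SyntheticTruth
    exposure: TraitSummaryStats
    concordance: TraitSummaryStats
    outcome: TraitSummaryStats
    proteins: Dict[str, TraitSummaryStats]
    annotations: Dict[str, GeneAnnotation]
    ld: LDPanel

    def write(self, directory) -> None:
        """Write all inputs as delimited text plus the truth manifest."""
        import os

        os.makedirs(directory, exist_ok=True)
        from .summary_stats import write_gwas

        write_gwas(self.exposure, os.path.join(directory, "exposure.tsv"))
        write_gwas(self.concordance, os.path.join(directory, "concordance.tsv"))
        write_gwas(self.outcome, os.path.join(directory, "outcome.tsv"))
        for pid, ss in self.proteins.items():
            write_gwas(ss, os.path.join(directory, f"protein_{pid}.tsv"))
        with open(os.path.join(directory, "annotations.tsv"), "w") as fh:
            fh.write("protein_id\tchromosome\ttss\n")
            for ann in self.annotations.values():
                fh.write(f"{ann.protein_id}\t{ann.chromosome}\t{ann.tss}\n")
        with open(os.path.join(directory, "ld_variants.txt"), "w") as fh:
            fh.write("\n".join(self.ld.variant_ids) + "\n")
        np.savetxt(os.path.join(directory, "ld_matrix.tsv"), self.ld.r,
                   delimiter="\t")
        with open(os.path.join(directory, "truth_manifest.txt"), "w") as fh:
            fh.write(self.truth.to_manifest())


def default_protein_mix(n_proteins: int, n_mediators: int) -> List[str]:
    """Category labels for a screen panel: mediators first, then
    step1-only, wrong-sign and directional-pleiotropy violators, with
    the remainder null."""
    if n_mediators > n_proteins:
        raise ConfigurationError("n_mediators cannot exceed n_proteins")
    rest = n_proteins - n_mediators
    n_step1 = min(rest, max(0, rest * 4 // 17))
    n_wrong = min(rest - n_step1, max(0, rest * 3 // 17))
    n_pleio = min(rest - n_step1 - n_wrong, max(0, rest * 3 // 17))
    cats = (
        ["mediator"] * n_mediators
        + ["step1_only"] * n_step1
        + ["wrong_sign"] * n_wrong
        + ["directional_pleiotropy"] * n_pleio
    )
    cats += ["null"] * (n_proteins - len(cats))
    return cats


def make_truth(
    n_proteins: int = 20,
    n_mediators: int = 3,
    seed: int = 0,
    theta1: float = 0.3,
    theta2: float = 0.2,
    **overrides,
) -> SyntheticTruth:
    """Assemble a :class:`SyntheticTruth` with the default protein mix."""
    cats = default_protein_mix(n_proteins, n_mediators)
    proteins = []
    for i, cat in enumerate(cats):
        pid = f"P{i + 1:03d}"
        chrom = str(2 + i % 20)
        tss = 50_000_000 + 10_000_000 * (i // 20)
        if cat == "mediator":
            p = ProteinTruth(pid, theta1, theta2, "none", "shared", chrom, tss, cat)
        elif cat == "step1_only":
            p = ProteinTruth(pid, theta1, 0.0, "none", "null", chrom, tss, cat)
        elif cat == "wrong_sign":
            p = ProteinTruth(pid, theta1, -theta2, "none", "shared", chrom, tss, cat)
        elif cat == "directional_pleiotropy":
            p = ProteinTruth(pid, theta1, 0.0, "directional", "null", chrom, tss, cat)
        else:
            p = ProteinTruth(pid, 0.0, 0.0, "none", "null", chrom, tss, cat)
        proteins.append(p)
    return SyntheticTruth(seed=seed, proteins=proteins, **overrides)


def simulate_screen_dataset(
    n_proteins: int = 20,
    n_mediators: int = 3,
    seed: int = 0,
    cis_n_variants: int = 100,
    **overrides,
) -> ScreenDataset:
    """Full input bundle for the end-to-end two-step screen.

    The panel mixes true mediators (theta1 and theta2 both nonzero with
    a shared cis causal variant), step-1-only proteins (theta2 = 0),
    wrong-sign proteins (theta1 * theta2 < 0), directional-pleiotropy
    violators and nulls.  The outcome GWAS carries the exposure's direct
    effect at the instrument variants and each protein's cis-region
    disease associations; the exposure GWAS also covers the cis regions
    (with null effects) so reverse MR is evaluable.
    """
    truth = make_truth(
        n_proteins, n_mediators, seed, cis_n_variants=cis_n_variants, **overrides
    )
    rng = np.random.default_rng(seed + 777_001)
    exposure, concordance, panel = simulate_step1_panel(truth)
    proteins = {ss.trait_id: ss for ss in panel}

    # exposure -> outcome direct effect at the instrument variants
    J = truth.n_instruments
    inst_df = exposure.df
    s_inst = _allele_scaling(inst_df["eaf"].to_numpy())
    se_o = s_inst / np.sqrt(truth.n_outcome)
    # replay the step-1 stream to recover the latent instrument effects
    truth_rng = np.random.default_rng(truth.seed)
    truth_rng.uniform(0.1, 0.9, size=J)  # eaf draw, already materialized above
    gamma_true = truth_rng.normal(0.0, truth.gamma_sd, size=J)
    beta_o = truth.theta_exposure_outcome * gamma_true * s_inst + (
        rng.standard_normal(J) * se_o
    )
    outcome_frames = [
        _sumstat_frame(
            list(inst_df.index), "1", inst_df["position"].to_numpy(),
            inst_df["eaf"].to_numpy(), beta_o, se_o, truth.n_outcome,
        )
    ]

    ld_ids: List[str] = list(inst_df.index)
    ld_blocks: List[np.ndarray] = [np.eye(J)]
    annotations: Dict[str, GeneAnnotation] = {}
    exposure_extra = []
    for prot in truth.proteins:
        region_p, region_d, ld_region = simulate_cis_region(truth, prot.protein_id)
        annotations[prot.protein_id] = GeneAnnotation(
            prot.protein_id, prot.chromosome, prot.tss
        )
        cis_ids = list(region_p.df.index)
        cis_pos = region_p.df["position"].to_numpy()
        cis_eaf = region_p.df["eaf"].to_numpy()
        cis_frame_p = _sumstat_frame(
            cis_ids, prot.chromosome, cis_pos, cis_eaf,
            region_p.df["beta"].to_numpy(), region_p.df["se"].to_numpy(),
            truth.n_protein,
        )
        proteins[prot.protein_id] = TraitSummaryStats(
            prot.protein_id, "quantitative",
            pd.concat([proteins[prot.protein_id].df, cis_frame_p]),
            truth.n_protein,
        )
        outcome_frames.append(
            _sumstat_frame(
                cis_ids, prot.chromosome, cis_pos, cis_eaf,
                region_d.df["beta"].to_numpy(), region_d.df["se"].to_numpy(),
                truth.n_outcome,
            )
        )
        # exposure has no effect in the cis region (noise only)
        s_cis = _allele_scaling(cis_eaf)
        se_x_cis = s_cis / np.sqrt(truth.n_exposure)
        exposure_extra.append(
            _sumstat_frame(
                cis_ids, prot.chromosome, cis_pos, cis_eaf,
                rng.standard_normal(len(cis_ids)) * se_x_cis, se_x_cis,
                truth.n_exposure,
            )
        )
        ld_ids.extend(cis_ids)
        ld_blocks.append(ld_region.r)

    m_total = len(ld_ids)
    big_r = np.zeros((m_total, m_total))
    offset = 0
    for block in ld_blocks:
        b = block.shape[0]
        big_r[offset:offset + b, offset:offset + b] = block
        offset += b
    ld = LDPanel(ld_ids, big_r)

    outcome = TraitSummaryStats(
        "outcome", "binary", pd.concat(outcome_frames), truth.n_outcome
    )
    exposure = TraitSummaryStats(
        "exposure", "quantitative",
        pd.concat([exposure.df] + exposure_extra), truth.n_exposure,
    )
    return ScreenDataset(
        truth=truth,
        exposure=exposure,
        concordance=concordance,
        outcome=outcome,
        proteins=proteins,
        annotations=annotations,
        ld=ld,
    )
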