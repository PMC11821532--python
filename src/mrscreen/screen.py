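"""The two-step MR mediation screen.

Step 1 estimates the causal effect of the exposure on every protein in
the panel with the random-effects IVW estimator and applies the
sensitivity-filter battery: Bonferroni significance, heterogeneity
(I^2), the MR-Egger intercept test, directional consistency across
estimators, reverse MR from the protein's cis-pQTLs, and directional
concordance with a second adiposity trait.  Step 2 estimates each
surviving protein's effect on a disease outcome from cis-pQTL
instruments (Wald ratio for a single instrument, IVW otherwise) with
Bonferroni correction, an Egger intercept gate when applicable, the
MR-Steiger directionality gate and a Bayesian colocalization gate
(PP.H4 > 0.8 in the 500-kb window around the lead cis-pQTL).  A protein
is called a mediator when it passes every gate in both steps and the
sign condition beta_step1 * beta_step2 > 0 (for a risk-increasing
exposure) holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd

from . import estimators as est
from .coloc import coloc_abf
from .summary_stats import (
    clump,
    exclude_mhc,
    exclusivity_filter,
    harmonize,
    select_cis_instruments,
)
from .types import (
    ColocResult,
    ConfigurationError,
    DirectionalityResult,
    GeneAnnotation,
    InstrumentSet,
    LDPanel,
    MREstimate,
    MRScreenError,
    RegionAssociations,
    TraitSummaryStats,
)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m."""
    if m < 1:
        raise ConfigurationError("number of tests must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError("alpha must be in (0, 1)")
    return alpha / m


@dataclass
class FilterBattery:
    """Thresholds for every gate of the screen.

    ``reverse_mr_n_tests`` sets the Bonferroni denominator of the
    reverse-MR gate explicitly (it is a study-level choice); when None
    it defaults to the number of proteins entering the reverse analysis.
    """

    bonferroni_alpha: float = 0.05
    i2_max: float = 50.0
    egger_intercept_alpha: float = 0.05
    require_directional_consistency: bool = True
    reverse_mr_alpha: float = 0.05
    reverse_mr_n_tests: Optional[int] = None
    concordance_alpha: float = 0.05
    clump_p: float = 5e-8
    clump_r2: float = 0.001
    clump_window_bp: int = 10_000_000
    cis_window_bp: int = 1_000_000
    proxy_r2_min: float = 0.8
    palindromic_eaf_limit: float = 0.42
    presso_n_sim: int = 1000
    presso_outlier_alpha: float = 0.05
    wm_n_boot: int = 1000
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    coloc_pp_h4_min: float = 0.8
    coloc_region_bp: int = 500_000

    def __post_init__(self) -> None:
        for name in ("bonferroni_alpha", "egger_intercept_alpha",
                     "reverse_mr_alpha", "concordance_alpha",
                     "presso_outlier_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1), got {v}")


@dataclass
class GateResult:
    """One gate's decision, with the statistic it was based on."""

    name: str
    passed: bool
    statistic: float
    threshold: float
    applicable: bool = True
    reason: str = ""


@dataclass
class Step1Record:
    """Per-protein outcome of step 1 (exposure -> protein MR + filters)."""

    protein_id: str
    evaluable: bool
    ivw: Optional[MREstimate] = None
    egger: Optional[MREstimate] = None
    weighted_median: Optional[MREstimate] = None
    presso_global_p: float = float("nan")
    presso_corrected: Optional[MREstimate] = None
    reverse: Optional[MREstimate] = None
    concordance: Optional[MREstimate] = None
    f_statistic: float = float("nan")
    relative_bias: float = float("nan")
    gates: List[GateResult] = field(default_factory=list)
    reason: str = ""

    @property
    def passed(self) -> bool:
        return self.evaluable and all(
            g.passed for g in self.gates if g.applicable
        )


@dataclass
class Step2Record:
    """Per-protein outcome of step 2 (protein -> disease cis-MR + gates)."""

    protein_id: str
    outcome_id: str
    evaluable: bool
    estimate: Optional[MREstimate] = None
    egger: Optional[MREstimate] = None
    steiger: Optional[DirectionalityResult] = None
    coloc: Optional[ColocResult] = None
    f_statistic: float = float("nan")
    relative_bias: float = float("nan")
    gates: List[GateResult] = field(default_factory=list)
    reason: str = ""

    @property
    def passed(self) -> bool:
        return self.evaluable and all(
            g.passed for g in self.gates if g.applicable
        )


@dataclass
class MediatorVerdict:
    """Full per-protein ledger entry with the final mediator call."""

    protein_id: str
    outcome_id: str
    step1: Optional[Step1Record]
    step2: Optional[Step2Record]
    sign_condition_met: bool
    relative_bias_step1: float
    relative_bias_step2: float
    final_call: str  # "mediator" or "rejected:<stage>" or "unevaluable"


def _sign_consistent(estimates: List[MREstimate]) -> bool:
    signs = {np.sign(e.beta) for e in estimates if e is not None}
    return len(signs) == 1 and 0.0 not in signs


def _gate(name, passed, statistic, threshold, applicable=True, reason=""):
    return GateResult(name, bool(passed), float(statistic), float(threshold),
                      applicable, reason)


def run_step1(
    exposure_ss: TraitSummaryStats,
    protein_panel: List[TraitSummaryStats],
    concordance_ss: Optional[TraitSummaryStats],
    ld: Optional[LDPanel],
    battery: FilterBattery = FilterBattery(),
    annotations: Optional[Mapping[str, GeneAnnotation]] = None,
    phi: float = 0.0,
    seed: int = 0,
    drop_mhc: bool = True,
) -> Dict[str, Step1Record]:
    """Exposure -> protein MR with the six-gate filter battery.

    Gates, in order: (1) Bonferroni significance across the panel,
    (2) heterogeneity I^2 <= i2_max, (3) Egger intercept not significant,
    (4) directional consistency across IVW, weighted median, Egger slope
    and the PRESSO-corrected estimate (the latter only when outliers were
    detected), (5) reverse MR (protein cis-instruments -> exposure) not
    significant, (6) concordance-trait MR nominally significant with the
    same sign.  Gates that cannot be evaluated are recorded as not
    applicable and do not reject.  Proteins without usable instruments
    are returned as unevaluable records, never silently dropped.
    """
    ss = exclude_mhc(exposure_ss) if drop_mhc else exposure_ss
    instruments = clump(ss, ld, battery.clump_p, battery.clump_r2,
                        battery.clump_window_bp)
    m = len(protein_panel)
    p_threshold = bonferroni_threshold(battery.bonferroni_alpha, max(m, 1))
    conc_instruments: List[str] = []
    if concordance_ss is not None:
        conc_instruments = clump(
            exclude_mhc(concordance_ss) if drop_mhc else concordance_ss,
            ld, battery.clump_p, battery.clump_r2, battery.clump_window_bp,
        )
    n_reverse = battery.reverse_mr_n_tests if battery.reverse_mr_n_tests else m
    reverse_threshold = bonferroni_threshold(battery.reverse_mr_alpha, n_reverse)

    records: Dict[str, Step1Record] = {}
    for prot_ss in protein_panel:
        pid = prot_ss.trait_id
        try:
            inst = harmonize(
                exposure_ss, prot_ss, instruments, ld,
                battery.palindromic_eaf_limit, battery.proxy_r2_min,
            )
        except MRScreenError as exc:
            records[pid] = Step1Record(pid, evaluable=False, reason=str(exc))
            continue
        if len(inst) < 2:
            records[pid] = Step1Record(
                pid, evaluable=False,
                reason=f"only {len(inst)} overlapping instruments",
            )
            continue
        rec = Step1Record(pid, evaluable=True)
        rec.ivw = est.ivw_random_effects(inst)
        strength = est.instrument_strength(inst, phi)
        rec.f_statistic = strength.f_statistic
        rec.relative_bias = strength.relative_bias
        if len(inst) >= 3:
            rec.egger = est.egger(inst)
            rec.weighted_median = est.weighted_median(
                inst, n_boot=battery.wm_n_boot, seed=seed
            )
        if len(inst) >= 4:
            rec.presso_global_p, flags, rec.presso_corrected = est.presso(
                inst, n_sim=battery.presso_n_sim, seed=seed,
                outlier_alpha=battery.presso_outlier_alpha,
            )

        rec.gates.append(_gate(
            "bonferroni", rec.ivw.pval < p_threshold, rec.ivw.pval, p_threshold
        ))
        rec.gates.append(_gate(
            "heterogeneity", rec.ivw.i2 <= battery.i2_max, rec.ivw.i2,
            battery.i2_max,
        ))
        if rec.egger is not None:
            rec.gates.append(_gate(
                "egger_intercept",
                rec.egger.egger_intercept_pval >= battery.egger_intercept_alpha,
                rec.egger.egger_intercept_pval, battery.egger_intercept_alpha,
            ))
        else:
            rec.gates.append(_gate("egger_intercept", True, float("nan"),
                                   battery.egger_intercept_alpha,
                                   applicable=False, reason="<3 instruments"))
        if battery.require_directional_consistency:
            cand = [rec.ivw, rec.weighted_median, rec.egger]
            if rec.presso_corrected is not None:
                cand.append(rec.presso_corrected)
            cand = [c for c in cand if c is not None]
            ok = _sign_consistent(cand)
            rec.gates.append(_gate(
                "directional_consistency", ok,
                float(len({np.sign(c.beta) for c in cand})), 1.0,
            ))

        # reverse MR: protein cis-pQTLs -> exposure
        ann = annotations.get(pid) if annotations else None
        if ann is not None:
            cis = select_cis_instruments(
                prot_ss, ann, ld, battery.cis_window_bp,
                battery.clump_p, battery.clump_r2, battery.clump_window_bp,
            )
            rev_inst = None
            if cis:
                try:
                    rev_inst = harmonize(
                        prot_ss, exposure_ss, cis, ld,
                        battery.palindromic_eaf_limit, battery.proxy_r2_min,
                    )
                except MRScreenError:
                    rev_inst = None
            if rev_inst is not None and len(rev_inst) >= 1:
                if len(rev_inst) == 1:
                    row = rev_inst.df.iloc[0]
                    rec.reverse = est.wald_ratio(
                        row["beta_exp"], row["se_exp"],
                        row["beta_out"], row["se_out"],
                    )
                else:
                    rec.reverse = est.ivw_random_effects(rev_inst)
                rec.gates.append(_gate(
                    "reverse_mr", rec.reverse.pval >= reverse_threshold,
                    rec.reverse.pval, reverse_threshold,
                ))
            else:
                rec.gates.append(_gate("reverse_mr", True, float("nan"),
                                       reverse_threshold, applicable=False,
                                       reason="no cis instruments"))
        else:
            rec.gates.append(_gate("reverse_mr", True, float("nan"),
                                   reverse_threshold, applicable=False,
                                   reason="no annotation"))

        if concordance_ss is not None and conc_instruments:
            try:
                conc_inst = harmonize(
                    concordance_ss, prot_ss, conc_instruments, ld,
                    battery.palindromic_eaf_limit, battery.proxy_r2_min,
                )
            except MRScreenError:
                conc_inst = None
            if conc_inst is not None and len(conc_inst) >= 2:
                rec.concordance = est.ivw_random_effects(conc_inst)
                ok = (
                    rec.concordance.pval < battery.concordance_alpha
                    and np.sign(rec.concordance.beta) == np.sign(rec.ivw.beta)
                    and rec.ivw.beta != 0
                )
                rec.gates.append(_gate(
                    "concordance", ok, rec.concordance.pval,
                    battery.concordance_alpha,
                ))
            else:
                rec.gates.append(_gate("concordance", True, float("nan"),
                                       battery.concordance_alpha,
                                       applicable=False,
                                       reason="no usable instruments"))
        else:
            rec.gates.append(_gate("concordance", True, float("nan"),
                                   battery.concordance_alpha,
                                   applicable=False, reason="no concordance trait"))
        records[pid] = rec
    return records


def _lead_variant(prot_ss: TraitSummaryStats, ann: GeneAnnotation,
                  window_bp: int) -> Optional[str]:
    df = prot_ss.df
    in_cis = (
        (df["chromosome"].astype(str) == str(ann.chromosome))
        & ((df["position"] - ann.tss).abs() <= window_bp)
    )
    cis = df[in_cis]
    if cis.empty:
        return None
    return cis["pval"].idxmin()


def _region_assoc(ss: TraitSummaryStats, chrom: str, start: int, end: int,
                  ids) -> RegionAssociations:
    df = ss.df
    mask = (
        (df["chromosome"].astype(str) == str(chrom))
        & (df["position"] >= start)
        & (df["position"] <= end)
        & df.index.isin(ids)
    )
    sub = df[mask]
    return RegionAssociations(
        ss.trait_id, ss.trait_type,
        sub[["beta", "se", "eaf", "n", "position"]].copy(),
        chromosome=chrom, start=start, end=end,
    )


def run_step2(
    protein_panel: List[TraitSummaryStats],
    outcome_ss: TraitSummaryStats,
    annotations: Mapping[str, GeneAnnotation],
    ld: Optional[LDPanel],
    battery: FilterBattery = FilterBattery(),
    coloc_settings: Optional[dict] = None,
    phi: float = 0.0,
) -> Dict[str, Step2Record]:
    """Protein -> disease cis-MR with Egger, Steiger and coloc gates.

    cis-pQTL instruments are selected within ``cis_window_bp`` of each
    protein's TSS, clumped, and filtered panel-wide so no variant
    instruments more than one protein.  The Bonferroni denominator is
    the number of proteins with at least one usable instrument for this
    outcome.  The colocalization gate tests PP.H4 > 0.8 in the
    ``coloc_region_bp`` window centred on the lead cis-pQTL.
    """
    cs = {"p1": battery.coloc_p1, "p2": battery.coloc_p2,
          "p12": battery.coloc_p12}
    if coloc_settings:
        cs.update(coloc_settings)

    cis_by_protein = {}
    for prot_ss in protein_panel:
        ann = annotations.get(prot_ss.trait_id)
        if ann is None:
            cis_by_protein[prot_ss.trait_id] = []
            continue
        cis_by_protein[prot_ss.trait_id] = select_cis_instruments(
            prot_ss, ann, ld, battery.cis_window_bp,
            battery.clump_p, battery.clump_r2, battery.clump_window_bp,
        )
    cis_by_protein, _counts = exclusivity_filter(cis_by_protein)

    # harmonize first so the Bonferroni denominator counts testable proteins
    prepared = {}
    for prot_ss in protein_panel:
        pid = prot_ss.trait_id
        cis = cis_by_protein.get(pid, [])
        if not cis:
            prepared[pid] = (prot_ss, None, "no cis instruments")
            continue
        try:
            inst = harmonize(
                prot_ss, outcome_ss, cis, ld,
                battery.palindromic_eaf_limit, battery.proxy_r2_min,
            )
        except MRScreenError as exc:
            prepared[pid] = (prot_ss, None, str(exc))
            continue
        if len(inst) == 0:
            prepared[pid] = (prot_ss, None, "no instruments after harmonization")
            continue
        prepared[pid] = (prot_ss, inst, "")
    m = sum(1 for _, inst, _ in prepared.values() if inst is not None)
    p_threshold = bonferroni_threshold(battery.bonferroni_alpha, max(m, 1))

    records: Dict[str, Step2Record] = {}
    for pid, (prot_ss, inst, why) in prepared.items():
        if inst is None:
            records[pid] = Step2Record(pid, outcome_ss.trait_id,
                                       evaluable=False, reason=why)
            continue
        rec = Step2Record(pid, outcome_ss.trait_id, evaluable=True)
        if len(inst) == 1:
            row = inst.df.iloc[0]
            rec.estimate = est.wald_ratio(
                row["beta_exp"], row["se_exp"], row["beta_out"], row["se_out"]
            )
        else:
            rec.estimate = est.ivw_random_effects(inst)
        strength = est.instrument_strength(inst, phi)
        rec.f_statistic = strength.f_statistic
        rec.relative_bias = strength.relative_bias

        rec.gates.append(_gate(
            "bonferroni", rec.estimate.pval < p_threshold,
            rec.estimate.pval, p_threshold,
        ))
        if len(inst) >= 3:
            rec.egger = est.egger(inst)
            rec.gates.append(_gate(
                "egger_intercept",
                rec.egger.egger_intercept_pval >= battery.egger_intercept_alpha,
                rec.egger.egger_intercept_pval, battery.egger_intercept_alpha,
            ))
        else:
            rec.gates.append(_gate("egger_intercept", True, float("nan"),
                                   battery.egger_intercept_alpha,
                                   applicable=False, reason="<3 instruments"))
        rec.steiger = est.steiger(inst, prot_ss.sample_size,
                                  outcome_ss.sample_size)
        rec.gates.append(_gate(
            "steiger", rec.steiger.correct_direction,
            rec.steiger.r2_exposure - rec.steiger.r2_outcome, 0.0,
        ))

        ann = annotations.get(pid)
        lead = _lead_variant(prot_ss, ann, battery.cis_window_bp) if ann else None
        if lead is not None:
            lead_pos = int(prot_ss.loc(lead)["position"])
            half = battery.coloc_region_bp // 2
            shared_ids = set(prot_ss.df.index) & set(outcome_ss.df.index)
            ra = _region_assoc(prot_ss, ann.chromosome, lead_pos - half,
                               lead_pos + half, shared_ids)
            rb = _region_assoc(outcome_ss, ann.chromosome, lead_pos - half,
                               lead_pos + half, shared_ids)
            if len(ra) and len(rb):
                rec.coloc = coloc_abf(ra, rb, **cs)
                rec.gates.append(_gate(
                    "colocalization", rec.coloc.pp_h4 > battery.coloc_pp_h4_min,
                    rec.coloc.pp_h4, battery.coloc_pp_h4_min,
                ))
            else:
                rec.gates.append(_gate("colocalization", False, 0.0,
                                       battery.coloc_pp_h4_min,
                                       reason="no shared region variants"))
        else:
            rec.gates.append(_gate("colocalization", False, 0.0,
                                   battery.coloc_pp_h4_min,
                                   reason="no lead cis-pQTL"))
        records[pid] = rec
    return records


def mediation_filter(
    step1_beta: float, step2_beta: float, exposure_outcome_beta: float
) -> bool:
    """Mediation sign condition: beta_step1 * beta_step2 > 0.

    Stated for a risk-increasing exposure (exposure_outcome_beta > 0);
    for a protective exposure the product is required to share the total
    effect's sign instead.  Zero betas fail (strict inequality).
    """
    if exposure_outcome_beta == 0:
        return False
    product = step1_beta * step2_beta
    return product * np.sign(exposure_outcome_beta) > 0


def assemble_verdicts(
    step1: Mapping[str, Step1Record],
    step2: Mapping[str, Step2Record],
    overlap_phi: Optional[Mapping[str, float]] = None,
    exposure_outcome_beta: float = 1.0,
) -> List[MediatorVerdict]:
    """Join step records into the final per-protein mediator ledger.

    Every step-1 protein appears exactly once.  ``overlap_phi`` maps
    protein ids to the step-2 sample-overlap fraction (step-1 bias is
    carried on the records themselves).  A protein passing both steps is
    a mediator iff the sign condition also holds.  Step-2 ids without a
    step-1 record are an input error.
    """
    orphans = [pid for pid in step2 if pid not in step1]
    if orphans:
        raise ConfigurationError(f"step-2 records without step-1: {orphans}")
    verdicts = []
    for pid, s1 in step1.items():
        s2 = step2.get(pid)
        rb1 = s1.relative_bias if s1 else float("nan")
        rb2 = s2.relative_bias if s2 else float("nan")
        if not s1.evaluable:
            call = "unevaluable"
            sign_ok = False
        elif not s1.passed:
            failed = next(g.name for g in s1.gates if g.applicable and not g.passed)
            call = f"rejected:step1_{failed}"
            sign_ok = False
        elif s2 is None or not s2.evaluable:
            call = "rejected:step2_unevaluable"
            sign_ok = False
        elif not s2.passed:
            failed = next(g.name for g in s2.gates if g.applicable and not g.passed)
            call = f"rejected:step2_{failed}"
            sign_ok = False
        else:
            sign_ok = mediation_filter(
                s1.ivw.beta, s2.estimate.beta, exposure_outcome_beta
            )
            call = "mediator" if sign_ok else "rejected:mediation_sign"
        verdicts.append(
            MediatorVerdict(
                protein_id=pid,
                outcome_id=s2.outcome_id if s2 else "",
                step1=s1,
                step2=s2,
                sign_condition_met=sign_ok,
                relative_bias_step1=rb1,
                relative_bias_step2=rb2,
                final_call=call,
            )
        )
    return verdicts


def verdicts_to_frame(verdicts: List[MediatorVerdict]) -> pd.DataFrame:
    """Flat delimited-friendly ledger: one row per protein."""
    rows = []
    for v in verdicts:
        row = {
            "protein_id": v.protein_id,
            "outcome_id": v.outcome_id,
            "final_call": v.final_call,
            "sign_condition_met": v.sign_condition_met,
            "relative_bias_step1": v.relative_bias_step1,
            "relative_bias_step2": v.relative_bias_step2,
        }
        if v.step1 and v.step1.ivw:
            row["step1_beta"] = v.step1.ivw.beta
            row["step1_pval"] = v.step1.ivw.pval
            row["step1_i2"] = v.step1.ivw.i2
        if v.step2 and v.step2.estimate:
            row["step2_beta"] = v.step2.estimate.beta
            row["step2_or"] = v.step2.estimate.odds_ratio
            row["step2_pval"] = v.step2.estimate.pval
            row["step2_method"] = v.step2.estimate.method
            if v.step2.coloc:
                row["pp_h4"] = v.step2.coloc.pp_h4
        for rec in (v.step1, v.step2):
            if rec is None:
                continue
            prefix = "step1" if isinstance(rec, Step1Record) else "step2"
            for g in rec.gates:
                row[f"{prefix}_gate_{g.name}"] = (
                    "pass" if g.passed else "fail"
                ) if g.applicable else "n/a"
        rows.append(row)
    return pd.DataFrame(rows)


def run_screen(
    exposure_ss: TraitSummaryStats,
    protein_panel: List[TraitSummaryStats],
    outcome_ss: TraitSummaryStats,
    concordance_ss: Optional[TraitSummaryStats],
    annotations: Mapping[str, GeneAnnotation],
    ld: Optional[LDPanel],
    battery: FilterBattery = FilterBattery(),
    phi_step1: float = 0.0,
    phi_step2: float = 0.0,
    seed: int = 0,
) -> List[MediatorVerdict]:
    """End-to-end two-step screen returning the full verdict ledger.

    The exposure -> outcome IVW effect (needed by the mediation sign
    condition) is estimated from the same genome-wide instruments used
    in step 1.
    """
    step1 = run_step1(
        exposure_ss, protein_panel, concordance_ss, ld, battery,
        annotations=annotations, phi=phi_step1, seed=seed,
    )
    survivors = [ss for ss in protein_panel if step1[ss.trait_id].passed]
    step2 = run_step2(
        survivors, outcome_ss, annotations, ld, battery, phi=phi_step2,
    )
    instruments = clump(exclude_mhc(exposure_ss), ld, battery.clump_p,
                        battery.clump_r2, battery.clump_window_bp)
    eo_inst = harmonize(exposure_ss, outcome_ss, instruments, ld,
                        battery.palindromic_eaf_limit, battery.proxy_r2_min)
    eo_beta = est.ivw_random_effects(eo_inst).beta if len(eo_inst) >= 2 else 1.0
    return assemble_verdicts(step1, step2, exposure_outcome_beta=eo_beta)
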