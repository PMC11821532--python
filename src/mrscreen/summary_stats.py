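"""Reading, harmonizing and filtering GWAS summary statistics.

Implements the instrument-selection toolchain of a two-sample MR
analysis: validated table ingest, region exclusion (e.g. the MHC),
greedy LD clumping, proxy lookup, exposure/outcome allele harmonization,
cis-window instrument selection and the cross-protein exclusivity
filter for cis-pQTLs.

Coordinates are 1-based and all windows are inclusive on both ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .types import (
    SUMSTAT_COLUMNS,
    ConfigurationError,
    DuplicateVariantError,
    EmptyInputError,
    GeneAnnotation,
    InstrumentSet,
    LDPanel,
    NoLDInformationError,
    TraitSummaryStats,
    _validate_sumstat_row,
)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Major histocompatibility complex region on GRCh37, excluded from
#: instrument selection because of its complex LD structure.
MHC_GRCH37 = ("6", 28477797, 33448354)


def _complement(allele: str) -> str:
    return "".join(COMPLEMENT[b] for b in allele)


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """A/T and C/G pairs are strand-ambiguous."""
    return _complement(effect_allele) == other_allele


@dataclass
class ReadReport:
    """Row-level outcomes of :func:`read_gwas` validation."""

    n_read: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    drop_reasons: Dict[str, int] = field(default_factory=dict)


def read_gwas(
    path,
    column_map: Mapping[str, str],
    trait_type: str,
    trait_id: Optional[str] = None,
    sep: Optional[str] = None,
) -> Tuple[TraitSummaryStats, ReadReport]:
    """Read a delimited summary-statistics file into a validated table.

    Parameters
    ----------
    path
        Delimited text file with a header row (tab or comma; sniffed
        unless ``sep`` is given).
    column_map
        Maps canonical names (``variant_id`` plus
        :data:`~mrscreen.types.SUMSTAT_COLUMNS`) to the file's column
        names.  ``eaf`` and ``n`` may be omitted.
    trait_type
        ``"quantitative"`` or ``"binary"``.

    Rows violating a per-variant invariant (non-positive SE, p outside
    (0, 1], malformed alleles, ...) are dropped and counted in the
    returned :class:`ReadReport`; a duplicated variant id raises.
    """
    df_raw = pd.read_csv(path, sep=sep if sep is not None else None, engine="python")
    mandatory = ["variant_id", "chromosome", "position", "effect_allele",
                 "other_allele", "beta", "se", "pval"]
    for canon in mandatory:
        src = column_map.get(canon, canon)
        if src not in df_raw.columns:
            raise ConfigurationError(
                f"column {src!r} (for {canon!r}) not found in {path}"
            )

    def col(canon, default=np.nan):
        src = column_map.get(canon, canon)
        if src in df_raw.columns:
            return df_raw[src]
        return pd.Series(default, index=df_raw.index)

    df = pd.DataFrame(
        {
            "chromosome": col("chromosome").astype(str),
            "position": pd.to_numeric(col("position"), errors="coerce"),
            "effect_allele": col("effect_allele").astype(str).str.upper(),
            "other_allele": col("other_allele").astype(str).str.upper(),
            "beta": pd.to_numeric(col("beta"), errors="coerce"),
            "se": pd.to_numeric(col("se"), errors="coerce"),
            "pval": pd.to_numeric(col("pval"), errors="coerce"),
            "eaf": pd.to_numeric(col("eaf"), errors="coerce"),
            "n": pd.to_numeric(col("n", 0), errors="coerce").fillna(0),
        }
    )
    df.index = col("variant_id").astype(str)
    df.index.name = "variant_id"

    report = ReadReport(n_read=len(df))
    keep = np.ones(len(df), dtype=bool)
    for i, (_, row) in enumerate(df.iterrows()):
        reason = _validate_sumstat_row(row)
        if reason is not None:
            keep[i] = False
            report.drop_reasons[reason] = report.drop_reasons.get(reason, 0) + 1
    df = df[keep]
    df["position"] = df["position"].astype(np.int64)
    df["n"] = df["n"].astype(np.int64)
    report.n_kept = len(df)
    report.n_dropped = report.n_read - report.n_kept
    if report.n_kept == 0:
        raise EmptyInputError(f"no valid rows in {path}")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DuplicateVariantError(f"duplicate variant ids: {dups}")
    tid = trait_id if trait_id is not None else str(path)
    return TraitSummaryStats(tid, trait_type, df[SUMSTAT_COLUMNS]), report


def write_gwas(ss: TraitSummaryStats, path, sep: str = "\t") -> None:
    """Write a summary-statistics table back to delimited text."""
    ss.df.to_csv(path, sep=sep, index=True, index_label="variant_id")


def exclude_region(
    ss: TraitSummaryStats, chromosome: str, start: int, end: int
) -> TraitSummaryStats:
    """Drop all variants inside chromosome:[start, end] (1-based, inclusive)."""
    if start > end:
        raise ConfigurationError(f"region start {start} > end {end}")
    df = ss.df
    inside = (
        (df["chromosome"].astype(str) == str(chromosome))
        & (df["position"] >= start)
        & (df["position"] <= end)
    )
    return TraitSummaryStats(ss.trait_id, ss.trait_type, df[~inside].copy(),
                             ss.sample_size)


def exclude_mhc(ss: TraitSummaryStats) -> TraitSummaryStats:
    """Drop variants in the GRCh37 MHC region (chr6:28477797-33448354)."""
    return exclude_region(ss, *MHC_GRCH37)


def clump(
    ss: TraitSummaryStats,
    ld: Optional[LDPanel],
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    window_bp: int = 10_000_000,
) -> List[str]:
    """Greedy LD clumping of genome-wide significant variants.

    Candidates with p < ``p_threshold`` are visited in ascending p
    (ties broken by position, then id); a candidate is accepted iff its
    LD r^2 with every already-accepted variant on the same chromosome
    within ``window_bp`` is below ``r2_threshold``.  Variants absent
    from the LD panel are treated as independent.

    Returns accepted variant ids in acceptance order.
    """
    if p_threshold < 0 or r2_threshold < 0 or window_bp < 0:
        raise ConfigurationError("clumping thresholds must be non-negative")
    cand = ss.df[ss.df["pval"] < p_threshold]
    order = sorted(
        cand.index,
        key=lambda v: (cand.at[v, "pval"], cand.at[v, "position"], v),
    )
    accepted: List[str] = []
    for v in order:
        chrom_v = cand.at[v, "chromosome"]
        pos_v = cand.at[v, "position"]
        ok = True
        for a in accepted:
            if cand.at[a, "chromosome"] != chrom_v:
                continue
            if abs(int(cand.at[a, "position"]) - int(pos_v)) > window_bp:
                continue
            if ld is None or v not in ld or a not in ld:
                continue  # no LD information: treated as independent
            if ld.r2(v, a) >= r2_threshold:
                ok = False
                break
        if ok:
            accepted.append(v)
    return accepted


def find_proxy(
    variant_id: str,
    ld: LDPanel,
    target_ss: TraitSummaryStats,
    r2_min: float = 0.8,
    query_position: Optional[int] = None,
) -> Optional[str]:
    """Best available proxy for a variant missing from ``target_ss``.

    Returns the variant present in ``target_ss`` with maximal r^2 to the
    query among those with r^2 >= ``r2_min``; ties broken by smaller
    genomic distance to ``query_position`` (when known), then
    lexicographic id.  ``None`` when no candidate qualifies.  Raises
    :class:`NoLDInformationError` when the query is absent from the LD
    panel.
    """
    qi = ld.index(variant_id)  # raises NoLDInformationError if absent
    candidates = []
    for v in ld.variant_ids:
        if v == variant_id or v not in target_ss:
            continue
        r2 = ld.r[qi, ld.index(v)] ** 2
        if r2 >= r2_min:
            candidates.append((v, r2))
    if not candidates:
        return None

    def sort_key(item):
        v, r2 = item
        if query_position is not None:
            dist = abs(int(target_ss.loc(v)["position"]) - int(query_position))
        else:
            dist = 0
        return (-r2, dist, v)

    candidates.sort(key=sort_key)
    return candidates[0][0]


def harmonize(
    exposure: TraitSummaryStats,
    outcome: TraitSummaryStats,
    instruments: Iterable[str],
    ld: Optional[LDPanel] = None,
    palindromic_eaf_limit: float = 0.42,
    proxy_r2_min: float = 0.8,
) -> InstrumentSet:
    """Align outcome alleles to the exposure effect allele per instrument.

    For each instrument: if the variant is missing from the outcome and
    an LD panel is supplied, a proxy with r^2 >= ``proxy_r2_min`` is
    substituted (the proxy's outcome effect is sign-aligned through the
    LD correlation sign).  Alleles are then reconciled: identical coding
    passes through; swapped effect/other alleles flip the outcome beta
    (and eaf -> 1 - eaf); strand-flipped codings are complemented first.
    Palindromic (A/T, C/G) variants are kept only when both allele
    frequencies are informative — outside
    [``palindromic_eaf_limit``, 1 - ``palindromic_eaf_limit``] — and
    agree in orientation; otherwise they are dropped.  Irreconcilable
    allele sets are dropped.  Every action is recorded in the log.
    """
    instruments = list(instruments)
    if not instruments:
        raise EmptyInputError("no instruments supplied to harmonize")
    lo, hi = palindromic_eaf_limit, 1.0 - palindromic_eaf_limit
    rows = []
    log: List[dict] = []
    for v in instruments:
        if v not in exposure:
            log.append({"variant": v, "action": "drop", "reason": "absent from exposure"})
            continue
        ex = exposure.loc(v)
        out_v = v
        ld_sign = 1.0
        if v not in outcome:
            proxy = None
            if ld is not None and v in ld:
                proxy = find_proxy(
                    v, ld, outcome, r2_min=proxy_r2_min,
                    query_position=int(ex["position"]),
                )
            if proxy is None:
                log.append({"variant": v, "action": "drop", "reason": "absent from outcome, no proxy"})
                continue
            ld_sign = float(np.sign(ld.r_of(v, proxy))) or 1.0
            log.append({"variant": v, "action": "proxy", "proxy": proxy,
                        "r": ld.r_of(v, proxy)})
            out_v = proxy
        oc = outcome.loc(out_v)
        ea_x, oa_x = ex["effect_allele"], ex["other_allele"]
        ea_y, oa_y = oc["effect_allele"], oc["other_allele"]
        beta_y = float(oc["beta"]) * ld_sign
        eaf_y = oc["eaf"]
        if out_v != v:
            # proxy alleles are not comparable with the query's; the LD
            # sign already aligned the effect direction
            flip = False
        elif (ea_y, oa_y) == (ea_x, oa_x):
            flip = False
        elif (ea_y, oa_y) == (oa_x, ea_x):
            flip = True
        elif (_complement(ea_y), _complement(oa_y)) == (ea_x, oa_x):
            flip = False  # strand flip only
        elif (_complement(ea_y), _complement(oa_y)) == (oa_x, ea_x):
            flip = True
        else:
            log.append({"variant": v, "action": "drop",
                        "reason": f"irreconcilable alleles {ea_x}/{oa_x} vs {ea_y}/{oa_y}"})
            continue
        if out_v == v and is_palindromic(ea_x, oa_x):
            fx, fy = ex["eaf"], oc["eaf"]
            if pd.isna(fx) or pd.isna(fy):
                log.append({"variant": v, "action": "drop",
                            "reason": "palindromic, missing eaf"})
                continue
            if (lo <= fx <= hi) or (lo <= fy <= hi):
                log.append({"variant": v, "action": "drop",
                            "reason": "palindromic, ambiguous eaf"})
                continue
            # orient by frequency: both minor or both major on the same allele
            flip = (fx < 0.5) != (fy < 0.5)
        if flip:
            beta_y = -beta_y
            eaf_y = 1.0 - eaf_y if pd.notna(eaf_y) else eaf_y
            log.append({"variant": v, "action": "flip"})
        rows.append(
            {
                "variant_id": v,
                "beta_exp": float(ex["beta"]),
                "se_exp": float(ex["se"]),
                "beta_out": beta_y,
                "se_out": float(oc["se"]),
                "eaf": float(ex["eaf"]) if pd.notna(ex["eaf"]) else np.nan,
            }
        )
    df = pd.DataFrame(rows).set_index("variant_id") if rows else pd.DataFrame(
        columns=["beta_exp", "se_exp", "beta_out", "se_out", "eaf"]
    )
    return InstrumentSet(exposure.trait_id, outcome.trait_id, df, log)


def select_cis_instruments(
    protein_ss: TraitSummaryStats,
    annotation: GeneAnnotation,
    ld: Optional[LDPanel],
    window_bp: int = 1_000_000,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    clump_window_bp: int = 10_000_000,
) -> List[str]:
    """Select cis-pQTL instruments: restrict to the TSS window, then clump.

    A cis-pQTL lies within ``window_bp`` (default 1 Mb) of the protein
    gene's transcription start site on the annotated chromosome.
    Returns an empty list when no variant falls in the window.
    """
    df = protein_ss.df
    in_cis = (
        (df["chromosome"].astype(str) == str(annotation.chromosome))
        & ((df["position"] - annotation.tss).abs() <= window_bp)
    )
    cis = TraitSummaryStats(
        protein_ss.trait_id, protein_ss.trait_type, df[in_cis].copy(),
        protein_ss.sample_size,
    )
    if len(cis) == 0:
        return []
    return clump(cis, ld, p_threshold, r2_threshold, clump_window_bp)


def exclusivity_filter(
    cis_instruments_by_protein: Mapping[str, List[str]],
) -> Tuple[Dict[str, List[str]], Dict[str, int]]:
    """Drop variants that are cis-pQTLs for more than one protein.

    Returns the filtered mapping and counts of retained/removed variant
    occurrences.  After filtering, no variant occurs in more than one
    protein's list.
    """
    owner_count: Dict[str, int] = {}
    for prot, variants in cis_instruments_by_protein.items():
        for v in set(variants):
            owner_count[v] = owner_count.get(v, 0) + 1
    shared = {v for v, c in owner_count.items() if c > 1}
    filtered = {
        prot: [v for v in variants if v not in shared]
        for prot, variants in cis_instruments_by_protein.items()
    }
    total = sum(len(vs) for vs in cis_instruments_by_protein.values())
    kept = sum(len(vs) for vs in filtered.values())
    return filtered, {"retained": kept, "removed": total - kept}
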