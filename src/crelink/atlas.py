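"""cCRE atlas operations: genomic annotation, variant colocalization, and
cell-type/category specificity calls.

Annotation classes follow the promoter > exonic > intronic > intergenic
precedence with a promoter window of TSS +/- 3,000 bp (strand-aware TSS).

Specificity follows the quartile rule: a peak detected in one cell type is
assigned to that cell type; a peak whose detected types all share a category
is assigned to that category; otherwise a category c is assigned iff the
peak is detected in strictly more than 75% of c's cell types (e.g. > 6 of 8
epithelial types), with multiple categories allowed when several pass.
A "depleted" flag records categories where the detected count falls strictly
below the 25th percentile; it does not affect assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set

import pandas as pd

from .taxonomy import TaxonomyError, category_sizes

TSS_FLANK = 3_000


@dataclass
class SpecificityCall:
    peak: str
    level: str  # "single cell type" | "single category" | "multiple categories" | "shared"
    assigned: Set[str]
    assigned_cell_type: Optional[str] = None
    depleted: Set[str] = field(default_factory=set)


def category_threshold(n_types_in_category: int, q: float = 0.75) -> float:
    """The strict lower bound on detected cell types for category assignment.

    With 8 epithelial types the 75th-percentile threshold is 6: a peak must
    be detected in more than 6 epithelial types to be attributed to the
    epithelial category.
    """
    return q * n_types_in_category


def annotate_peak(
    chrom: str,
    start: int,
    end: int,
    gene_models: pd.DataFrame,
    exons: Optional[pd.DataFrame] = None,
    tss_flank: int = TSS_FLANK,
) -> Dict[str, Optional[str]]:
    """Classify a peak as promoter / exonic / intronic / intergenic.

    ``gene_models`` columns: gene, chrom, tss, strand, and optionally
    gene_start / gene_end for gene bodies. ``exons`` columns: gene, chrom,
    start, end (0-based half-open). Precedence: promoter > exonic >
    intronic > intergenic. Returns {"annotation": ..., "promoter_gene": ...}.
    """
    if start >= end:
        raise ValueError("peak start must be < end")
    g = gene_models.loc[gene_models["chrom"] == chrom]
    # promoter: overlap with [TSS - flank, TSS + flank] (strand-aware TSS)
    for _, row in g.iterrows():
        lo, hi = int(row["tss"]) - tss_flank, int(row["tss"]) + tss_flank
        if start < hi + 1 and end > lo:  # interval overlap, promoter window inclusive
            return {"annotation": "promoter", "promoter_gene": str(row["gene"])}
    if exons is not None:
        e = exons.loc[exons["chrom"] == chrom]
        if ((start < e["end"]) & (end > e["start"])).any():
            return {"annotation": "exonic", "promoter_gene": None}
    if {"gene_start", "gene_end"}.issubset(g.columns):
        inside = (start < g["gene_end"]) & (end > g["gene_start"])
        if inside.any():
            return {"annotation": "intronic", "promoter_gene": None}
    return {"annotation": "intergenic", "promoter_gene": None}


def annotate_atlas(
    peaks: pd.DataFrame,
    gene_models: pd.DataFrame,
    exons: Optional[pd.DataFrame] = None,
    tss_flank: int = TSS_FLANK,
) -> pd.DataFrame:
    """Vector of annotate_peak over an atlas table (name, chrom, start, end)."""
    out = []
    for _, p in peaks.iterrows():
        ann = annotate_peak(p["chrom"], int(p["start"]), int(p["end"]), gene_models, exons, tss_flank)
        out.append({"name": p["name"], **ann})
    return peaks.merge(pd.DataFrame(out), on="name")


def colocalize(ccvs: pd.DataFrame, peaks: pd.DataFrame, detected_in: Dict[str, Set[str]]) -> pd.DataFrame:
    """Overlap 1-based variant positions with 0-based half-open peaks.

    A variant at position p falls in a peak iff start < p <= end, i.e. the
    first covered base is start+1. Returns one row per (variant, peak) with
    the peak's detected cell types.
    """
    rows = []
    for _, v in ccvs.iterrows():
        chrom, pos = v["chrom"], int(v["pos"])
        hits = peaks.loc[
            (peaks["chrom"] == chrom) & (peaks["start"] < pos) & (pos <= peaks["end"])
        ]
        for _, pk in hits.iterrows():
            rows.append(
                {
                    "variant_id": v["variant_id"],
                    "peak": pk["name"],
                    "cell_types": ",".join(sorted(detected_in.get(pk["name"], set()))),
                }
            )
    return pd.DataFrame(rows, columns=["variant_id", "peak", "cell_types"])


def assign_specificity(
    peak: str,
    detected_in: Set[str],
    taxonomy: Dict[str, str],
    q_hi: float = 0.75,
    q_lo: float = 0.25,
) -> SpecificityCall:
    """Quartile-rule category attribution for one peak."""
    if not detected_in:
        raise ValueError(f"peak {peak} detected in no cell type")
    unknown = detected_in - set(taxonomy)
    if unknown:
        raise TaxonomyError(f"unknown cell types: {sorted(unknown)}")
    sizes = category_sizes(taxonomy)
    counts = {c: 0 for c in sizes}
    for t in detected_in:
        counts[taxonomy[t]] += 1
    depleted = {c for c, k in counts.items() if k < q_lo * sizes[c]}

    if len(detected_in) == 1:
        t = next(iter(detected_in))
        return SpecificityCall(peak, "single cell type", {taxonomy[t]}, t, depleted)
    cats_present = {taxonomy[t] for t in detected_in}
    if len(cats_present) == 1:
        return SpecificityCall(peak, "single category", cats_present, None, depleted)
    passing = {c for c, k in counts.items() if k > category_threshold(sizes[c], q_hi)}
    if not passing:
        return SpecificityCall(peak, "shared", set(), None, depleted)
    level = "single category" if len(passing) == 1 else "multiple categories"
    return SpecificityCall(peak, level, passing, None, depleted)


def assign_specificity_table(
    detected_in: Dict[str, Set[str]], taxonomy: Dict[str, str]
) -> pd.DataFrame:
    rows = []
    for peak, types in detected_in.items():
        call = assign_specificity(peak, types, taxonomy)
        rows.append(
            {
                "peak": peak,
                "level": call.level,
                "assigned": ",".join(sorted(call.assigned)),
                "assigned_cell_type": call.assigned_cell_type or "",
            }
        )
    return pd.DataFrame(rows)


def summarize_locus(
    overlaps: pd.DataFrame,
    calls: Dict[str, SpecificityCall],
    rule: str = "unanimity",
) -> str:
    """Category label for a locus from its CCV-colocalized cCREs.

    Unanimity (default): the locus takes a category iff every colocalized
    cCRE is assigned solely to that category; otherwise "mixed". The
    "majority" rule takes the modal single-category assignment instead.
    """
    if len(overlaps) == 0:
        raise ValueError("no overlaps for this locus")
    peak_cats: List[Optional[str]] = []
    for peak in overlaps["peak"].unique():
        call = calls[peak]
        peak_cats.append(next(iter(call.assigned)) if len(call.assigned) == 1 else None)
    if rule == "unanimity":
        uniq = set(peak_cats)
        if len(uniq) == 1 and None not in uniq:
            return peak_cats[0]
        return "mixed"
    if rule == "majority":
        named = [c for c in peak_cats if c is not None]
        if not named:
            return "mixed"
        counts = pd.Series(named).value_counts()
        top = counts.index[0]
        return top if (counts == counts.max()).sum() == 1 else "mixed"
    raise ValueError(f"unknown rule: {rule}")
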