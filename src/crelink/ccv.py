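"""Candidate causal variant (CCV) compilation from GWAS summary statistics.

A locus's CCV set is the lead variant plus every variant passing either of
two rules against the lead:

* likelihood-ratio rule — the variant's likelihood relative to the lead,
  computed from two-sided p-values via the 1-df chi-square quantile
  approximation, is at least 1:1000 (ratio >= 1e-3);
* LD rule — R^2 to the lead exceeds 0.8 (ties at the threshold inclusive,
  compared after rounding to 6 decimals).

Studies differ in which rules they apply (some LD-only); conditional lead
variants without proxies enter as singletons. Overlapping loci are merged by
CCV-footprint interval overlap and variants deduplicated by
(chrom, pos, ref, alt).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

LLR_CUTOFF = 1e-3  # "1:1000" likelihood ratio against the lead
R2_CUTOFF = 0.8


class RuleError(ValueError):
    """A selection rule was requested without the inputs it needs."""


@dataclass(frozen=True)
class StudyRules:
    """Which inclusion rules a study's summary statistics support."""

    use_llr: bool = True
    use_r2: bool = True
    llr_cutoff: float = LLR_CUTOFF
    r2_cutoff: float = R2_CUTOFF


@dataclass
class CcvSet:
    locus_id: str
    lead_variant_id: str
    members: Dict[str, Set[str]] = field(default_factory=dict)  # variant -> reasons

    @property
    def variant_ids(self) -> Set[str]:
        return set(self.members)


def likelihood_ratio_vs_lead(p_variant: float, p_lead: float) -> float:
    """Likelihood of the variant relative to the lead from two-sided p-values.

    Both p-values are converted to 1-df chi-square statistics; the ratio is
    exp((chi2_variant - chi2_lead) / 2), so equal p-values give exactly 1 and
    a weaker variant gives a ratio below 1.
    """
    for p in (p_variant, p_lead):
        if not 0 < p <= 1:
            raise ValueError(f"p-value outside (0, 1]: {p}")
    chi2_v = stats.chi2.isf(p_variant, df=1)
    chi2_l = stats.chi2.isf(p_lead, df=1)
    return float(np.exp((chi2_v - chi2_l) / 2.0))


def compile_ccvs(variants: pd.DataFrame, locus_id: str, rules: StudyRules = StudyRules()) -> CcvSet:
    """Apply the study's selection rules to one locus.

    ``variants`` needs columns variant_id, p_value, r2_to_lead, is_lead and
    optionally is_conditional. Conditional leads are included as singleton
    members with reason "conditional".
    """
    leads = variants.loc[variants["is_lead"]]
    if len(leads) != 1:
        raise ValueError(f"locus {locus_id} must have exactly one lead, found {len(leads)}")
    lead = leads.iloc[0]
    ccv = CcvSet(locus_id=locus_id, lead_variant_id=str(lead["variant_id"]))
    ccv.members[ccv.lead_variant_id] = {"lead"}

    if rules.use_llr and variants["p_value"].isna().any():
        raise RuleError(f"locus {locus_id}: LLR rule requested but p-values missing")

    p_lead = float(lead["p_value"])
    for _, row in variants.iterrows():
        vid = str(row["variant_id"])
        if bool(row.get("is_conditional", False)):
            ccv.members.setdefault(vid, set()).add("conditional")
        if vid == ccv.lead_variant_id:
            continue
        if rules.use_llr:
            ratio = likelihood_ratio_vs_lead(float(row["p_value"]), p_lead)
            if ratio >= rules.llr_cutoff:
                ccv.members.setdefault(vid, set()).add("LLR")
        if rules.use_r2 and not pd.isna(row.get("r2_to_lead", np.nan)):
            # ties at the threshold are inclusive after rounding
            if round(float(row["r2_to_lead"]), 6) >= rules.r2_cutoff:
                ccv.members.setdefault(vid, set()).add("R2")
    return ccv


def merge_loci(
    ccv_sets: List[CcvSet], coords: pd.DataFrame
) -> Tuple[List[Set[str]], pd.DataFrame]:
    """Merge loci whose CCV footprints overlap; deduplicate the union table.

    ``coords`` has columns variant_id, chrom, pos, ref, alt. Returns the
    merged partition (sets of input locus_ids) and the deduplicated CCV
    table with a merged_locus column.
    """
    coord_ix = coords.set_index("variant_id")
    intervals = []
    for s in ccv_sets:
        sub = coord_ix.loc[sorted(s.variant_ids & set(coord_ix.index))]
        if len(sub) == 0:
            intervals.append((s.locus_id, None, None, None))
            continue
        chroms = sub["chrom"].unique()
        # a locus footprint spans one chromosome; mixed input is a data error
        if len(chroms) != 1:
            raise ValueError(f"locus {s.locus_id} spans multiple chromosomes")
        intervals.append((s.locus_id, chroms[0], int(sub["pos"].min()), int(sub["pos"].max())))

    # sweep per chromosome over [min, max] footprints; any overlap merges
    groups: List[Set[str]] = []
    by_chrom: Dict[str, List[Tuple[int, int, str]]] = {}
    for lid, chrom, lo, hi in intervals:
        if chrom is None:
            groups.append({lid})
        else:
            by_chrom.setdefault(chrom, []).append((lo, hi, lid))
    for chrom, ivs in sorted(by_chrom.items()):
        ivs.sort()
        cur: Set[str] = set()
        cur_hi = None
        for lo, hi, lid in ivs:
            if cur and lo <= cur_hi:
                cur.add(lid)
                cur_hi = max(cur_hi, hi)
            else:
                if cur:
                    groups.append(cur)
                cur = {lid}
                cur_hi = hi
        if cur:
            groups.append(cur)

    locus_of = {lid: i for i, grp in enumerate(groups) for lid in grp}
    rows = []
    seen: Set[Tuple] = set()
    for s in ccv_sets:
        for vid in sorted(s.variant_ids):
            if vid not in coord_ix.index:
                continue
            c = coord_ix.loc[vid]
            key = (c["chrom"], int(c["pos"]), c["ref"], c["alt"])
            if key in seen:
                continue
            seen.add(key)
            rows.append(
                {
                    "variant_id": vid,
                    "chrom": c["chrom"],
                    "pos": int(c["pos"]),
                    "ref": c["ref"],
                    "alt": c["alt"],
                    "merged_locus": f"ML{locus_of[s.locus_id]}",
                    "reasons": ",".join(sorted(s.members[vid])),
                }
            )
    return groups, pd.DataFrame(rows)
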