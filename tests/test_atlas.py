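"""Peak annotation, variant colocalization, and the quartile specificity rule."""

import itertools

import numpy as np
import pandas as pd
import pytest

from crelink.atlas import (
    annotate_peak,
    assign_specificity,
    category_threshold,
    colocalize,
    summarize_locus,
)
from crelink.taxonomy import DEFAULT_TAXONOMY, TaxonomyError

GENES = pd.DataFrame(
    {
        "gene": ["g1", "g2"],
        "chrom": ["chr1", "chr1"],
        "tss": [50_000, 90_000],
        "strand": ["+", "-"],
        "gene_start": [50_000, 70_000],
        "gene_end": [60_000, 90_000],
    }
)
EXONS = pd.DataFrame(
    {"gene": ["g2"], "chrom": ["chr1"], "start": [75_000], "end": [76_000]}
)


class TestAnnotate:
    def test_promoter_window_is_tss_plus_minus_3000(self):
        assert annotate_peak("chr1", 52_500, 53_500, GENES)["annotation"] == "promoter"
        assert annotate_peak("chr1", 53_100, 54_000, GENES)["annotation"] != "promoter"

    def test_no_genes_on_chromosome_gives_intergenic(self):
        assert annotate_peak("chrX", 100, 200, GENES)["annotation"] == "intergenic"

    def test_precedence_promoter_over_exon(self):
        # overlaps g1's promoter window and g2's exon region if it spanned;
        # build a peak overlapping g2 exon AND g2 promoter window
        got = annotate_peak("chr1", 87_500, 88_500, GENES, EXONS)
        assert got == {"annotation": "promoter", "promoter_gene": "g2"}

    def test_exonic_and_intronic_classes(self):
        assert annotate_peak("chr1", 75_200, 75_400, GENES, EXONS)["annotation"] == "exonic"
        assert annotate_peak("chr1", 78_000, 79_000, GENES, EXONS)["annotation"] == "intronic"

    def test_against_interval_overlap_oracle(self, rng):
        flank = 3000
        for _ in range(200):
            start = int(rng.integers(40_000, 100_000))
            end = start + int(rng.integers(100, 2_000))
            got = annotate_peak("chr1", start, end, GENES, EXONS)["annotation"]
            promoter = any(
                start <= t + flank and end > t - flank
                for t in GENES["tss"]
            )
            exonic = any(start < e and end > s for s, e in zip(EXONS["start"], EXONS["end"]))
            genic = any(
                start < ge and end > gs
                for gs, ge in zip(GENES["gene_start"], GENES["gene_end"])
            )
            expected = (
                "promoter" if promoter else "exonic" if exonic else "intronic" if genic else "intergenic"
            )
            assert got == expected, (start, end)


class TestColocalize:
    PEAKS = pd.DataFrame(
        {"name": ["p1"], "chrom": ["chr1"], "start": [1000], "end": [1500]}
    )
    DET = {"p1": {"AT2"}}

    def _ccvs(self, pos):
        return pd.DataFrame(
            {"variant_id": ["v"], "chrom": ["chr1"], "pos": [pos], "ref": ["A"], "alt": ["T"]}
        )

    def test_first_base_of_peak_overlaps(self):
        assert len(colocalize(self._ccvs(1001), self.PEAKS, self.DET)) == 1

    def test_base_before_peak_does_not(self):
        assert len(colocalize(self._ccvs(1000), self.PEAKS, self.DET)) == 0

    def test_last_base_inclusive(self):
        assert len(colocalize(self._ccvs(1500), self.PEAKS, self.DET)) == 1
        assert len(colocalize(self._ccvs(1501), self.PEAKS, self.DET)) == 0

    def test_matches_brute_force_double_loop(self, rng):
        peaks = pd.DataFrame(
            {
                "name": [f"p{i}" for i in range(30)],
                "chrom": "chr1",
                "start": rng.integers(0, 10_000, 30),
            }
        )
        peaks["end"] = peaks["start"] + rng.integers(50, 500, 30)
        det = {n: {"AT2"} for n in peaks["name"]}
        ccvs = pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(50)],
                "chrom": "chr1",
                "pos": rng.integers(0, 11_000, 50),
                "ref": "A",
                "alt": "T",
            }
        )
        got = set(map(tuple, colocalize(ccvs, peaks, det)[["variant_id", "peak"]].values))
        expected = {
            (v["variant_id"], p["name"])
            for _, v in ccvs.iterrows()
            for _, p in peaks.iterrows()
            if p["start"] < v["pos"] <= p["end"]
        }
        assert got == expected


EPI = [t for t, c in DEFAULT_TAXONOMY.items() if c == "epithelial"]
IMM = [t for t, c in DEFAULT_TAXONOMY.items() if c == "immune"]
END = [t for t, c in DEFAULT_TAXONOMY.items() if c == "endothelial"]
STR = [t for t, c in DEFAULT_TAXONOMY.items() if c == "stromal"]


def _detected(n_epi, n_imm, n_end, n_str):
    return set(EPI[:n_epi]) | set(IMM[:n_imm]) | set(END[:n_end]) | set(STR[:n_str])


class TestSpecificity:
    def test_worked_example_7_2_1_1_assigned_epithelial(self):
        call = assign_specificity("pk", _detected(7, 2, 1, 1), DEFAULT_TAXONOMY)
        assert call.assigned == {"epithelial"}

    def test_epithelial_threshold_is_6_of_8(self):
        assert category_threshold(8) == 6.0
        # 7 > 6 passes, 6 does not (strict inequality)
        assert assign_specificity("pk", _detected(7, 2, 0, 1), DEFAULT_TAXONOMY).assigned == {"epithelial"}
        assert assign_specificity("pk", _detected(6, 2, 0, 1), DEFAULT_TAXONOMY).assigned == set()

    def test_single_cell_type(self):
        call = assign_specificity("pk", {EPI[0]}, DEFAULT_TAXONOMY)
        assert call.level == "single cell type"
        assert call.assigned_cell_type == EPI[0]
        assert call.assigned == {"epithelial"}

    def test_single_category_when_all_types_share_it(self):
        call = assign_specificity("pk", set(IMM[:3]), DEFAULT_TAXONOMY)
        assert call.level == "single category"
        assert call.assigned == {"immune"}

    def test_two_categories_can_pass_simultaneously(self):
        call = assign_specificity("pk", _detected(7, 0, 4, 1), DEFAULT_TAXONOMY)
        assert call.assigned == {"epithelial", "endothelial"}
        assert call.level == "multiple categories"

    def test_unknown_cell_type_raises(self):
        with pytest.raises(TaxonomyError):
            assign_specificity("pk", {"martian"}, DEFAULT_TAXONOMY)

    def test_exhaustive_enumeration_against_direct_rule_oracle(self):
        sizes = {"epithelial": 8, "immune": 7, "endothelial": 4, "stromal": 4}
        for ne, ni, nd, ns in itertools.product(range(9), range(8), range(5), range(5)):
            if ne + ni + nd + ns == 0:
                continue
            detected = _detected(ne, ni, nd, ns)
            call = assign_specificity("pk", detected, DEFAULT_TAXONOMY)
            counts = {"epithelial": ne, "immune": ni, "endothelial": nd, "stromal": ns}
            present = {c for c, k in counts.items() if k > 0}
            if len(detected) == 1:
                expected = present
            elif len(present) == 1:
                expected = present
            else:
                expected = {c for c, k in counts.items() if k > 0.75 * sizes[c]}
            assert call.assigned == expected, (ne, ni, nd, ns)

    def test_permutation_invariance_and_monotonicity(self, rng):
        for _ in range(50):
            ne, ni = int(rng.integers(1, 9)), int(rng.integers(0, 8))
            nd, ns = int(rng.integers(0, 5)), int(rng.integers(0, 5))
            detected = _detected(ne, ni, nd, ns)
            base = assign_specificity("pk", detected, DEFAULT_TAXONOMY).assigned
            # permutation of membership order cannot matter (sets), but adding
            # another epithelial type must never remove epithelial
            if ne < 8:
                grown = assign_specificity("pk", detected | {EPI[ne]}, DEFAULT_TAXONOMY).assigned
                if "epithelial" in base:
                    assert "epithelial" in grown


class TestSummarizeLocus:
    def _overlaps(self, peaks):
        return pd.DataFrame({"variant_id": [f"v{i}" for i in range(len(peaks))], "peak": peaks})

    def test_unanimous_epithelial(self):
        calls = {
            "p1": assign_specificity("p1", _detected(7, 2, 1, 1), DEFAULT_TAXONOMY),
            "p2": assign_specificity("p2", {EPI[0]}, DEFAULT_TAXONOMY),
        }
        assert summarize_locus(self._overlaps(["p1", "p2"]), calls) == "epithelial"

    def test_mixed_when_categories_differ(self):
        calls = {
            "p1": assign_specificity("p1", {EPI[0]}, DEFAULT_TAXONOMY),
            "p2": assign_specificity("p2", {IMM[0]}, DEFAULT_TAXONOMY),
        }
        assert summarize_locus(self._overlaps(["p1", "p2"]), calls) == "mixed"

    def test_randomized_against_set_comprehension_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 6))
            calls = {}
            peaks = []
            for i in range(n):
                det = _detected(
                    int(rng.integers(0, 9)), int(rng.integers(0, 8)),
                    int(rng.integers(0, 5)), int(rng.integers(0, 5)),
                ) or {EPI[0]}
                calls[f"p{i}"] = assign_specificity(f"p{i}", det, DEFAULT_TAXONOMY)
                peaks.append(f"p{i}")
            got = summarize_locus(self._overlaps(peaks), calls)
            cats = {
                next(iter(c.assigned)) if len(c.assigned) == 1 else None
                for c in calls.values()
            }
            expected = cats.pop() if len(cats) == 1 and None not in cats else "mixed"
            assert got == (expected or "mixed")
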