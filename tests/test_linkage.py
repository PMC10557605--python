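"""Metacells, co-accessibility, modules, peak-gene links, tier assignment."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from crelink import linkage
from crelink.linkage import (
    ConfigurationError,
    LinkParams,
    assign_tiers,
    coaccessibility,
    detect_modules,
    link_peaks_to_genes,
    lsi_embedding,
    make_metacells,
    tiers_table,
)
from crelink.simulate import SimConfig, generate_multiome


def _peaks_frame(n, spacing=5_000, width=500, start0=10_000):
    starts = start0 + np.arange(n) * spacing
    return pd.DataFrame(
        {
            "name": [f"p{i}" for i in range(n)],
            "chrom": "chr1",
            "start": starts,
            "end": starts + width,
        }
    )


class TestMetacells:
    def test_k1_is_identity(self, rng):
        M = rng.poisson(1.0, size=(20, 30))
        emb = rng.standard_normal((30, 3))
        meta, members = make_metacells(M, emb, k=1, seed=0)
        assert meta.shape == M.shape
        cols = {tuple(m) for m in members}
        assert cols == {(i,) for i in range(30)}

    def test_metacell_totals_are_member_sums(self, rng):
        M = rng.poisson(2.0, size=(15, 60))
        emb = rng.standard_normal((60, 4))
        meta, members = make_metacells(M, emb, k=5, seed=0)
        for col, m in zip(meta.T, members):
            np.testing.assert_array_equal(col, M[:, m].sum(axis=1))

    def test_separated_clusters_never_mix(self, rng):
        emb = np.concatenate([rng.standard_normal((40, 2)), rng.standard_normal((40, 2)) + 50])
        M = rng.poisson(1.0, size=(10, 80))
        _, members = make_metacells(M, emb, k=8, seed=0)
        for m in members:
            side = set(m < 40)
            assert len(side) == 1  # all members on one side

    def test_bad_k_rejected(self, rng):
        M = rng.poisson(1.0, size=(5, 10))
        emb = rng.standard_normal((10, 2))
        with pytest.raises(ConfigurationError):
            make_metacells(M, emb, k=0)
        with pytest.raises(ConfigurationError):
            make_metacells(M, emb, k=10)


class TestCoaccessibility:
    def test_duplicated_nearby_peaks_score_high(self, rng):
        base = rng.poisson(3.0, size=200).astype(float)
        M = np.vstack([base + rng.poisson(0.2, 200), base + rng.poisson(0.2, 200)]
                      + [rng.poisson(3.0, size=200).astype(float) for _ in range(8)])
        peaks = _peaks_frame(10, spacing=1_000)
        edges = coaccessibility(M, peaks)
        top = edges.set_index(["peak_a", "peak_b"])["score"].get(("p0", "p1"), 0.0)
        assert top > 0.5

    def test_independent_peaks_mostly_near_zero(self, rng):
        n_meta, n_peaks = 200, 60
        M = rng.binomial(5, 0.3, size=(n_peaks, n_meta)).astype(float)
        peaks = _peaks_frame(n_peaks)
        edges = coaccessibility(M, peaks)
        mids = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
        in_range = sum(
            1
            for i in range(n_peaks)
            for j in range(i + 1, n_peaks)
            if abs(mids[i] - mids[j]) <= 500_000
        )
        n_large = (edges["score"].abs() >= 0.1).sum()
        assert 1 - n_large / in_range >= 0.99

    def test_scores_bounded(self, rng):
        M = rng.poisson(2.0, size=(20, 150)).astype(float)
        edges = coaccessibility(M, _peaks_frame(20))
        assert (edges["score"].abs() <= 1.0).all()


class TestModules:
    def _clique_edges(self, groups, intra, inter=0.0, rng=None):
        rows = []
        names = [p for g in groups for p in g]
        for g in groups:
            for i, a in enumerate(g):
                for b in g[i + 1 :]:
                    rows.append({"peak_a": a, "peak_b": b, "score": intra})
        if inter > 0:
            for gi in range(len(groups) - 1):
                rows.append({"peak_a": groups[gi][0], "peak_b": groups[gi + 1][0], "score": inter})
        return pd.DataFrame(rows)

    def test_two_planted_cliques_recovered_exactly(self):
        g1 = [f"a{i}" for i in range(5)]
        g2 = [f"b{i}" for i in range(5)]
        mods = detect_modules(self._clique_edges([g1, g2], intra=0.6), seed=0)
        assert sorted(map(sorted, mods)) == [sorted(g1), sorted(g2)]

    def test_everything_below_cutoff_gives_no_modules(self):
        edges = self._clique_edges([["x", "y", "z"]], intra=0.2)
        assert detect_modules(edges, cutoff=0.32, seed=0) == []

    def test_planted_partition_ari(self, rng):
        groups = [[f"m{k}_{i}" for i in range(5)] for k in range(5)]
        rows = []
        for g in groups:
            for i, a in enumerate(g):
                for b in g[i + 1 :]:
                    rows.append({"peak_a": a, "peak_b": b, "score": 0.5 + 0.1 * rng.uniform()})
        for k in range(4):
            rows.append({"peak_a": groups[k][0], "peak_b": groups[k + 1][0], "score": 0.1})
        mods = detect_modules(pd.DataFrame(rows), seed=0)
        truth = {p: k for k, g in enumerate(groups) for p in g}
        pred = {p: k for k, m in enumerate(mods) for p in m}
        common = sorted(set(truth) & set(pred))
        ari = adjusted_rand_score([truth[p] for p in common], [pred[p] for p in common])
        assert ari >= 0.9


class TestLinks:
    def test_constant_peak_excluded_and_logged(self, rng):
        atac = rng.poisson(1.0, size=(3, 200))
        atac[0] = 1  # constant
        rna = rng.poisson(2.0, size=(2, 200))
        peaks = _peaks_frame(3)
        peaks["gc"] = 0.5
        peaks["width"] = 500
        genes = pd.DataFrame({"gene": ["g0", "g1"], "chrom": "chr1", "tss": [12_000, 20_000]})
        links, skipped = link_peaks_to_genes(atac, rna, peaks, genes, LinkParams(n_background=2))
        assert "p0" not in set(links["peak"])
        assert any("p0" in s for s in skipped)

    def test_min_cells_and_distance_filters(self, rng):
        atac = rng.poisson(1.0, size=(4, 300))
        atac[1, 5:] = 0
        atac[1, :5] = [1, 2, 1, 3, 1]  # detected in 5 cells only
        rna = rng.poisson(2.0, size=(1, 300))
        peaks = _peaks_frame(4)
        peaks["gc"], peaks["width"] = 0.5, 500
        params = LinkParams(p_cutoff=1.01, score_cutoff=-1, n_background=2)
        far_gene = pd.DataFrame({"gene": ["g"], "chrom": "chr1", "tss": [5_000_000]})
        links, _ = link_peaks_to_genes(atac, rna, peaks, far_gene, params)
        assert len(links) == 0  # beyond the 1 Mb cis window
        near_gene = pd.DataFrame({"gene": ["g"], "chrom": "chr1", "tss": [12_000]})
        links, _ = link_peaks_to_genes(atac, rna, peaks, near_gene, params)
        assert "p1" not in set(links["peak"])  # fails min.cells = 10
        assert set(links["peak"]) == {"p0", "p2", "p3"}

    def test_planted_link_r_close_to_direct_pearson_oracle(self, default_config, default_multiome):
        matrices, _, _ = default_multiome
        links, _ = link_peaks_to_genes(
            matrices.atac, matrices.rna, matrices.peaks, matrices.genes,
            LinkParams(p_cutoff=1.01, score_cutoff=-1),
        )
        ix = links.set_index(["peak", "gene"])["r"]
        for p, g, _l in default_config.planted_links:
            r_link = ix[(f"peak{p:05d}", f"gene{g:03d}")]
            r_direct = np.corrcoef(matrices.atac[p], matrices.rna[g])[0, 1]
            assert r_direct > 0
            assert abs(r_link - r_direct) < 0.1


class TestTiers:
    GENES = pd.DataFrame(
        {
            "gene": ["gA", "gB", "gC", "gD"],
            "chrom": "chr1",
            "tss": [15_000, 25_000, 35_000, 45_000],
        }
    )

    def _run_toy(self):
        peaks = _peaks_frame(10)
        overlaps = pd.DataFrame(
            {"variant_id": ["v1", "v2", "v3"], "peak": ["p1", "p3", "p5"]}
        )
        modules = [{"p1", "p2"}, {"p5", "p6", "p7"}]
        edges = pd.DataFrame(
            {
                "peak_a": ["p1", "p3", "p5", "p5"],
                "peak_b": ["p2", "p4", "p6", "p7"],
                "score": [0.6, 0.4, 0.55, 0.3],
            }
        )
        promoter_of = {"p1": "gA", "p2": "gB", "p4": "gA", "p7": "gD"}
        links = pd.DataFrame(
            {"peak": ["p2", "p1", "p6"], "gene": ["gC", "gD", "gD"],
             "r": [0.2, 0.2, 0.2], "z": [3, 3, 3], "p": [0.001] * 3,
             "n_cells_detected": [50] * 3}
        )
        out = assign_tiers(overlaps, modules, edges, promoter_of, links, peaks, self.GENES)
        return {(a.peak, a.gene): a.levels for a in out}

    def test_hand_enumerated_level_table(self):
        got = self._run_toy()
        expected = {
            ("p1", "gA"): {3},       # own promoter only; self never grants 1/2
            ("p1", "gB"): {1, 2},    # module partner p2 is gB's promoter, edge 0.6
            ("p1", "gC"): {4, 5},    # p2 linked to gC, co-module + direct edge
            ("p1", "gD"): {6},       # own link; 6 must not force 4/5 via self
            ("p5", "gD"): {1, 4, 5}, # p7 promoter in module; p6 linked, edge 0.55
        }
        assert got == expected
        assert ("p3", "gA") not in got  # edge 0.4 below the 0.5 direct cutoff

    def test_max_level_consistency(self):
        peaks = _peaks_frame(2)
        overlaps = pd.DataFrame({"variant_id": ["v"], "peak": ["p0"]})
        links = pd.DataFrame(
            {"peak": ["p0"], "gene": ["gA"], "r": [0.2], "z": [3], "p": [0.01],
             "n_cells_detected": [20]}
        )
        out = assign_tiers(overlaps, [], pd.DataFrame(columns=["peak_a", "peak_b", "score"]),
                           {"p0": "gA"}, links, peaks, self.GENES)
        (a,) = [x for x in out if x.gene == "gA"]
        assert a.levels == {3, 6}
        assert a.max_level == 6
        table = tiers_table(out)
        assert list(table.columns) == ["variant_id", "peak", "gene", "levels", "max_level"]

    def test_unknown_overlap_peak_raises(self):
        peaks = _peaks_frame(2)
        overlaps = pd.DataFrame({"variant_id": ["v"], "peak": ["ghost"]})
        with pytest.raises(KeyError):
            assign_tiers(overlaps, [], pd.DataFrame(columns=["peak_a", "peak_b", "score"]),
                         {}, pd.DataFrame(columns=["peak", "gene"]), peaks, self.GENES)


def test_coaccessibility_invariant_to_metacell_order(rng):
    M = rng.poisson(2.0, size=(12, 120)).astype(float)
    peaks = _peaks_frame(12)
    e1 = coaccessibility(M, peaks)
    e2 = coaccessibility(M[:, rng.permutation(120)], peaks)
    m1 = e1.set_index(["peak_a", "peak_b"])["score"]
    m2 = e2.set_index(["peak_a", "peak_b"])["score"]
    shared = m1.index.intersection(m2.index)
    np.testing.assert_allclose(m1[shared], m2[shared], atol=1e-8)
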