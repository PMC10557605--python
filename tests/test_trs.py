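"""Trait relevance scoring: weights, deviations, propagation, group means."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from crelink import trs
from crelink.trs import (
    ConfigurationError,
    category_means,
    colocalization_zscores,
    compare_groups,
    knn_graph,
    propagate,
    variant_peak_weights,
)


def _ccv_table(loci):
    rows = []
    for locus, vids in loci.items():
        for v in vids:
            rows.append({"variant_id": v, "merged_locus": locus})
    return pd.DataFrame(rows)


class TestWeights:
    def test_four_ccvs_in_one_peak_gives_weight_one(self):
        ccvs = _ccv_table({"L": ["v1", "v2", "v3", "v4"]})
        overlaps = pd.DataFrame({"variant_id": ["v1", "v2", "v3", "v4"], "peak": ["pk"] * 4})
        w, acct = variant_peak_weights(ccvs, overlaps, ["pk", "other"])
        assert w[0] == pytest.approx(1.0)
        assert w[1] == 0.0

    def test_locus_weight_conservation(self):
        ccvs = _ccv_table({"L": ["v1", "v2", "v3"]})
        overlaps = pd.DataFrame({"variant_id": ["v1"], "peak": ["pk"]})
        w, acct = variant_peak_weights(ccvs, overlaps, ["pk"])
        row = acct.set_index("locus").loc["L"]
        assert row["assigned_weight"] + row["unassigned_weight"] == pytest.approx(1.0)
        assert w.sum() == pytest.approx(row["assigned_weight"])

    def test_random_assignment_matches_direct_summation_oracle(self, rng):
        peaks = [f"p{i}" for i in range(20)]
        loci = {f"L{k}": [f"v{k}_{i}" for i in range(int(rng.integers(1, 8)))] for k in range(5)}
        ccvs = _ccv_table(loci)
        ov_rows = []
        for _, r in ccvs.iterrows():
            if rng.uniform() < 0.7:
                ov_rows.append({"variant_id": r["variant_id"], "peak": peaks[int(rng.integers(20))]})
        overlaps = pd.DataFrame(ov_rows)
        w, _ = variant_peak_weights(ccvs, overlaps, peaks)
        oracle = np.zeros(20)
        for _, r in overlaps.iterrows():
            locus = r["variant_id"].split("_")[0][1:]
            m = len(loci[f"L{locus}"])
            oracle[peaks.index(r["peak"])] += 1.0 / m
        np.testing.assert_allclose(w, oracle, atol=1e-12)


class TestZscores:
    def test_uniform_weights_give_near_zero_z(self, rng):
        X = rng.poisson(1.0, size=(50, 200))
        w = np.full(50, 1.0 / 50)
        z = colocalization_zscores(X, w, rng.uniform(0.3, 0.7, 50), seed=0)
        assert abs(np.mean(z)) < 0.5

    def test_weights_on_private_peaks_raise_their_cells(self, default_config, default_multiome):
        matrices, _, truth = default_multiome
        names = list(matrices.peaks["name"])
        from collections import Counter

        priv = Counter(lab for lev, lab in truth.true_specificity.values() if lev == "cell_type")
        target = priv.most_common(1)[0][0]
        w = np.zeros(len(names))
        for pk, (lev, lab) in truth.true_specificity.items():
            if lev == "cell_type" and lab == target:
                w[names.index(pk)] = 1.0
        w /= w.sum()
        z = colocalization_zscores(matrices.atac, w, matrices.peaks["gc"].to_numpy(), seed=0)
        is_target = (matrices.cells["cell_type"] == target).to_numpy()
        assert z[is_target].mean() > z[~is_target].mean()

    def test_all_zero_weights_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            colocalization_zscores(rng.poisson(1.0, (5, 10)), np.zeros(5), np.full(5, 0.5))


class TestPropagate:
    def test_restart_one_returns_seed_indicator(self, rng):
        raw = rng.standard_normal(50)
        G = knn_graph(rng.standard_normal((50, 3)), k=5)
        scores, seeds = propagate(raw, G, seed_proportion=0.1, restart_prob=1.0)
        assert np.all(scores[seeds] > 0)
        assert np.allclose(scores[~seeds], 0.0)

    def test_disconnected_component_gets_zero(self, rng):
        A = np.zeros((6, 6))
        A[0, 1] = A[1, 0] = A[1, 2] = A[2, 1] = A[0, 2] = A[2, 0] = 1
        A[3, 4] = A[4, 3] = A[4, 5] = A[5, 4] = A[3, 5] = A[5, 3] = 1
        raw = np.array([3.0, 2.0, 1.0, -1.0, -2.0, -3.0])
        scores, seeds = propagate(raw, A, seed_proportion=0.34, restart_prob=0.3)
        assert seeds[:2].all()
        assert np.allclose(scores[3:], 0.0)

    def test_matches_dense_power_iteration_oracle(self, rng):
        n = 100
        emb = rng.standard_normal((n, 5))
        G = knn_graph(emb, k=8)
        raw = rng.standard_normal(n)
        scores, seeds = propagate(raw, G, seed_proportion=0.1, restart_prob=0.05, tol=1e-14)
        A = G.toarray()
        W = A / np.maximum(A.sum(axis=1, keepdims=True), 1e-12)
        s = seeds / seeds.sum()
        p = s.copy()
        for _ in range(100_000):
            pn = 0.95 * (W.T @ p) + 0.05 * s
            pn /= pn.sum()
            if np.abs(pn - p).sum() < 1e-16:
                p = pn
                break
            p = pn
        oracle = (p - p.min()) / (p.max() - p.min()) * p.max()
        np.testing.assert_allclose(scores, oracle, atol=1e-8)

    def test_permutation_equivariance(self, rng):
        n = 60
        emb = rng.standard_normal((n, 4))
        G = knn_graph(emb, k=6)
        raw = rng.standard_normal(n)
        scores, _ = propagate(raw, G, seed_proportion=0.1)
        perm = rng.permutation(n)
        A = G.toarray()[np.ix_(perm, perm)]
        scores_p, _ = propagate(raw[perm], A, seed_proportion=0.1)
        np.testing.assert_allclose(scores_p, scores[perm], atol=1e-9)

    def test_no_seeds_rejected(self, rng):
        G = knn_graph(rng.standard_normal((20, 3)), k=3)
        with pytest.raises(ConfigurationError):
            propagate(rng.standard_normal(20), G, seed_proportion=0.001)


class TestGroups:
    def _cells(self, n=40):
        half = n // 2
        return pd.DataFrame(
            {
                "barcode": [f"b{i}" for i in range(n)],
                "cell_type": ["AT2"] * half + ["T"] * half,
                "category": ["epithelial"] * half + ["immune"] * half,
            }
        )

    def test_equal_scores_equal_means(self):
        cells = self._cells()
        table = compare_groups(np.ones(40), cells)
        assert table["mean_trs"].nunique() == 1

    def test_grouping_respects_category_taxonomy(self):
        cells = self._cells()
        scores = np.concatenate([np.full(20, 2.0), np.full(20, 1.0)])
        by_cat = category_means(scores, cells)
        assert list(by_cat["category"]) == ["epithelial", "immune"]
        assert by_cat["mean_trs"].tolist() == [2.0, 1.0]
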