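"""Per-cell trait relevance scores (TRS).

Variant weights are flat within each locus (each of a locus's m candidate
causal variants carries 1/m); a peak's weight is the sum over the variants it
contains. Per-cell colocalization deviations follow the chromVAR recipe —
observed weighted counts minus the depth-expected value — and are z-scored
against background weight vectors that reassign each weighted peak's weight
to a peak matched on GC content and mean accessibility. The top-scoring cells
seed a random walk with restart over the cell-cell kNN graph, smoothing the
signal into a propagated per-cell trait relevance score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.neighbors import NearestNeighbors


class ConfigurationError(ValueError):
    pass


def variant_peak_weights(
    ccv_table: pd.DataFrame,
    overlaps: pd.DataFrame,
    peak_names: Sequence[str],
) -> Tuple[np.ndarray, pd.DataFrame]:
    """Flat per-locus variant weights summed into per-peak weights.

    ``ccv_table`` needs variant_id and merged_locus; ``overlaps`` maps
    variant_id -> peak. Returns (weight vector aligned to peak_names, a
    per-locus accounting table of assigned vs unassigned weight).
    """
    peak_ix = {p: i for i, p in enumerate(peak_names)}
    w = np.zeros(len(peak_names))
    acct = []
    peak_of = overlaps.groupby("variant_id")["peak"].apply(list)
    for locus, grp in ccv_table.groupby("merged_locus"):
        m = len(grp)
        if m == 0:
            continue
        per_variant = 1.0 / m
        assigned = 0.0
        for vid in grp["variant_id"]:
            for pk in peak_of.get(vid, []):
                w[peak_ix[pk]] += per_variant
                assigned += per_variant
        acct.append({"locus": locus, "n_ccvs": m, "assigned_weight": assigned, "unassigned_weight": 1.0 - min(assigned, 1.0)})
    return w, pd.DataFrame(acct)


def colocalization_zscores(
    atac: np.ndarray,
    weights: np.ndarray,
    gc: np.ndarray,
    n_bg_iterations: int = 50,
    n_bins: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Bias-corrected per-cell deviation z-scores (gchromVAR style).

    deviation_c = sum_j w_j (x_jc - e_jc) with e_jc the depth expectation
    (cell total x peak share of the grand total). The null reassigns each
    peak's weight to a random peak from the same (GC, mean accessibility)
    equal-frequency bin, n_bg_iterations times.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.min() < 0:
        raise ConfigurationError("weights must be non-negative")
    if not np.any(weights > 0):
        raise ConfigurationError("all-zero weight vector")
    X = atac.astype(float)
    cell_tot = X.sum(axis=0)
    peak_tot = X.sum(axis=1)
    grand = max(cell_tot.sum(), 1e-12)
    E = np.outer(peak_tot / grand, cell_tot)
    D = X - E

    # equal-frequency 2D bins over (GC, mean accessibility)
    side = max(int(np.round(np.sqrt(n_bins))), 1)
    mean_acc = X.mean(axis=1)
    gbin = np.clip((stats_rankdata(gc) * side).astype(int), 0, side - 1)
    abin = np.clip((stats_rankdata(mean_acc) * side).astype(int), 0, side - 1)
    bin_id = gbin * side + abin
    bins: Dict[int, np.ndarray] = {b: np.where(bin_id == b)[0] for b in np.unique(bin_id)}

    rng = np.random.default_rng(seed)
    dev = weights @ D
    weighted = np.where(weights > 0)[0]
    bg_devs = np.empty((n_bg_iterations, X.shape[1]))
    for it in range(n_bg_iterations):
        wbg = np.zeros_like(weights)
        for j in weighted:
            pool = bins[bin_id[j]]
            wbg[rng.choice(pool)] += weights[j]
        bg_devs[it] = wbg @ D
    mu = bg_devs.mean(axis=0)
    sd = bg_devs.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (dev - mu) / sd


def stats_rankdata(x: np.ndarray) -> np.ndarray:
    """Fractional ranks in [0, 1)."""
    order = np.argsort(np.argsort(x, kind="stable"), kind="stable")
    return order / len(x)


def knn_graph(embedding: np.ndarray, k: int = 30, mutual: bool = True) -> sparse.csr_matrix:
    """Binary (mutual) kNN adjacency over cells."""
    n = embedding.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    rows = np.repeat(np.arange(n), idx.shape[1] - 1)
    cols = idx[:, 1:].ravel()
    A = sparse.csr_matrix((np.ones_like(rows, dtype=float), (rows, cols)), shape=(n, n))
    if mutual:
        A = A.minimum(A.T)
    else:
        A = A.maximum(A.T)
    return A


def propagate(
    raw_z: np.ndarray,
    graph: sparse.spmatrix | np.ndarray,
    seed_proportion: float = 0.05,
    restart_prob: float = 0.05,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> Tuple[np.ndarray, np.ndarray]:
    """Random walk with restart from the top raw_z cells.

    Seeds are the top ``seed_proportion`` of cells by raw_z; the walk
    restarts to the uniform seed distribution with probability
    ``restart_prob`` and iterates until the L1 change falls below ``tol``.
    Scores are min-max scaled onto [0, max]. Returns (trs, is_seed).
    """
    n = len(raw_z)
    n_seeds = int(round(seed_proportion * n))
    if n_seeds < 1:
        raise ConfigurationError("seed proportion selects no cells")
    seed_ix = np.argsort(raw_z)[::-1][:n_seeds]
    is_seed = np.zeros(n, dtype=bool)
    is_seed[seed_ix] = True
    s = is_seed / n_seeds

    A = sparse.csr_matrix(graph).astype(float)
    deg = np.asarray(A.sum(axis=1)).ravel()
    inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1e-12), 0.0)
    W = sparse.diags(inv) @ A  # row-stochastic on non-isolated nodes

    p = s.copy()
    for _ in range(max_iter):
        p_new = (1 - restart_prob) * (W.T @ p) + restart_prob * s
        # isolated nodes leak walk mass; restart re-injects it at the seeds
        if abs(p_new.sum()) > 0:
            p_new = p_new / p_new.sum()
        if np.abs(p_new - p).sum() < tol:
            p = p_new
            break
        p = p_new
    lo, hi = p.min(), p.max()
    trs = (p - lo) / (hi - lo) * hi if hi > lo else np.zeros_like(p)
    return trs, is_seed


def compare_groups(trs: np.ndarray, cells: pd.DataFrame) -> pd.DataFrame:
    """Mean TRS per cell type and per category, with rank order."""
    df = cells.copy()
    df["trs"] = trs
    by_type = df.groupby("cell_type", sort=False).agg(mean_trs=("trs", "mean"), n=("trs", "size"))
    by_type["category"] = [
        df.loc[df["cell_type"] == t, "category"].iloc[0] for t in by_type.index
    ]
    by_type = by_type.sort_values("mean_trs", ascending=False).reset_index()
    by_type["rank"] = np.arange(1, len(by_type) + 1)
    return by_type


def category_means(trs: np.ndarray, cells: pd.DataFrame) -> pd.DataFrame:
    df = cells.copy()
    df["trs"] = trs
    out = df.groupby("category").agg(mean_trs=("trs", "mean"), n=("trs", "size"))
    return out.sort_values("mean_trs", ascending=False).reset_index()
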