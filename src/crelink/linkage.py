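"""Co-accessibility, peak-gene links, and the six-level gene tiering.

The gene-nomination machinery works in four stages:

1. metacell aggregation — sparse per-cell accessibility is summed over
   k-nearest-neighbor neighborhoods (limited overlap) to densify signal;
2. co-accessibility — within 500 kb sliding windows, a graphical lasso with
   a distance-increasing elementwise penalty yields regularized partial
   correlations between peaks; scores of pairs seen in several windows are
   averaged. Modules are Louvain communities of the graph thresholded at
   0.32; "directly co-accessible" pairs are edges above 0.5;
3. peak-gene links — Pearson correlation between a peak's accessibility and
   a gene's expression within +/-1 Mb of the TSS, z-scored against background
   peaks matched on GC content, mean accessibility, and peak width;
4. tier assignment — each variant-colocalizing cCRE e and nearby gene g get
   the evidence levels: (1) e's module contains a promoter cCRE of g,
   (2) e is directly co-accessible with a promoter cCRE of g, (3) e is
   itself the promoter of g, (4) e's module contains a cCRE linked to g's
   expression, (5) e is directly co-accessible with a cCRE linked to g,
   (6) e itself is linked to g's expression — level 6 the strongest.
   For levels 1/2/4/5 the partner cCRE must differ from e, so promoter or
   linked status of e itself never mechanically grants the indirect levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors

MODULE_CUTOFF = 0.32  # co-accessibility score for module membership
DIRECT_CUTOFF = 0.5  # "directly co-accessible"
LINK_DISTANCE = 1_000_000
LINK_MIN_CELLS = 10
LINK_P_CUTOFF = 0.05
LINK_SCORE_CUTOFF = 0.05


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# embeddings and metacells
# ---------------------------------------------------------------------------

def lsi_embedding(atac: np.ndarray, n_components: int = 20, seed: int = 0) -> np.ndarray:
    """TF-IDF + truncated SVD of the peak matrix; the first (depth) component
    is dropped. Returns cells x components."""
    from sklearn.decomposition import TruncatedSVD

    X = atac.astype(float)
    colsum = np.maximum(X.sum(axis=0), 1.0)
    tf_ = X / colsum[None, :]
    nnz = np.maximum((X > 0).sum(axis=1), 1)
    idf = X.shape[1] / nnz
    lsi = np.log1p(tf_ * idf[:, None] * 1e4)
    svd = TruncatedSVD(n_components=n_components + 1, random_state=seed)
    emb = svd.fit_transform(lsi.T)
    return emb[:, 1:]


def make_metacells(
    matrix: np.ndarray,
    embedding: np.ndarray,
    k: int = 20,
    seed: int = 0,
    max_overlap: float = 0.1,
) -> Tuple[np.ndarray, List[np.ndarray]]:
    """Sum features over k-NN neighborhoods with limited pairwise overlap.

    Neighborhoods include the anchor cell, so k=1 reproduces single cells.
    Candidate anchors are visited in random order and accepted only if the
    neighborhood shares at most ``max_overlap * k`` members with every
    previously accepted metacell. Returns (features x metacells, memberships).
    """
    n_cells = matrix.shape[1]
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if k >= n_cells:
        raise ConfigurationError("k must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_cells)
    accepted: List[Set[int]] = []
    memberships: List[np.ndarray] = []
    allowed = max_overlap * k
    for anchor in order:
        hood = set(idx[anchor])
        if all(len(hood & prev) <= allowed for prev in accepted):
            accepted.append(hood)
            memberships.append(idx[anchor])
    cols = [matrix[:, m].sum(axis=1) for m in memberships]
    return np.stack(cols, axis=1), memberships


# ---------------------------------------------------------------------------
# graphical lasso with an elementwise (distance) penalty
# ---------------------------------------------------------------------------

try:  # numba makes the block coordinate descent ~100x faster
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=False)
def _glasso_core(S, penalty, max_iter, tol):  # pragma: no cover - jit kernel
    p = S.shape[0]
    W = S.copy()
    for j in range(p):
        W[j, j] = S[j, j] + penalty[j, j]
    B = np.zeros((p, p))
    for _ in range(max_iter):
        max_change = 0.0
        for j in range(p):
            # lasso on column j: W[rest,rest] beta = soft(S[rest,j])
            for _cd in range(100):
                delta = 0.0
                for i in range(p):
                    if i == j:
                        continue
                    # residual r = s12_i - sum_k W[i,k] beta_k (k != j, k != i)
                    acc = 0.0
                    for kk in range(p):
                        if kk != j and kk != i:
                            acc += W[i, kk] * B[kk, j]
                    r = S[i, j] - acc
                    lam = penalty[i, j]
                    if r > lam:
                        new = (r - lam) / W[i, i]
                    elif r < -lam:
                        new = (r + lam) / W[i, i]
                    else:
                        new = 0.0
                    d = abs(new - B[i, j])
                    if d > delta:
                        delta = d
                    B[i, j] = new
                if delta < 1e-6:
                    break
            # update W column j: W[rest, j] = W[rest, rest] @ beta
            for i in range(p):
                if i == j:
                    continue
                acc = 0.0
                for kk in range(p):
                    if kk != j:
                        acc += W[i, kk] * B[kk, j]
                d = abs(acc - W[i, j])
                if d > max_change:
                    max_change = d
                W[i, j] = acc
                W[j, i] = acc
        if max_change < tol:
            break
    Theta = np.zeros((p, p))
    for j in range(p):
        acc = 0.0
        for i in range(p):
            if i != j:
                acc += W[i, j] * B[i, j]
        tjj = 1.0 / max(W[j, j] - acc, 1e-12)
        Theta[j, j] = tjj
        for i in range(p):
            if i != j:
                Theta[i, j] = -B[i, j] * tjj
    return (Theta + Theta.T) / 2.0


def _glasso_matrix_penalty(
    S: np.ndarray, penalty: np.ndarray, max_iter: int = 50, tol: float = 1e-4
) -> np.ndarray:
    """Friedman-style block coordinate descent with an elementwise penalty.

    Minimizes -logdet(Theta) + tr(S Theta) + sum_ij penalty_ij |Theta_ij|.
    Returns the precision matrix estimate.
    """
    return _glasso_core(
        np.ascontiguousarray(S, dtype=np.float64),
        np.ascontiguousarray(penalty, dtype=np.float64),
        max_iter,
        tol,
    )


def coaccessibility(
    metacell_matrix: np.ndarray,
    peaks: pd.DataFrame,
    window_bp: int = 500_000,
    step_bp: int = 250_000,
    base_penalty: float = 0.1,
    distance_scale: float = 1.0,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Distance-penalized regularized partial correlations between peaks.

    Within each sliding window, the correlation matrix of (log1p) metacell
    profiles is fed to a graphical lasso whose elementwise penalty grows with
    genomic distance: penalty(d) = base + distance_scale * (d / window)^2.
    Scores (negated scaled precision entries, i.e. partial correlations) of
    pairs appearing in several windows are averaged; pairs farther apart than
    the window span are not scored.
    """
    if log_transform:
        metacell_matrix = np.log1p(metacell_matrix.astype(float))
    mids = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    order = np.argsort(mids, kind="stable")
    names = peaks["name"].to_numpy()
    scores: Dict[Tuple[str, str], List[float]] = {}
    lo_pos, hi_pos = mids.min(), mids.max()
    starts = np.arange(lo_pos, max(hi_pos - window_bp, lo_pos) + step_bp, step_bp)
    for chrom in peaks["chrom"].unique():
        on_chrom = order[peaks["chrom"].to_numpy()[order] == chrom]
        for w0 in starts:
            inside = on_chrom[(mids[on_chrom] >= w0) & (mids[on_chrom] < w0 + window_bp)]
            if len(inside) < 2:
                continue
            X = metacell_matrix[inside].astype(float)
            sd = X.std(axis=1)
            keep = sd > 0
            inside = inside[keep]
            if len(inside) < 2:
                continue
            X = X[keep]
            C = np.corrcoef(X)
            d = np.abs(mids[inside][:, None] - mids[inside][None, :])
            penalty = base_penalty + distance_scale * (d / window_bp) ** 2
            np.fill_diagonal(penalty, base_penalty)
            try:
                Theta = _glasso_matrix_penalty(C, penalty)
            except np.linalg.LinAlgError as err:  # pragma: no cover
                raise np.linalg.LinAlgError(f"window at {w0}: {err}") from err
            dd = np.sqrt(np.diag(Theta))
            pc = -Theta / np.outer(dd, dd)
            for a in range(len(inside)):
                for b in range(a + 1, len(inside)):
                    s = float(np.clip(pc[a, b], -1.0, 1.0))
                    if s != 0.0:
                        key = tuple(sorted((names[inside[a]], names[inside[b]])))
                        scores.setdefault(key, []).append(s)
    rows = [
        {"peak_a": a, "peak_b": b, "score": float(np.mean(v))}
        for (a, b), v in sorted(scores.items())
    ]
    return pd.DataFrame(rows, columns=["peak_a", "peak_b", "score"])


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

def detect_modules(
    edges: pd.DataFrame, cutoff: float = MODULE_CUTOFF, seed: int = 0
) -> List[Set[str]]:
    """Louvain communities of the co-accessibility graph thresholded at
    ``cutoff``; singleton communities are discarded. Deterministic for a
    fixed seed; output sorted by smallest member for stable ids."""
    G = nx.Graph()
    strong = edges.loc[edges["score"] >= cutoff]
    for _, e in strong.iterrows():
        G.add_edge(e["peak_a"], e["peak_b"], weight=float(e["score"]))
    if G.number_of_nodes() == 0:
        return []
    comms = nx.community.louvain_communities(G, weight="weight", seed=seed)
    modules = [set(c) for c in comms if len(c) >= 2]
    return sorted(modules, key=lambda m: min(m))


# ---------------------------------------------------------------------------
# peak-gene links
# ---------------------------------------------------------------------------

@dataclass
class LinkParams:
    distance: int = LINK_DISTANCE
    min_cells: int = LINK_MIN_CELLS
    p_cutoff: float = LINK_P_CUTOFF
    score_cutoff: float = LINK_SCORE_CUTOFF
    n_background: int = 200
    normalize: bool = True
    seed: int = 0


def _normalize(mat: np.ndarray) -> np.ndarray:
    colsum = np.maximum(mat.sum(axis=0), 1.0)
    return np.log1p(mat / colsum[None, :] * 1e4)


def link_peaks_to_genes(
    atac: np.ndarray,
    rna: np.ndarray,
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    params: LinkParams = LinkParams(),
) -> Tuple[pd.DataFrame, List[str]]:
    """Correlate peak accessibility with gene expression in cis, z-scored
    against GC/accessibility/width-matched background peaks.

    peaks needs name/chrom/start/end/gc/width columns; genes needs
    gene/chrom/tss. Returns (links table, skip log). The table keeps pairs
    with one-sided p < p_cutoff and |r| > score_cutoff.
    """
    n_cells = atac.shape[1]
    A = _normalize(atac.astype(float)) if params.normalize else atac.astype(float)
    R = _normalize(rna.astype(float)) if params.normalize else rna.astype(float)

    def zrows(M: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        mu = M.mean(axis=1, keepdims=True)
        sd = M.std(axis=1)
        ok = sd > 0
        Z = np.zeros_like(M)
        Z[ok] = (M[ok] - mu[ok]) / sd[ok][:, None]
        return Z, ok

    Az, peak_ok = zrows(A)
    Rz, gene_ok = zrows(R)
    # a feature constant in raw counts carries no signal even if per-cell
    # normalization makes it vary with depth
    peak_ok &= atac.std(axis=1) > 0
    gene_ok &= rna.std(axis=1) > 0

    n_detected = (atac > 0).sum(axis=1)
    mids = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    feats = np.column_stack(
        [peaks["gc"].to_numpy(), atac.mean(axis=1), peaks["width"].to_numpy()]
    ).astype(float)
    feats = (feats - feats.mean(axis=0)) / np.maximum(feats.std(axis=0), 1e-12)
    n_bg = min(params.n_background, atac.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=n_bg + 1).fit(feats)
    _, bg_idx = nn.kneighbors(feats)  # first neighbor is the peak itself

    skipped: List[str] = []
    rows = []
    peak_chrom = peaks["chrom"].to_numpy()
    peak_names = peaks["name"].to_numpy()
    for gi, g in genes.iterrows():
        gix = genes.index.get_loc(gi)
        if not gene_ok[gix]:
            skipped.append(f"gene {g['gene']}: zero variance")
            continue
        cand = np.where(
            (peak_chrom == g["chrom"])
            & (np.abs(mids - int(g["tss"])) <= params.distance)
            & (n_detected >= params.min_cells)
        )[0]
        if len(cand) == 0:
            continue
        r_all = Az @ Rz[gix] / n_cells
        for pj in cand:
            if not peak_ok[pj]:
                skipped.append(f"peak {peak_names[pj]}: zero variance")
                continue
            bg = bg_idx[pj][bg_idx[pj] != pj][:n_bg]
            r_bg = r_all[bg]
            sd = r_bg.std()
            if sd == 0:
                skipped.append(f"peak {peak_names[pj]}: degenerate background")
                continue
            z = (r_all[pj] - r_bg.mean()) / sd
            p = float(stats.norm.sf(z))
            if p < params.p_cutoff and abs(r_all[pj]) > params.score_cutoff:
                rows.append(
                    {
                        "peak": peak_names[pj],
                        "gene": g["gene"],
                        "r": float(r_all[pj]),
                        "z": float(z),
                        "p": p,
                        "n_cells_detected": int(n_detected[pj]),
                    }
                )
    return pd.DataFrame(rows, columns=["peak", "gene", "r", "z", "p", "n_cells_detected"]), skipped


# ---------------------------------------------------------------------------
# six-level tier assignment
# ---------------------------------------------------------------------------

@dataclass
class TierAssignment:
    variant_id: str
    peak: str
    gene: str
    levels: Set[int]
    max_level: int


def assign_tiers(
    ccv_overlaps: pd.DataFrame,
    modules: Sequence[Set[str]],
    edges: pd.DataFrame,
    promoter_of: Dict[str, str],
    links: pd.DataFrame,
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    max_distance: int = LINK_DISTANCE,
    direct_cutoff: float = DIRECT_CUTOFF,
) -> List[TierAssignment]:
    """Evidence levels for every (CCV-colocalizing cCRE, nearby gene) pair.

    ``promoter_of`` maps promoter-annotated peaks to their gene. Genes are
    restricted to +/- max_distance of the cCRE midpoint.
    """
    known = set(peaks["name"])
    missing = set(ccv_overlaps["peak"]) - known
    if missing:
        raise KeyError(f"overlap peaks absent from the atlas: {sorted(missing)[:5]}")

    module_of: Dict[str, int] = {}
    for i, m in enumerate(modules):
        for p in m:
            module_of[p] = i
    edge_lookup: Dict[str, Dict[str, float]] = {}
    for _, e in edges.iterrows():
        edge_lookup.setdefault(e["peak_a"], {})[e["peak_b"]] = float(e["score"])
        edge_lookup.setdefault(e["peak_b"], {})[e["peak_a"]] = float(e["score"])
    links_by_gene: Dict[str, Set[str]] = {}
    for _, l in links.iterrows():
        links_by_gene.setdefault(l["gene"], set()).add(l["peak"])
    promoters_by_gene: Dict[str, Set[str]] = {}
    for p, g in promoter_of.items():
        promoters_by_gene.setdefault(g, set()).add(p)

    mids = dict(zip(peaks["name"], (peaks["start"] + peaks["end"]) // 2))
    chroms = dict(zip(peaks["name"], peaks["chrom"]))

    out: List[TierAssignment] = []
    for _, row in ccv_overlaps.drop_duplicates(["variant_id", "peak"]).iterrows():
        e = row["peak"]
        e_mid, e_chrom = mids[e], chroms[e]
        e_module = modules[module_of[e]] if e in module_of else set()
        e_edges = edge_lookup.get(e, {})
        near = genes.loc[
            (genes["chrom"] == e_chrom)
            & ((genes["tss"] - e_mid).abs() <= max_distance)
        ]
        for _, g in near.iterrows():
            gname = g["gene"]
            levels: Set[int] = set()
            g_promoters = promoters_by_gene.get(gname, set())
            g_linked = links_by_gene.get(gname, set())
            if any(m != e for m in (e_module & g_promoters)):
                levels.add(1)
            if any(e_edges.get(m, 0.0) > direct_cutoff for m in g_promoters if m != e):
                levels.add(2)
            if promoter_of.get(e) == gname:
                levels.add(3)
            if any(m != e for m in (e_module & g_linked)):
                levels.add(4)
            if any(e_edges.get(m, 0.0) > direct_cutoff for m in g_linked if m != e):
                levels.add(5)
            if e in g_linked:
                levels.add(6)
            if levels:
                out.append(
                    TierAssignment(
                        variant_id=row["variant_id"],
                        peak=e,
                        gene=gname,
                        levels=levels,
                        max_level=max(levels),
                    )
                )
    return out


def tiers_table(assignments: Sequence[TierAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant_id": a.variant_id,
                "peak": a.peak,
                "gene": a.gene,
                "levels": ",".join(str(l) for l in sorted(a.levels)),
                "max_level": a.max_level,
            }
            for a in assignments
        ],
        columns=["variant_id", "peak", "gene", "levels", "max_level"],
    )
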