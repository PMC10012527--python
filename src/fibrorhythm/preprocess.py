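"""Cell quality filters, modularity-enriched genes and cluster merging.

The clustering strategy works on an over-split ("fine") cell partition and
merges it guided by modularity-enriched genes (MEGs): genes whose expressing
cells occupy a coherent territory of the embedding graph.  The merge uses an
explicit gene-gene distance — for two genes, the average embedding distance
between each expressing cell of one gene and its k nearest expressing cells
of the other.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform

from .config import ANALYSIS_DEFAULTS
from .graphs import knn_adjacency

__all__ = [
    "filter_cells",
    "find_megs",
    "modularity_fold",
    "meg_gene_distance",
    "meg_distance_matrix",
    "merge_fine_clusters",
]

_MEG = ANALYSIS_DEFAULTS["meg"]
_FILT = ANALYSIS_DEFAULTS["cell_filter"]


# ---------------------------------------------------------------------------
# cell filters
# ---------------------------------------------------------------------------

def filter_cells(adata: ad.AnnData) -> tuple[ad.AnnData, pd.DataFrame]:
    """Two-stage cell quality filter.

    1. Cells whose total UMI exceeds ``median + 2*MAD`` of the totals are
       removed (MAD = raw median absolute deviation, unscaled).
    2. Among the remaining cells, the numbers of detected (UMI >= 1) and
       expressed (UMI >= 2) genes must both lie within the 2.5-97.5%
       quantile interval computed on those remaining cells.

    Returns the filtered matrix and a removal report (cell_id, reason).
    """
    if adata.n_obs < 4:
        raise ValueError("need at least 4 cells for quantile-based filtering")
    x = sp.csr_matrix(adata.X)
    totals = np.asarray(x.sum(axis=1)).ravel()
    med = np.median(totals)
    mad = np.median(np.abs(totals - med))
    umi_cut = med + _FILT["umi_mad_factor"] * mad
    keep_umi = totals <= umi_cut

    detected = np.asarray((x >= _FILT["detected_umi_min"]).sum(axis=1)).ravel()
    expressed = np.asarray((x >= _FILT["expressed_umi_min"]).sum(axis=1)).ravel()
    lo_q, hi_q = _FILT["gene_quantile_low"], _FILT["gene_quantile_high"]
    d_lo, d_hi = np.quantile(detected[keep_umi], [lo_q, hi_q])
    e_lo, e_hi = np.quantile(expressed[keep_umi], [lo_q, hi_q])
    keep_genes = (
        (detected >= d_lo) & (detected <= d_hi)
        & (expressed >= e_lo) & (expressed <= e_hi)
    )

    keep = keep_umi & keep_genes
    reasons = []
    for i in np.flatnonzero(~keep):
        if not keep_umi[i]:
            reasons.append((adata.obs_names[i], "umi_total_above_median_2mad"))
        else:
            reasons.append((adata.obs_names[i], "gene_count_outside_quantiles"))
    report = pd.DataFrame(reasons, columns=["cell_id", "reason"])
    return adata[keep].copy(), report


# ---------------------------------------------------------------------------
# modularity-enriched genes
# ---------------------------------------------------------------------------

def modularity_fold(a: sp.csr_matrix, members: np.ndarray) -> float:
    """Observed/expected intra-set edge weight under the modularity null.

    ``a`` is a (weighted) symmetric adjacency matrix; ``members`` indexes
    the vertex set.  The expectation is proportional to the squared degree
    fraction of the set, so a set containing every vertex has fold exactly 1.
    """
    deg = np.asarray(a.sum(axis=1)).ravel()
    two_m = deg.sum()
    sub = a[members][:, members]
    observed = sub.sum() / 2.0
    d_s = deg[members].sum()
    expected = d_s * d_s / (2.0 * two_m)
    return observed / expected if expected > 0 else np.nan


def find_megs(
    adata: ad.AnnData,
    graph_k: int = _MEG["graph_k"],
    n_background: int = _MEG["n_background"],
    seed: int = 0,
    fold_over_background: float = _MEG["fold_over_background"],
) -> pd.DataFrame:
    """Scan candidate genes for spatial enrichment on the embedding graph.

    Candidates are genes expressed (UMI >= 1) in more than 100 cells and in
    less than half of all cells.  For each, the enrichment fold is the
    observed intra-set edge weight among expressing cells divided by the
    modularity-null expectation (proportional to the squared degree
    fraction of the set).  The background fold is the median over seeded
    random cell subsets of the same size; a gene is a MEG iff its fold is
    at least ``fold_over_background`` times the background.
    """
    coords = adata.obsm["X_umap"]
    a = knn_adjacency(coords, graph_k)
    deg = np.asarray(a.sum(axis=1)).ravel()
    two_m = deg.sum()  # = 2 * total edge weight
    n = adata.n_obs

    x = sp.csc_matrix(adata.X)
    n_cells_per_gene = np.asarray((x >= 1).sum(axis=0)).ravel()
    lo = _MEG["candidate_min_cells"]
    hi = _MEG["candidate_max_cell_fraction"] * n
    cand = np.flatnonzero((n_cells_per_gene > lo) & (n_cells_per_gene < hi))
    if cand.size == 0:
        warnings.warn("MEG candidate pool is empty", stacklevel=2)
        return pd.DataFrame(columns=["gene", "n_cells", "fold",
                                     "background_fold", "is_meg"])

    rng = np.random.default_rng(seed)
    rows = []
    for gi in cand:
        members = x.indices[x.indptr[gi]: x.indptr[gi + 1]]
        members = members[x.data[x.indptr[gi]: x.indptr[gi + 1]] >= 1]
        fold = modularity_fold(a, members)
        # vectorised background: n_background random indicator columns
        size = members.size
        picks = np.argpartition(
            rng.random((n_background, n)), size - 1, axis=1)[:, :size]
        ind = np.zeros((n, n_background), dtype=np.float64)
        ind[picks.T, np.arange(n_background)[None, :]] = 1.0
        observed = 0.5 * np.einsum("ij,ij->j", ind, a @ ind)
        d_s = deg @ ind
        expected = d_s * d_s / (2.0 * two_m)
        with np.errstate(invalid="ignore", divide="ignore"):
            bg = float(np.median(observed / expected))
        rows.append({
            "gene": adata.var_names[gi],
            "n_cells": int(size),
            "fold": fold,
            "background_fold": bg,
            "is_meg": bool(fold >= fold_over_background * bg),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# MEG gene distance
# ---------------------------------------------------------------------------

def _directed_distance(ids_i: np.ndarray, ids_j: np.ndarray,
                       xi: np.ndarray, xj: np.ndarray, k: int) -> float | None:
    """Average over cells m of gene i of the mean distance to the k nearest
    expressing cells of gene j (m excluded from its own candidates).
    Returns None when no cell of i has any candidate neighbour."""
    d = cdist(xi, xj)
    same = ids_i[:, None] == ids_j[None, :]
    contrib, n_used = 0.0, 0
    order_j = np.arange(len(ids_j))
    for m in range(len(ids_i)):
        mask = ~same[m]
        cand = np.flatnonzero(mask)
        if cand.size == 0:
            continue
        k_eff = min(k, cand.size)
        # deterministic ties: sort by (distance, cell order)
        sel = cand[np.lexsort((order_j[cand], d[m, cand]))[:k_eff]]
        contrib += d[m, sel].mean()
        n_used += 1
    if n_used == 0:
        return None
    return contrib / n_used


def meg_gene_distance(
    ec_i: pd.Index | np.ndarray,
    ec_j: pd.Index | np.ndarray,
    embedding: pd.DataFrame,
    k: int = _MEG["distance_knn_k"],
) -> float:
    """Symmetric MEG gene distance on the embedding.

    ``ec_i``/``ec_j`` are the expressing-cell id sets of the two genes and
    ``embedding`` a per-cell (x, y) table.  The directed distance from i to
    j averages, over expressing cells of i, the mean embedding distance to
    the k nearest expressing cells of j (a cell is never its own
    neighbour); the symmetric distance is the mean of both directions.
    Identical singleton sets have distance 0 by convention.
    """
    ids_i = np.asarray(ec_i)
    ids_j = np.asarray(ec_j)
    if ids_i.size == 0 or ids_j.size == 0:
        raise ValueError("expressing-cell sets must be nonempty")
    xi = embedding.loc[ids_i, ["x", "y"]].to_numpy(dtype=float)
    xj = embedding.loc[ids_j, ["x", "y"]].to_numpy(dtype=float)
    dij = _directed_distance(ids_i, ids_j, xi, xj, k)
    dji = _directed_distance(ids_j, ids_i, xj, xi, k)
    parts = [p for p in (dij, dji) if p is not None]
    if not parts:
        return 0.0  # identical singleton sets
    return float(np.mean(parts))


def meg_distance_matrix(
    adata: ad.AnnData,
    meg_genes: list,
    k: int = _MEG["distance_knn_k"],
) -> pd.DataFrame:
    """Pairwise symmetric MEG distance matrix over ``meg_genes``."""
    coords = adata.obsm["X_umap"]
    embedding = pd.DataFrame(coords, index=adata.obs_names, columns=["x", "y"])
    x = sp.csc_matrix(adata.X)
    var_pos = {g: i for i, g in enumerate(adata.var_names)}
    ecs = {}
    for g in meg_genes:
        gi = var_pos[g]
        members = x.indices[x.indptr[gi]: x.indptr[gi + 1]]
        members = members[x.data[x.indptr[gi]: x.indptr[gi + 1]] >= 1]
        ecs[g] = adata.obs_names[members].to_numpy()
    n = len(meg_genes)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = meg_gene_distance(
                ecs[meg_genes[i]], ecs[meg_genes[j]], embedding, k=k)
    return pd.DataFrame(dmat, index=meg_genes, columns=meg_genes)


# ---------------------------------------------------------------------------
# cluster merging
# ---------------------------------------------------------------------------

def merge_fine_clusters(
    adata: ad.AnnData,
    fine_labels: pd.Series | np.ndarray,
    distance: pd.DataFrame,
    n_groups: int = _MEG["merge_n_groups"],
    ratio_floor: float = _MEG["merge_ratio_floor"],
    linkage_method: str = _MEG["merge_linkage"],
) -> pd.Series:
    """Merge an over-split partition into final clusters guided by MEGs.

    The MEG distance matrix is hierarchically clustered and cut into
    ``n_groups`` MEG groups.  Each fine cluster is assigned to the MEG
    group with the highest mean expressing-cell fraction of its member
    genes inside that fine cluster, provided the fraction exceeds
    ``ratio_floor``; unassigned fine clusters are merged into a single
    "no-MEG" final cluster.  Output labels are integers, MEG-bearing
    clusters first ordered by decreasing size, the no-MEG cluster last.
    """
    fine = pd.Series(np.asarray(fine_labels), index=adata.obs_names)
    if distance.shape[0] == 0:
        return pd.Series(0, index=adata.obs_names, name="cluster")
    if n_groups > distance.shape[0]:
        raise ValueError("n_groups exceeds the number of MEGs")

    z = linkage(squareform(distance.to_numpy(), checks=False),
                method=linkage_method)
    groups = fcluster(z, t=n_groups, criterion="maxclust")
    meg_groups = {g: distance.index[groups == g].tolist()
                  for g in np.unique(groups)}

    x = sp.csc_matrix(adata.X)
    var_pos = {g: i for i, g in enumerate(adata.var_names)}
    expressed = (x >= 1)

    assign: dict = {}
    for fc in fine.unique():
        cells = np.flatnonzero((fine == fc).to_numpy())
        best_group, best_frac = None, -1.0
        for g, members in meg_groups.items():
            cols = [var_pos[m] for m in members]
            frac = float(expressed[cells][:, cols].mean())
            if frac > best_frac:
                best_group, best_frac = g, frac
        assign[fc] = best_group if best_frac > ratio_floor else None

    merged = fine.map(lambda fc: assign[fc])
    # stable integer labels: groups ordered by decreasing cell count,
    # the no-MEG cluster (None) last
    sizes = merged.value_counts(dropna=True)
    order = {g: i for i, g in enumerate(sizes.index)}
    no_meg_label = len(order)
    out = merged.map(lambda g: no_meg_label if pd.isna(g) else order[g])
    out.name = "cluster"
    return out.astype(int)
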