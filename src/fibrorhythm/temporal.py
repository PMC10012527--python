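"""Pseudo-bulk binning of the embedding and reference-profile correlation.

Cells are grouped into axis-aligned square bins of the 2-D embedding
(granularity 0.5 for identity correlation, 0.2 for time mapping), their
counts summed into pseudo-bulk CPM profiles, and each bin correlated
(Spearman) with external reference samples — a developmental time course
or purified-cell references.  Each cell inherits its bin's best-matching
reference timepoint as its relative expression time.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .config import ANALYSIS_DEFAULTS

__all__ = [
    "bin_pseudobulk",
    "filter_reference_genes",
    "correlate_bins",
    "assign_time",
]

_TP = ANALYSIS_DEFAULTS["temporal"]


def bin_pseudobulk(
    adata: ad.AnnData,
    granularity: float = _TP["granularity_identity"],
) -> tuple[pd.Series, pd.DataFrame]:
    """Partition cells into square bins and sum counts to pseudo-bulk CPM.

    The grid origin is fixed at 0, bins are [i*g, (i+1)*g) x [j*g, (j+1)*g).
    Returns (bin label per cell, bin x gene CPM table); empty bins are
    omitted.
    """
    if granularity <= 0:
        raise ValueError("granularity must be positive")
    coords = np.asarray(adata.obsm["X_umap"], dtype=float)
    ij = np.floor(coords / granularity).astype(int)
    labels = pd.Series([f"{i}_{j}" for i, j in ij], index=adata.obs_names,
                       name="bin")
    x = sp.csr_matrix(adata.X).astype(float)
    groups = labels.groupby(labels).groups
    profiles = {}
    pos = {c: i for i, c in enumerate(adata.obs_names)}
    for b, cells in groups.items():
        rows = [pos[c] for c in cells]
        s = np.asarray(x[rows].sum(axis=0)).ravel()
        tot = s.sum()
        profiles[b] = s / tot * 1e6 if tot > 0 else s
    pb = pd.DataFrame(profiles, index=adata.var_names).T
    pb = pb.sort_index()
    return labels, pb


def filter_reference_genes(refs: pd.DataFrame, rule: str = "fpkm_any") -> pd.Index:
    """Reference gene-set rules.

    ``fpkm_any``  — keep genes with expression > 1 in at least one sample
    (the time-course rule); ``cpm_all`` — keep genes with mean > 1 across
    samples in every sample (the purified-fiber rule).
    """
    if rule == "fpkm_any":
        keep = (refs > 1).any(axis=1)
    elif rule == "cpm_all":
        keep = (refs > 1).all(axis=1)
    else:
        raise ValueError(f"unknown reference gene rule {rule!r}")
    return refs.index[keep]


def correlate_bins(
    pseudobulk: pd.DataFrame,
    refs: pd.DataFrame,
    gene_rule: str = "fpkm_any",
) -> pd.DataFrame:
    """Spearman correlation of each bin profile with each reference sample.

    Computed over the reference gene set (after ``gene_rule``) intersected
    with the pseudo-bulk genes.  Bins whose profile has zero variance on
    that gene set get NaN (flagged unassigned).
    """
    genes = filter_reference_genes(refs, gene_rule).intersection(pseudobulk.columns)
    if len(genes) < 3:
        raise ValueError("fewer than 3 shared genes after the reference rule")
    a = pseudobulk[genes].to_numpy(dtype=float)        # bins x genes
    b = refs.loc[genes].to_numpy(dtype=float).T        # samples x genes
    ra = scipy.stats.rankdata(a, axis=1)
    rb = scipy.stats.rankdata(b, axis=1)
    ra_c = ra - ra.mean(axis=1, keepdims=True)
    rb_c = rb - rb.mean(axis=1, keepdims=True)
    na = np.sqrt((ra_c ** 2).sum(axis=1))
    nb = np.sqrt((rb_c ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ra_c @ rb_c.T) / np.outer(na, nb)
    rho[na == 0, :] = np.nan
    return pd.DataFrame(rho, index=pseudobulk.index, columns=refs.columns)


def assign_time(
    correlations: pd.DataFrame,
    sample_times: pd.Series,
    cell_bins: pd.Series,
) -> pd.Series:
    """Assign each cell the timepoint its bin correlates best with.

    Reference replicate columns sharing a timepoint are averaged first;
    each bin takes the argmax timepoint (ties resolved to the earliest);
    bins flagged unassigned (NaN correlations) propagate a missing label.
    """
    times = pd.Series(sample_times)
    by_time = correlations.T.groupby(times.loc[correlations.columns]).mean().T
    order = np.array(sorted(by_time.columns))
    by_time = by_time[order]
    vals = by_time.to_numpy(dtype=float)
    best = np.full(len(by_time), np.nan)
    ok = ~np.isnan(vals).all(axis=1)
    # argmax with earliest-timepoint tie break (columns already time-sorted)
    best[ok] = order[np.nanargmax(vals[ok], axis=1)]
    bin_time = pd.Series(best, index=by_time.index)
    return cell_bins.map(bin_time).rename("estimated_time")
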