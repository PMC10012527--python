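"""Marker-gene selection and condition-wise differential expression.

Candidate markers come from a one-vs-rest rank-sum scan per cluster run
separately on the WT-like, mutant-like and merged datasets (a candidate
must pass FDR < 1e-9 and fold change > 2 in every dataset that contains
the cluster).  Transcription factors are accepted as markers directly;
other genes must additionally satisfy three expression-ratio conditions
that enforce cluster specificity.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .config import ANALYSIS_DEFAULTS

__all__ = [
    "cpm_matrix",
    "rank_sum_test",
    "expression_ratios",
    "candidate_markers",
    "select_markers",
    "condition_degs",
]

_MK = ANALYSIS_DEFAULTS["markers"]
_DATASETS = ("wt", "fl", "merged")


def cpm_matrix(adata: ad.AnnData) -> np.ndarray:
    """Dense counts-per-million matrix (cells x genes)."""
    x = sp.csr_matrix(adata.X).astype(float)
    totals = np.asarray(x.sum(axis=1)).ravel()
    totals[totals == 0] = 1.0
    return np.asarray(x.multiply(1e6 / totals[:, None]).todense())


def _tie_terms(x: np.ndarray) -> np.ndarray:
    """Per-column sum of t^3 - t over tied groups (for rank-test variance)."""
    n, g = x.shape
    xs = np.sort(x, axis=0)
    new = np.ones((n, g), dtype=bool)
    new[1:] = xs[1:] != xs[:-1]
    run_id = np.cumsum(new, axis=0)  # 1..n per column
    ids = (np.arange(g)[None, :] * (n + 1) + run_id).ravel()
    t = np.bincount(ids, minlength=g * (n + 1)).astype(np.int64)
    t = t.reshape(g, n + 1)
    return (t ** 3 - t).sum(axis=1).astype(float)


def rank_sum_test(x: np.ndarray, group1: np.ndarray,
                  ranks: np.ndarray | None = None,
                  tie_term: np.ndarray | None = None) -> np.ndarray:
    """Two-sided Mann-Whitney rank-sum p-values, vectorised over columns.

    Normal approximation with tie correction and continuity correction
    (the standard large-sample form).  ``ranks``/``tie_term`` may be
    precomputed once per matrix and reused across group masks.
    """
    n, g = x.shape
    group1 = np.asarray(group1, dtype=bool)
    n1 = int(group1.sum())
    n2 = n - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    if ranks is None:
        ranks = scipy.stats.rankdata(x, axis=0)
    if tie_term is None:
        tie_term = _tie_terms(x)
    r1 = group1 @ ranks
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    var_u = np.maximum(var_u, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (u1 - mean_u - np.sign(u1 - mean_u) * 0.5) / np.sqrt(var_u)
    p = 2.0 * scipy.stats.norm.sf(np.abs(z))
    p = np.where(var_u == 0, 1.0, p)
    return np.minimum(p, 1.0)


# ---------------------------------------------------------------------------
# expression ratios
# ---------------------------------------------------------------------------

def _dataset_mask(adata: ad.AnnData, dataset: str) -> np.ndarray:
    if dataset == "merged":
        return np.ones(adata.n_obs, dtype=bool)
    return (adata.obs["condition"] == dataset).to_numpy()


def expression_ratios(adata: ad.AnnData, partition: pd.Series) -> pd.DataFrame:
    """Fraction of cluster cells with UMI >= 1, per gene x (dataset, cluster).

    Clusters absent from a dataset are NaN (explicitly missing, never 0).
    """
    labels = pd.Series(np.asarray(partition), index=adata.obs_names)
    clusters = sorted(labels.unique())
    x = sp.csr_matrix(adata.X)
    expressed = (x >= 1).astype(np.float64)
    cols = {}
    any_cells = False
    for ds in _DATASETS:
        ds_mask = _dataset_mask(adata, ds)
        for c in clusters:
            mask = ds_mask & (labels == c).to_numpy()
            if mask.sum() == 0:
                cols[(ds, c)] = np.full(adata.n_vars, np.nan)
            else:
                any_cells = True
                cols[(ds, c)] = np.asarray(
                    expressed[mask].mean(axis=0)).ravel()
    out = pd.DataFrame(cols, index=adata.var_names)
    out.columns = pd.MultiIndex.from_tuples(out.columns,
                                            names=["dataset", "cluster"])
    if not any_cells:
        raise ValueError("every cluster is empty in every dataset")
    return out


# ---------------------------------------------------------------------------
# candidate scan
# ---------------------------------------------------------------------------

def candidate_markers(
    adata: ad.AnnData,
    partition: pd.Series,
    fdr_cut: float = _MK["candidate_fdr"],
    fc_cut: float = _MK["candidate_fold_change"],
    min_cells: int = 3,
) -> pd.DataFrame:
    """One-vs-rest rank-sum marker scan per cluster and dataset.

    Returns a long table (gene, cluster, fdr_<ds>, fc_<ds>, candidate);
    a gene is a candidate for a cluster iff FDR < ``fdr_cut`` and fold
    change > ``fc_cut`` in every dataset that contains the cluster.
    """
    labels = pd.Series(np.asarray(partition), index=adata.obs_names)
    clusters = sorted(labels.unique())
    cpm = cpm_matrix(adata)
    results: dict = {}
    present: dict = {}
    for ds in _DATASETS:
        ds_mask = _dataset_mask(adata, ds)
        if ds_mask.sum() == 0:
            continue
        x = cpm[ds_mask]
        ds_labels = labels[ds_mask].to_numpy()
        if len(np.unique(ds_labels)) < 2:
            continue
        ranks = scipy.stats.rankdata(x, axis=0)
        ties = _tie_terms(x)
        for c in clusters:
            in_c = ds_labels == c
            n_c = int(in_c.sum())
            present[(ds, c)] = n_c > 0
            if n_c == 0:
                continue
            if n_c < min_cells:
                warnings.warn(
                    f"cluster {c} has {n_c} cells in dataset {ds}; skipped",
                    stacklevel=2)
                present[(ds, c)] = False
                continue
            p = rank_sum_test(x, in_c, ranks=ranks, tie_term=ties)
            fdr = multipletests(p, method="fdr_bh")[1]
            fc = (x[in_c].mean(axis=0) + 1.0) / (x[~in_c].mean(axis=0) + 1.0)
            results[(ds, c)] = (fdr, fc)

    rows = []
    for c in clusters:
        datasets_c = [ds for ds in _DATASETS if results.get((ds, c))]
        if not datasets_c:
            continue
        ok = np.ones(adata.n_vars, dtype=bool)
        rec: dict = {}
        for ds in _DATASETS:
            if (ds, c) in results:
                fdr, fc = results[(ds, c)]
                rec[f"fdr_{ds}"], rec[f"fc_{ds}"] = fdr, fc
                ok &= (fdr < fdr_cut) & (fc > fc_cut)
            else:
                rec[f"fdr_{ds}"] = np.full(adata.n_vars, np.nan)
                rec[f"fc_{ds}"] = np.full(adata.n_vars, np.nan)
        df = pd.DataFrame(rec, index=adata.var_names)
        df.insert(0, "cluster", c)
        df.insert(0, "gene", adata.var_names)
        df["candidate"] = ok
        rows.append(df[df["candidate"]])
    if not rows:
        return pd.DataFrame(columns=["gene", "cluster", "candidate"])
    return pd.concat(rows, ignore_index=True)


def select_markers(
    candidates: pd.DataFrame,
    ratios: pd.DataFrame,
    tf_list: set | list,
    min_own: float = _MK["ratio_min_own"],
    own_over_other: float = _MK["ratio_own_over_other"],
    max_other: float = _MK["ratio_max_other"],
) -> pd.DataFrame:
    """Apply the three-condition non-TF marker filter.

    TFs (ids in ``tf_list``) keep all their candidates.  Non-TFs must
    satisfy (1) minimum own-cluster expression ratio across datasets
    > ``min_own``; (2) that minimum > ``own_over_other`` times the maximum
    other-cluster ratio; (3) maximum other-cluster ratio < ``max_other``.
    Datasets missing the cluster are excluded from the min/max.
    """
    tf_set = set(tf_list)
    out = candidates.copy()
    cond1, cond2, cond3, is_tf, selected = [], [], [], [], []
    clusters = ratios.columns.get_level_values("cluster").unique()
    for row in candidates.itertuples(index=False):
        own = ratios.loc[row.gene, (slice(None), row.cluster)]
        r_min = np.nanmin(own.to_numpy(dtype=float))
        other_cols = [col for col in ratios.columns if col[1] != row.cluster]
        other = ratios.loc[row.gene, other_cols].to_numpy(dtype=float)
        r_max_other = np.nanmax(other) if np.any(~np.isnan(other)) else 0.0
        c1 = bool(r_min > min_own)
        c2 = bool(r_min > own_over_other * r_max_other)
        c3 = bool(r_max_other < max_other)
        tf = row.gene in tf_set
        cond1.append(c1)
        cond2.append(c2)
        cond3.append(c3)
        is_tf.append(tf)
        selected.append(tf or (c1 and c2 and c3))
    out["is_tf"] = is_tf
    out["pass_min_own"] = cond1
    out["pass_own_over_other"] = cond2
    out["pass_max_other"] = cond3
    out["selected"] = selected
    return out


# ---------------------------------------------------------------------------
# condition-wise differential expression
# ---------------------------------------------------------------------------

def condition_degs(
    adata: ad.AnnData,
    partition: pd.Series,
    fdr_cut: float = _MK["deg_fdr"],
    fc_cut: float = _MK["deg_fold_change"],
    min_cells: int = 3,
) -> pd.DataFrame:
    """Per-cluster WT-vs-mutant differential expression (rank-sum test).

    A gene is a DEG in a cluster iff BH-FDR < ``fdr_cut`` and fold change
    (either direction) > ``fc_cut``.  Clusters absent from one condition
    are skipped and reported with a note.
    """
    labels = pd.Series(np.asarray(partition), index=adata.obs_names)
    cpm = cpm_matrix(adata)
    condition = adata.obs["condition"].to_numpy()
    rows = []
    for c in sorted(labels.unique()):
        in_c = (labels == c).to_numpy()
        wt = in_c & (condition == "wt")
        fl = in_c & (condition == "fl")
        if wt.sum() < min_cells or fl.sum() < min_cells:
            warnings.warn(f"cluster {c} lacks cells in one condition; skipped",
                          stacklevel=2)
            continue
        sub = cpm[in_c]
        p = rank_sum_test(sub, wt[in_c])
        fdr = multipletests(p, method="fdr_bh")[1]
        fc = (sub[wt[in_c]].mean(axis=0) + 1.0) / (sub[fl[in_c]].mean(axis=0) + 1.0)
        fc_sym = np.maximum(fc, 1.0 / fc)
        is_deg = (fdr < fdr_cut) & (fc_sym > fc_cut)
        rows.append(pd.DataFrame({
            "gene": adata.var_names,
            "cluster": c,
            "fdr": fdr,
            "fold_change": fc,
            "direction": np.where(fc >= 1.0, "up_in_wt", "up_in_fl"),
            "is_deg": is_deg,
        }))
    if not rows:
        return pd.DataFrame(columns=["gene", "cluster", "fdr", "fold_change",
                                     "direction", "is_deg"])
    return pd.concat(rows, ignore_index=True)
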