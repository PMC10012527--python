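"""Cell-specific k-mer motif discovery in accessible chromatin.

The pipeline scans every gene-associated ACR sequence in the gene's 5'->3'
frame for all k-mers (k = 8): a literal occurrence is "forward", an
occurrence of the reverse complement is "reverse".  Each occurrence records
the signed gene-frame distance of its midpoint to the TSS (negative =
upstream).  Per cell, two statistics summarise each motif — the number of
expressed target genes (UMI >= 1) and their total UMI — and motifs whose
Moran's I spatial autocorrelation on the embedding is in the top 5% for
both statistics are called cell-specific.  Cell-specific motifs are split
into two groups by Ward.D2 clustering of their per-cluster target
expression, and per-cluster enrichment of target genes is assessed with a
one-sided Fisher exact test plus random-control draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from scipy.cluster.hierarchy import fcluster, linkage

from .chromatin import associate_acrs
from .config import ANALYSIS_DEFAULTS
from .graphs import knn_adjacency

__all__ = [
    "kmer_code",
    "kmer_string",
    "MotifGeneMatrix",
    "build_motif_gene_matrix",
    "per_cell_motif_stats",
    "morans_i",
    "motif_moran_table",
    "select_cell_specific_motifs",
    "cluster_motifs",
    "cluster_enrichment",
]

_MO = ANALYSIS_DEFAULTS["motifs"]
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


def kmer_code(kmer: str) -> int:
    """Integer code of a k-mer (A=0, C=1, G=2, T=3, big-endian)."""
    code = 0
    for b in kmer:
        code = code * 4 + _BASE_INDEX[b]
    return code


def kmer_string(code: int, k: int = 8) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def revcomp_code(code: int, k: int = 8) -> int:
    out = 0
    for _ in range(k):
        out = out * 4 + (3 - code % 4)
        code //= 4
    return out


def _revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorised reverse-complement of k-mer codes."""
    c = codes.copy()
    out = np.zeros_like(c)
    for _ in range(k):
        out = out * 4 + (3 - c % 4)
        c //= 4
    return out


@dataclass
class MotifGeneMatrix:
    """0/1 motif-gene incidence plus per-occurrence records.

    ``occurrences`` has columns motif_code, gene_id, acr_id, distance
    (signed gene-frame midpoint-to-TSS), orientation (forward/reverse).
    ``incidence`` is a (4**k x n_genes) sparse matrix over ``genes``.
    """

    k: int
    genes: pd.Index
    occurrences: pd.DataFrame
    incidence: sp.csr_matrix

    def motif_row(self, kmer: str) -> np.ndarray:
        return np.asarray(self.incidence[kmer_code(kmer)].todense()).ravel()

    def targets(self, kmer: str) -> pd.Index:
        return self.genes[self.motif_row(kmer) > 0]

    def occurrences_of(self, kmer: str) -> pd.DataFrame:
        return self.occurrences[self.occurrences["motif_code"] == kmer_code(kmer)]

    @property
    def present_codes(self) -> np.ndarray:
        return np.unique(self.occurrences["motif_code"].to_numpy())


def _encode_seq(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int64)
    for b, v in _BASE_INDEX.items():
        out[arr == ord(b)] = v
    return out


def _window_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """Codes of all k-windows; windows containing non-ACGT get -1."""
    if enc.size < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(enc, k)
    powers = 4 ** np.arange(k - 1, -1, -1)
    codes = win @ powers
    codes[(win < 0).any(axis=1)] = -1
    return codes


def build_motif_gene_matrix(
    sequences: dict,
    acrs: pd.DataFrame,
    ann: pd.DataFrame,
    k: int = _MO["k"],
    chrom_sizes: dict | None = None,
) -> MotifGeneMatrix:
    """Scan gene-associated ACRs for all k-mers in the gene frame.

    ``sequences`` maps chromosome -> string; ``acrs`` has chrom/start/end/
    name; ``ann`` has gene_id/chrom/start/end/strand (0-based half-open).
    Occurrence midpoint is window start + k//2 in gene-frame coordinates;
    an ACR outside its chromosome is an error.
    """
    for row in acrs.itertuples(index=False):
        if row.chrom not in sequences:
            raise ValueError(f"ACR chromosome {row.chrom} not in genome")
        if row.start < 0 or row.end > len(sequences[row.chrom]):
            raise ValueError(f"ACR {row.name} outside chromosome bounds")
    if chrom_sizes is None:
        chrom_sizes = {c: len(s) for c, s in sequences.items()}
    assoc = associate_acrs(acrs, ann, chrom_sizes)
    gene_info = ann.set_index("gene_id")
    acr_info = acrs.set_index("name")
    half = k // 2
    enc_cache: dict = {}

    occ_motif, occ_gene, occ_acr, occ_dist, occ_orient = [], [], [], [], []
    for pair in assoc.itertuples(index=False):
        acr = acr_info.loc[pair.acr_id]
        g = gene_info.loc[pair.gene_id]
        key = (acr["chrom"], int(acr["start"]), int(acr["end"]))
        if key not in enc_cache:
            enc_cache[key] = _encode_seq(
                sequences[acr["chrom"]][int(acr["start"]): int(acr["end"])])
        enc = enc_cache[key]
        tss = int(g["start"]) if g["strand"] == "+" else int(g["end"]) - 1
        if g["strand"] == "+":
            frame = enc
            # genomic position of frame index i is acr.start + i
            mid = np.arange(frame.size - k + 1) + int(acr["start"]) + half
            dist = mid - tss
        else:
            frame = (3 - enc[::-1]) % 4
            frame[enc[::-1] < 0] = -1
            # frame index i corresponds to genomic acr.end - 1 - i
            mid_genomic = int(acr["end"]) - 1 - (np.arange(frame.size - k + 1) + half)
            dist = tss - mid_genomic
        codes = _window_codes(frame, k)
        valid = codes >= 0
        codes, dist = codes[valid], dist[valid]
        rc = _revcomp_codes(codes, k)
        n = codes.size
        occ_motif.append(codes)
        occ_motif.append(rc)
        occ_gene.extend([pair.gene_id] * (2 * n))
        occ_acr.extend([pair.acr_id] * (2 * n))
        occ_dist.append(dist)
        occ_dist.append(dist)
        occ_orient.extend(["forward"] * n)
        occ_orient.extend(["reverse"] * n)

    occurrences = pd.DataFrame({
        "motif_code": np.concatenate(occ_motif) if occ_motif else np.empty(0, int),
        "gene_id": occ_gene,
        "acr_id": occ_acr,
        "distance": np.concatenate(occ_dist) if occ_dist else np.empty(0, int),
        "orientation": occ_orient,
    })
    genes = pd.Index(ann["gene_id"].to_numpy(), name="gene_id")
    gene_pos = {gid: i for i, gid in enumerate(genes)}
    rows = occurrences["motif_code"].to_numpy()
    cols = occurrences["gene_id"].map(gene_pos).to_numpy()
    data = np.ones(rows.size)
    incidence = sp.csr_matrix((data, (rows, cols)), shape=(4 ** k, len(genes)))
    incidence.data[:] = 1.0
    return MotifGeneMatrix(k=k, genes=genes, occurrences=occurrences,
                           incidence=incidence)


# ---------------------------------------------------------------------------
# per-cell statistics and Moran's I
# ---------------------------------------------------------------------------

def per_cell_motif_stats(
    mgm: MotifGeneMatrix,
    adata: ad.AnnData,
    motifs: list | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per cell: number of expressed target genes (UMI >= 1) and their
    total UMI, for the given motifs (default: all motifs with targets).
    Returns two (motif x cell) tables indexed by k-mer string."""
    codes = (np.array([kmer_code(m) for m in motifs], dtype=np.int64)
             if motifs is not None else mgm.present_codes)
    shared = mgm.genes.intersection(adata.var_names)
    sub = adata[:, shared]
    x = sp.csc_matrix(sub.X)
    gcols = [mgm.genes.get_loc(g) for g in shared]
    inc = mgm.incidence[codes][:, gcols]                   # motifs x genes
    expressed = (x >= 1).toarray().astype(np.float64).T    # genes x cells
    umis_gc = x.toarray().astype(np.float64).T
    counts = inc @ expressed
    umis = inc @ umis_gc
    names = [kmer_string(int(c), mgm.k) for c in codes]
    return (pd.DataFrame(counts, index=names, columns=sub.obs_names),
            pd.DataFrame(umis, index=names, columns=sub.obs_names))


def _row_normalized_knn(coords: np.ndarray, k: int) -> sp.csr_matrix:
    a = knn_adjacency(coords, k)
    rowsum = np.asarray(a.sum(axis=1)).ravel()
    rowsum[rowsum == 0] = 1.0
    return sp.diags(1.0 / rowsum) @ a


def morans_i(values: np.ndarray, coords: np.ndarray,
             graph_k: int = _MO["moran_graph_k"],
             weights: sp.spmatrix | None = None) -> tuple[float, str]:
    """Moran's I of ``values`` over a row-normalised binary kNN graph.

    I = (n/W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2.
    Zero-variance input returns (0.0, "undefined")."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Moran's I needs at least 3 observations")
    w = weights if weights is not None else _row_normalized_knn(coords, graph_k)
    z = x - x.mean()
    den = float(z @ z)
    if den == 0.0:
        return 0.0, "undefined"
    w_sum = w.sum()
    num = float(z @ (w @ z))
    return float(x.size / w_sum * num / den), "ok"


def motif_moran_table(
    mgm: MotifGeneMatrix,
    adata: ad.AnnData,
    graph_k: int = _MO["moran_graph_k"],
    chunk: int = 4096,
) -> pd.DataFrame:
    """Moran's I of both per-cell statistics for every motif with targets.

    Streams over motif chunks so the full (motif x cell) tables are never
    materialised.  Returns a table indexed by k-mer string with columns
    moran_count, moran_umi, status, n_targets."""
    coords = np.asarray(adata.obsm["X_umap"], dtype=float)
    w = _row_normalized_knn(coords, graph_k)
    w_sum = w.sum()
    n = adata.n_obs

    shared = mgm.genes.intersection(adata.var_names)
    sub = adata[:, shared]
    x = sp.csc_matrix(sub.X).astype(np.float64)
    expressed = (x >= 1).toarray().astype(np.float64).T   # genes x cells, dense
    umi_t = x.toarray().T
    gcols = [mgm.genes.get_loc(g) for g in shared]
    codes = mgm.present_codes
    inc_all = mgm.incidence[:, gcols]
    n_targets_all = np.asarray(mgm.incidence.sum(axis=1)).ravel()

    rows_i: list = []
    for start in range(0, codes.size, chunk):
        cc = codes[start: start + chunk]
        inc = inc_all[cc]
        for stats_mat, label in ((expressed, "count"), (umi_t, "umi")):
            vals = inc @ stats_mat                        # motifs x cells, dense
            z = vals - vals.mean(axis=1, keepdims=True)
            den = np.einsum("ij,ij->i", z, z)
            num = np.einsum("ij,ij->i", z, (w @ z.T).T)
            with np.errstate(invalid="ignore", divide="ignore"):
                i_val = n / w_sum * num / den
            if label == "count":
                block = pd.DataFrame({
                    "motif_code": cc,
                    "moran_count": np.where(den == 0, 0.0, i_val),
                    "defined": den > 0,
                })
            else:
                block["moran_umi"] = np.where(den == 0, 0.0, i_val)
                block["defined"] &= den > 0
        rows_i.append(block)
    table = pd.concat(rows_i, ignore_index=True)
    table["status"] = np.where(table["defined"], "ok", "undefined")
    table["n_targets"] = n_targets_all[table["motif_code"].to_numpy()].astype(int)
    table.index = pd.Index(
        [kmer_string(int(c), mgm.k) for c in table["motif_code"]], name="motif")
    return table.drop(columns=["defined"])


def select_cell_specific_motifs(
    moran: pd.DataFrame,
    top_fraction: float = _MO["top_fraction"],
) -> pd.Index:
    """Motifs whose Moran's I is at or above the (1 - top_fraction)
    quantile for BOTH per-cell statistics; undefined motifs excluded."""
    ok = moran[moran["status"] == "ok"]
    if not len(ok):
        return pd.Index([], name="motif")
    q = 1.0 - top_fraction
    cut_count = np.quantile(ok["moran_count"], q)
    cut_umi = np.quantile(ok["moran_umi"], q)
    sel = ok[(ok["moran_count"] >= cut_count) & (ok["moran_umi"] >= cut_umi)]
    return sel.index


# ---------------------------------------------------------------------------
# motif grouping and cluster enrichment
# ---------------------------------------------------------------------------

def cluster_motifs(
    selected: list,
    mgm: MotifGeneMatrix,
    adata: ad.AnnData,
    partition: pd.Series,
    fiber_cluster,
) -> pd.DataFrame:
    """Split selected motifs into M1/M2 by Ward.D2 on per-cluster target
    expression.

    The feature vector of a motif is, per cell cluster, the summed mean
    CPM of its target genes.  The 2-cut group whose target genes are
    depleted of ``fiber_cluster``-maximal genes is M1 (inhibitory-like),
    the other M2 (activating-like)."""
    if len(selected) < 2:
        raise ValueError("need at least 2 selected motifs")
    from .markers import cpm_matrix
    labels = pd.Series(np.asarray(partition), index=adata.obs_names)
    clusters = sorted(labels.unique())
    cpm = cpm_matrix(adata)
    gene_cluster_mean = np.column_stack([
        cpm[(labels == c).to_numpy()].mean(axis=0) for c in clusters])
    gdf = pd.DataFrame(gene_cluster_mean, index=adata.var_names, columns=clusters)
    shared = mgm.genes.intersection(adata.var_names)
    gmat = gdf.loc[shared].to_numpy()
    max_cluster = pd.Series(
        [clusters[i] for i in np.argmax(gmat, axis=1)], index=shared)

    feats = []
    for m in selected:
        t = mgm.targets(m).intersection(shared)
        feats.append(gdf.loc[t].sum(axis=0).to_numpy() if len(t)
                     else np.zeros(len(clusters)))
    feats = np.log1p(np.asarray(feats))
    z = linkage(feats, method="ward")  # Ward.D2 on Euclidean distances
    cut = fcluster(z, t=2, criterion="maxclust")

    frac_fiber = {}
    for g in (1, 2):
        members = [m for m, c in zip(selected, cut) if c == g]
        target_union = pd.Index([])
        for m in members:
            target_union = target_union.union(mgm.targets(m).intersection(shared))
        frac_fiber[g] = (float((max_cluster.loc[target_union] == fiber_cluster).mean())
                         if len(target_union) else 0.0)
    # group depleted of fiber-maximal targets = M1
    m1_group = min(frac_fiber, key=lambda g: frac_fiber[g])
    names = {m1_group: "M1", 3 - m1_group: "M2"}
    return pd.DataFrame({"motif": list(selected),
                         "group": [names[c] for c in cut]}).set_index("motif")


def cluster_enrichment(
    target_genes,
    gene_max_cluster: pd.Series,
    expressed_genes,
    n_random: int = _MO["n_random_controls"],
    seed: int = 0,
    obs_exp_high: float = _MO["obs_exp_high"],
    obs_exp_low: float = _MO["obs_exp_low"],
    p_cut: float = _MO["enrichment_p"],
) -> pd.DataFrame:
    """Per-cluster Obs/Exp enrichment of a motif's targets.

    ``gene_max_cluster`` maps every expressed gene to the cluster where it
    is maximally expressed; ``expressed_genes`` is the expressed universe
    (CPM > 1 in any cluster).  For each cluster a 2x2 one-sided Fisher
    exact test (in the observed direction, equal to the hypergeometric
    tail) compares targets vs non-targets against maximal-in-cluster vs
    not; Obs/Exp = (targets_in_cluster/targets) / (expressed_in_cluster/
    expressed).  Random controls redraw ``len(targets)`` genes from the
    expressed universe ``n_random`` times."""
    expressed = pd.Index(expressed_genes)
    if len(expressed) == 0:
        raise ValueError("expressed gene set is empty")
    targets = pd.Index(target_genes).intersection(expressed)
    maxc = gene_max_cluster.loc[expressed]
    clusters = sorted(maxc.unique())
    n_expr = len(expressed)
    n_t = len(targets)
    rng = np.random.default_rng(seed)

    cluster_sizes = np.array([(maxc == c).sum() for c in clusters])
    # random controls: counts per cluster of same-size draws
    draws = rng.multivariate_hypergeometric(cluster_sizes, n_t, size=n_random) \
        if n_t > 0 else np.zeros((n_random, len(clusters)), dtype=int)

    rows = []
    for ci, c in enumerate(clusters):
        in_c = int(cluster_sizes[ci])
        t_in_c = int((maxc.loc[targets] == c).sum()) if n_t else 0
        exp_frac = in_c / n_expr
        obs_frac = t_in_c / n_t if n_t else np.nan
        obs_exp = obs_frac / exp_frac if exp_frac > 0 and n_t else np.nan
        if n_t and exp_frac > 0:
            if obs_exp >= 1.0:
                p = float(scipy.stats.hypergeom.sf(t_in_c - 1, n_expr, in_c, n_t))
            else:
                p = float(scipy.stats.hypergeom.cdf(t_in_c, n_expr, in_c, n_t))
        else:
            p = np.nan
        ctrl = draws[:, ci] / n_t * n_expr / in_c if (n_t and in_c) else np.zeros(n_random)
        call = "none"
        if np.isfinite(obs_exp) and p < p_cut:
            if obs_exp > obs_exp_high:
                call = "enriched"
            elif obs_exp < obs_exp_low:
                call = "depleted"
        rows.append({
            "cluster": c,
            "n_targets": n_t,
            "n_targets_in_cluster": t_in_c,
            "n_expressed": n_expr,
            "n_expressed_in_cluster": in_c,
            "obs_exp": obs_exp,
            "fisher_p": p,
            "control_mean_obs_exp": float(np.mean(ctrl)),
            "control_sd_obs_exp": float(np.std(ctrl, ddof=1)) if n_random > 1 else 0.0,
            "call": call,
        })
    return pd.DataFrame(rows).set_index("cluster")
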