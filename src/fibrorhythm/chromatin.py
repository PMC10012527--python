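"""Active chromatin regions: merging, gene-level signal and differential calls.

Peak sets from the two conditions are unioned into ACRs (overlapping or
book-ended intervals merge).  Gene-level ATAC signal sums the counts of
ACRs overlapping the gene body or the strand-aware 1-kb promoter upstream
of the TSS.  Differential regions/genes are called between conditions on
depth-normalised counts (fold change >= 2, p < 0.01).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ANALYSIS_DEFAULTS

__all__ = [
    "merge_acrs",
    "promoter_interval",
    "gene_atac_signal",
    "call_dars_dags",
]

_CH = ANALYSIS_DEFAULTS["chromatin"]


def merge_acrs(*peak_sets: pd.DataFrame) -> pd.DataFrame:
    """Union of interval sets (columns chrom, start, end; 0-based half-open).

    Overlapping or book-ended intervals are merged; output is sorted by
    (chrom, start) and named acr_00001...
    """
    frames = [df[["chrom", "start", "end"]] for df in peak_sets if len(df)]
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "name"])
    peaks = pd.concat(frames, ignore_index=True)
    if (peaks["start"] >= peaks["end"]).any():
        bad = peaks[peaks["start"] >= peaks["end"]]
        raise ValueError(f"invalid intervals (start >= end):\n{bad}")
    peaks = peaks.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    rows = []
    for chrom, grp in peaks.groupby("chrom", sort=True):
        cur_s, cur_e = None, None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    out["name"] = [f"acr_{i + 1:05d}" for i in range(len(out))]
    return out


def promoter_interval(start: int, end: int, strand: str,
                      chrom_size: int | None = None,
                      promoter_bp: int = _CH["promoter_bp"]) -> tuple[int, int]:
    """Strand-aware promoter window upstream of the TSS (0-based half-open).

    For + genes this is [start - promoter_bp, start); for - genes
    [end, end + promoter_bp); clipped at chromosome bounds.
    """
    if strand == "+":
        p0, p1 = start - promoter_bp, start
    else:
        p0, p1 = end, end + promoter_bp
    p0 = max(p0, 0)
    if chrom_size is not None:
        p1 = min(p1, chrom_size)
    return p0, p1


def _overlaps(s1: int, e1: int, s2: int, e2: int) -> bool:
    return s1 < e2 and s2 < e1  # >= 1 bp shared


def gene_regions(ann: pd.DataFrame, chrom_sizes: dict | None = None) -> pd.DataFrame:
    """Per gene, the gene-body and promoter intervals used for association."""
    rows = []
    for g in ann.itertuples(index=False):
        size = chrom_sizes.get(g.chrom) if chrom_sizes else None
        p0, p1 = promoter_interval(g.start, g.end, g.strand, size)
        rows.append({"gene_id": g.gene_id, "chrom": g.chrom,
                     "body_start": g.start, "body_end": g.end,
                     "prom_start": p0, "prom_end": p1, "strand": g.strand})
    return pd.DataFrame(rows)


def associate_acrs(acrs: pd.DataFrame, ann: pd.DataFrame,
                   chrom_sizes: dict | None = None,
                   strict_chroms: bool = False) -> pd.DataFrame:
    """Map each ACR to every gene whose body or 1-kb promoter it overlaps.

    Many-to-many; returns (acr index label, acr name, gene_id).  With
    ``strict_chroms`` an ACR on a chromosome absent from the annotation is
    an error.
    """
    regions = gene_regions(ann, chrom_sizes)
    known = set(regions["chrom"])
    missing = sorted(set(acrs["chrom"]) - known)
    if strict_chroms and missing:
        raise ValueError(f"ACR chromosomes missing from annotation: {missing}")
    pairs = []
    for chrom, genes_c in regions.groupby("chrom"):
        acrs_c = acrs[acrs["chrom"] == chrom]
        if not len(acrs_c):
            continue
        a_start = acrs_c["start"].to_numpy()
        a_end = acrs_c["end"].to_numpy()
        for g in genes_c.itertuples(index=False):
            lo = min(g.body_start, g.prom_start)
            hi = max(g.body_end, g.prom_end)
            near = (a_start < hi) & (a_end > lo)
            for idx, name, s, e in zip(acrs_c.index[near],
                                       acrs_c["name"].to_numpy()[near],
                                       a_start[near], a_end[near]):
                if (_overlaps(s, e, g.body_start, g.body_end)
                        or _overlaps(s, e, g.prom_start, g.prom_end)):
                    pairs.append((idx, name, g.gene_id))
    return pd.DataFrame(pairs, columns=["acr_index", "acr_id", "gene_id"])


def gene_atac_signal(acrs: pd.DataFrame, counts: pd.DataFrame,
                     ann: pd.DataFrame,
                     chrom_sizes: dict | None = None) -> pd.DataFrame:
    """Per-gene ATAC signal: sum of counts of ACRs overlapping the gene body
    or strand-aware 1-kb promoter (an ACR overlapping two genes counts
    toward both).  ``counts`` is ACR x sample, indexed by ACR name.
    Errors if an ACR chromosome is unknown to the annotation.
    """
    assoc = associate_acrs(acrs, ann, chrom_sizes, strict_chroms=True)
    out = pd.DataFrame(0.0, index=ann["gene_id"], columns=counts.columns)
    for gene_id, grp in assoc.groupby("gene_id"):
        out.loc[gene_id] = counts.loc[grp["acr_id"]].sum(axis=0)
    return out


def call_dars_dags(
    signal: pd.DataFrame,
    conditions: pd.Series,
    fc_cut: float = _CH["dar_fold_change"],
    p_cut: float = _CH["dar_p"],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Differential accessibility between two conditions.

    ``signal`` is region/gene x cell (or sample); ``conditions`` labels the
    columns.  Counts are depth-normalised to counts per 10,000 per cell,
    compared by a two-sided rank-sum test across cells, and called
    differential iff fold change >= ``fc_cut`` (either direction) and
    p < ``p_cut``.
    """
    conds = sorted(pd.Series(conditions).unique())
    if len(conds) != 2:
        raise ValueError("need exactly two conditions")
    cond = pd.Series(conditions)
    depth = signal.sum(axis=0).replace(0, 1.0)
    norm = signal / depth * _CH["norm_per"]
    a = norm.loc[:, cond[signal.columns] == conds[0]].to_numpy()
    b = norm.loc[:, cond[signal.columns] == conds[1]].to_numpy()
    from .markers import rank_sum_test
    x = np.vstack([a.T, b.T])
    mask = np.zeros(x.shape[0], dtype=bool)
    mask[: a.shape[1]] = True
    p = rank_sum_test(x, mask)
    fc = (a.mean(axis=1) + pseudocount) / (b.mean(axis=1) + pseudocount)
    fc_sym = np.maximum(fc, 1.0 / fc)
    return pd.DataFrame({
        "feature": signal.index,
        "fold_change": fc,
        "p": p,
        "direction": np.where(fc >= 1.0, f"up_in_{conds[0]}", f"up_in_{conds[1]}"),
        "is_differential": (fc_sym >= fc_cut) & (p < p_cut),
    }).set_index("feature")
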