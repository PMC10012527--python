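"""Diurnal rhythmic-gene calling from replicated time-course counts.

A gene is a potential rhythmically expressed gene (REG) when its
adjacent-timepoint fold-change signs alternate strictly (+-+-...) over at
least 72 h (six 12-h pairs); it is a significant REG when at least four
consecutive pairs (48 h) inside that window are individually significant
(FDR < 0.05, fold change > 1.5).  Pair significance uses a moderated
t-statistic: per-gene replicate variance pooled across timepoints and
shrunk toward the across-gene median, which keeps n=2 designs powered and
calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .config import ANALYSIS_DEFAULTS

__all__ = [
    "PairStats",
    "adjacent_pair_changes",
    "longest_alternating_run",
    "call_regs",
    "significant_regs",
    "classify_patterns",
    "differential_rhythm",
]

_RH = ANALYSIS_DEFAULTS["rhythm"]

def estimate_dispersion(cpm: pd.DataFrame, groups: list) -> float:
    """Genome-wide NB dispersion by method of moments.

    ``groups`` lists the replicate column sets (one per timepoint).  With
    E[var] = mu + alpha*mu^2 across replicates, alpha is estimated per gene
    by pooling (var - mean) against mean^2 over timepoints, and summarised
    by the across-gene median (clipped at a small positive floor)."""
    num = np.zeros(len(cpm))
    den = np.zeros(len(cpm))
    for cc in groups:
        block = cpm[cc].to_numpy()
        m = block.mean(axis=1)
        v = block.var(axis=1, ddof=1)
        num += v - m
        den += m ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha_g = num / den
    alpha = float(np.nanmedian(alpha_g))
    return max(alpha, 1e-4)


def _cpm(counts: pd.DataFrame) -> pd.DataFrame:
    tot = counts.sum(axis=0)
    return counts / tot * 1e6


@dataclass
class PairStats:
    """Adjacent-pair statistics per condition.

    Each mapping is condition -> DataFrame (genes x pairs); pair columns
    are labelled by the hour of the later timepoint.
    """

    sign: dict
    fdr: dict
    fold_change: dict
    log2fc: dict
    timepoints: np.ndarray
    spacing_h: float


def adjacent_pair_changes(counts: pd.DataFrame, sheet: pd.DataFrame) -> PairStats:
    """Fold change and significance between every pair of adjacent timepoints.

    ``counts`` is gene x sample; ``sheet`` has columns sample, condition,
    replicate, timepoint_h.  Requires >= 2 replicates per (condition,
    timepoint).  Sign is + for FC > 1, - for FC < 1, 0 for FC exactly 1;
    FDR is Benjamini-Hochberg across genes within each pair.
    """
    sheet = sheet.set_index("sample")
    cpm = _cpm(counts)
    log = np.log2(cpm + 1.0)
    sign: dict = {}
    fdr: dict = {}
    fold: dict = {}
    lfc: dict = {}
    timepoints = np.array(sorted(sheet["timepoint_h"].unique()))
    spacing = float(np.diff(timepoints).min()) if len(timepoints) > 1 else np.nan
    for cond in sheet["condition"].unique():
        cols = {t: sheet.index[(sheet["condition"] == cond)
                               & (sheet["timepoint_h"] == t)].tolist()
                for t in timepoints}
        for t, cc in cols.items():
            if len(cc) < 2:
                raise ValueError(
                    f"condition {cond} timepoint {t} has a single replicate")
        # genome-wide NB dispersion shared across genes (the information
        # sharing that keeps an n=2 design powered)
        alpha = estimate_dispersion(cpm, list(cols.values()))
        log2_sq = np.log(2.0) ** 2

        s_cols, f_cols, fc_cols, l_cols = {}, {}, {}, {}
        for t0, t1 in zip(timepoints[:-1], timepoints[1:]):
            n0, n1 = len(cols[t0]), len(cols[t1])
            m0 = cpm[cols[t0]].mean(axis=1).to_numpy()
            m1 = cpm[cols[t1]].mean(axis=1).to_numpy()
            # raw-count means set the Poisson part of the NB variance
            c0 = counts[cols[t0]].mean(axis=1).to_numpy()
            c1 = counts[cols[t1]].mean(axis=1).to_numpy()
            fc = (m1 + 1.0) / (m0 + 1.0)
            delta = np.log2(m1 + 1.0) - np.log2(m0 + 1.0)
            # Wald variance of log2 mean under the NB model (delta method)
            var = ((1.0 / np.maximum(c0, 0.5) + alpha) / n0
                   + (1.0 / np.maximum(c1, 0.5) + alpha) / n1) / log2_sq
            with np.errstate(invalid="ignore", divide="ignore"):
                z = delta / np.sqrt(var)
            p = 2.0 * scipy.stats.norm.sf(np.abs(z))
            p = np.where(np.isnan(p), 1.0, p)
            key = float(t1)
            s_cols[key] = np.sign(np.log(fc)).astype(int)
            f_cols[key] = multipletests(p, method="fdr_bh")[1]
            fc_cols[key] = fc
            l_cols[key] = np.log2(fc)
        idx = counts.index
        sign[cond] = pd.DataFrame(s_cols, index=idx)
        fdr[cond] = pd.DataFrame(f_cols, index=idx)
        fold[cond] = pd.DataFrame(fc_cols, index=idx)
        lfc[cond] = pd.DataFrame(l_cols, index=idx)
    return PairStats(sign=sign, fdr=fdr, fold_change=fold, log2fc=lfc,
                     timepoints=timepoints, spacing_h=spacing)


def longest_alternating_run(signs) -> tuple[int, int]:
    """Length and start index of the longest strictly alternating run of
    nonzero signs; zeros break a run.  Earliest run wins ties."""
    s = np.asarray(signs, dtype=int)
    best_len, best_start = 0, 0
    run_len, run_start = 0, 0
    for i, v in enumerate(s):
        if v == 0:
            run_len = 0
            continue
        if run_len > 0 and v == -s[i - 1]:
            run_len += 1
        else:
            run_len = 1
            run_start = i
        if run_len > best_len:
            best_len, best_start = run_len, run_start
    return best_len, best_start


def call_regs(stats: PairStats,
              window_h: float = _RH["reg_window_h"]) -> pd.DataFrame:
    """Call potential REGs per condition from the sign table.

    A gene is a REG in a condition iff its sign string contains at least
    ``window_h / spacing`` consecutive strictly alternating nonzero signs.
    Genes rhythmic in both conditions must show the same sign pattern on
    the overlap of their alternating windows, else ``pattern_match`` is
    False.
    """
    n_pairs_needed = int(round(window_h / stats.spacing_h))
    conds = list(stats.sign)
    genes = stats.sign[conds[0]].index
    out = pd.DataFrame(index=genes)
    windows = {}
    for cond in conds:
        s = stats.sign[cond].to_numpy()
        lens, starts = zip(*(longest_alternating_run(row) for row in s))
        lens = np.array(lens)
        starts = np.array(starts)
        out[f"reg_{cond}"] = lens >= n_pairs_needed
        out[f"run_start_{cond}"] = starts
        out[f"run_len_{cond}"] = lens
        windows[cond] = (starts, lens)
    if len(conds) >= 2:
        c0, c1 = conds[:2]
        both = out[f"reg_{c0}"] & out[f"reg_{c1}"]
        match = np.full(len(genes), np.nan, dtype=object)
        s0 = stats.sign[c0].to_numpy()
        s1 = stats.sign[c1].to_numpy()
        for i in np.flatnonzero(both.to_numpy()):
            a0, l0 = windows[c0][0][i], windows[c0][1][i]
            a1, l1 = windows[c1][0][i], windows[c1][1][i]
            lo, hi = max(a0, a1), min(a0 + l0, a1 + l1)
            match[i] = bool(hi > lo and np.array_equal(s0[i, lo:hi], s1[i, lo:hi]))
        out["pattern_match"] = match
    return out


def significant_regs(
    regcalls: pd.DataFrame,
    stats: PairStats,
    window_h: float = _RH["significant_window_h"],
    fdr_cut: float = _RH["pair_fdr"],
    fc_cut: float = _RH["pair_fold_change"],
) -> pd.DataFrame:
    """Flag REGs with a significant 48-h stretch inside their window.

    Significant iff >= ``window_h / spacing`` consecutive pairs within the
    gene's alternating window each have FDR < ``fdr_cut`` and fold change
    (either direction) > ``fc_cut``.
    """
    n_sig = int(round(window_h / stats.spacing_h))
    out = regcalls.copy()
    for cond in stats.sign:
        fdr = stats.fdr[cond].to_numpy()
        fc = stats.fold_change[cond].to_numpy()
        fc_sym = np.maximum(fc, 1.0 / fc)
        good = (fdr < fdr_cut) & (fc_sym > fc_cut)
        flags = np.zeros(len(out), dtype=bool)
        for i in np.flatnonzero(out[f"reg_{cond}"].to_numpy()):
            a = out[f"run_start_{cond}"].iloc[i]
            ln = out[f"run_len_{cond}"].iloc[i]
            window = good[i, a: a + ln]
            run = 0
            for v in window:
                run = run + 1 if v else 0
                if run >= n_sig:
                    flags[i] = True
                    break
        out[f"significant_{cond}"] = flags
    sig_cols = [c for c in out.columns if c.startswith("significant_")]
    out["significant_any"] = out[sig_cols].any(axis=1)
    return out


def classify_patterns(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    reg_genes,
    k: int = _RH["n_pattern_groups"],
    seed: int = 0,
    condition: str = "wt",
) -> pd.DataFrame:
    """Group REG expression patterns by seeded k-means.

    Features are the z-scored log2 mean-CPM profiles across timepoints of
    ``condition``.  Groups are labelled P1..Pk ordered by the timepoint of
    their centroid peak (then by size), which separates day- from
    night-peaking programmes.
    """
    reg_genes = pd.Index(reg_genes)
    if len(reg_genes) < k:
        raise ValueError(f"need at least k={k} REGs, got {len(reg_genes)}")
    sheet = sheet.set_index("sample")
    cpm = _cpm(counts)
    timepoints = sorted(sheet["timepoint_h"].unique())
    prof = np.column_stack([
        np.log2(cpm[sheet.index[(sheet["condition"] == condition)
                                & (sheet["timepoint_h"] == t)]]
                .mean(axis=1).loc[reg_genes] + 1.0)
        for t in timepoints
    ])
    mu = prof.mean(axis=1, keepdims=True)
    sd = prof.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (prof - mu) / sd
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(z)
    peaks = km.cluster_centers_.argmax(axis=1)
    order = np.lexsort((-np.bincount(km.labels_, minlength=k), peaks))
    relabel = {old: f"P{i + 1}" for i, old in enumerate(order)}
    return pd.DataFrame({
        "gene": reg_genes,
        "group": [relabel[l] for l in km.labels_],
        "peak_timepoint_h": [timepoints[p] for p in peaks[km.labels_]],
    })


def _amplitude(tp_means_log: np.ndarray, statistic: str) -> np.ndarray:
    """Per-gene rhythm amplitude from a genes x timepoints log2 matrix."""
    if statistic == "range":
        return tp_means_log.max(axis=1) - tp_means_log.min(axis=1)
    if statistic == "mean_abs_adjacent":
        return np.abs(np.diff(tp_means_log, axis=1)).mean(axis=1)
    raise ValueError(f"unknown amplitude statistic {statistic!r}")


def differential_rhythm(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    genes=None,
    n_perm: int = 1000,
    seed: int = 0,
    statistic: str = "mean_abs_adjacent",
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Per-gene amplitude difference between conditions with a permutation p.

    Amplitude is computed on log2(mean CPM + 1) timepoint profiles; the
    default statistic is the mean absolute adjacent-pair log2 fold change
    (the range max-min is available as ``statistic='range'``).  Condition
    labels are permuted within each timepoint across replicates (seeded;
    ``exhaustive=True`` enumerates all label assignments, only sensible
    for small designs).  The p-value is two-sided on |amplitude
    difference|.
    """
    sheet = sheet.set_index("sample")
    conds = sorted(sheet["condition"].unique())
    if len(conds) != 2:
        raise ValueError("differential rhythm needs exactly two conditions")
    timepoints = sorted(sheet["timepoint_h"].unique())
    for c in conds:
        tps = set(sheet.loc[sheet["condition"] == c, "timepoint_h"])
        if tps != set(timepoints):
            raise ValueError("conditions must share all timepoints")
    cpm = _cpm(counts)
    if genes is not None:
        cpm = cpm.loc[pd.Index(genes)]
    log = np.log2(cpm + 1.0)

    # per-timepoint replicate blocks (pooled across conditions)
    blocks, n_a = [], None
    for t in timepoints:
        cols_a = sheet.index[(sheet["condition"] == conds[0])
                             & (sheet["timepoint_h"] == t)].tolist()
        cols_b = sheet.index[(sheet["condition"] == conds[1])
                             & (sheet["timepoint_h"] == t)].tolist()
        n_a = len(cols_a)
        blocks.append(log[cols_a + cols_b].to_numpy())

    def amp_diff(assignments) -> np.ndarray:
        ma = np.column_stack([
            b[:, list(sel)].mean(axis=1) for b, sel in zip(blocks, assignments)])
        mb = np.column_stack([
            b[:, [j for j in range(b.shape[1]) if j not in sel]].mean(axis=1)
            for b, sel in zip(blocks, assignments)])
        return _amplitude(ma, statistic) - _amplitude(mb, statistic)

    obs = amp_diff([tuple(range(n_a))] * len(timepoints))

    from itertools import combinations, product
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(log), dtype=int)
    if exhaustive:
        per_tp = list(combinations(range(blocks[0].shape[1]), n_a))
        all_assignments = list(product(per_tp, repeat=len(timepoints)))
        n_used = len(all_assignments)
        for assignment in all_assignments:
            exceed += np.abs(amp_diff(assignment)) >= np.abs(obs) - 1e-12
        p = exceed / n_used
    else:
        n_used = n_perm
        n_tot = blocks[0].shape[1]
        for _ in range(n_perm):
            assignment = [tuple(rng.choice(n_tot, size=n_a, replace=False))
                          for _ in timepoints]
            exceed += np.abs(amp_diff(assignment)) >= np.abs(obs) - 1e-12
        p = (1 + exceed) / (n_perm + 1.0)

    amp_a = _amplitude(np.column_stack(
        [b[:, :n_a].mean(axis=1) for b in blocks]), statistic)
    amp_b = _amplitude(np.column_stack(
        [b[:, n_a:].mean(axis=1) for b in blocks]), statistic)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(amp_b > 0, amp_a / amp_b, np.inf)
    return pd.DataFrame({
        "gene": log.index,
        f"amplitude_{conds[0]}": amp_a,
        f"amplitude_{conds[1]}": amp_b,
        "amplitude_diff": obs,
        "amplitude_ratio": ratio,
        "p_perm": p,
    }).set_index("gene")
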