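"""TSS-proximity and directionality classification of motifs.

A motif concentrated near transcription start sites has a small median
absolute deviation (MAD) of its signed gene-frame TSS distances.  For each
orientation the observed MAD is compared with shuffled controls — the same
number of pseudo-occurrences placed uniformly over all ACR base positions,
100 times — and the orientation "passes" when its MAD falls below the
control mean minus two control standard deviations.  Motifs where exactly
one orientation passes are directional; both, non-directional; neither,
non-enriched around the TSS.  The passing MAD doubles as the targeting
radius: expressed genes with an occurrence closer to the TSS than the
radius are the motif's targets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ANALYSIS_DEFAULTS

__all__ = [
    "mad",
    "TssShuffler",
    "shuffle_controls",
    "classify_directionality",
    "assign_targets",
]

_DIR = ANALYSIS_DEFAULTS["directionality"]

NON_ENRICHED = "non-enriched around TSS"
DIRECTIONAL = "directional"
NON_DIRECTIONAL = "non-directional"


def mad(values) -> float:
    """Raw median absolute deviation from the median (no scaling)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("MAD of an empty list")
    return float(np.median(np.abs(x - np.median(x))))


class TssShuffler:
    """Uniform placement of pseudo-occurrences over ACR base positions.

    Precomputes the concatenated ACR coordinate space and the ACR-to-gene
    association so repeated shuffles are cheap.  A pseudo-occurrence at a
    base of an ACR contributes one signed gene-frame TSS distance per gene
    associated with that ACR.
    """

    def __init__(self, acrs: pd.DataFrame, ann: pd.DataFrame,
                 chrom_sizes: dict | None = None):
        from .chromatin import associate_acrs
        acrs = acrs.reset_index(drop=True)
        assoc = associate_acrs(acrs, ann, chrom_sizes)
        self._acr_start = acrs["start"].to_numpy()
        lengths = (acrs["end"] - acrs["start"]).to_numpy()
        self._cum = np.concatenate([[0], np.cumsum(lengths)])
        self.total_length = int(self._cum[-1])
        gene_info = ann.set_index("gene_id")
        tss = np.where(gene_info["strand"] == "+",
                       gene_info["start"], gene_info["end"] - 1)
        sign = np.where(gene_info["strand"] == "+", 1, -1)
        tss_map = dict(zip(gene_info.index, tss))
        sign_map = dict(zip(gene_info.index, sign))
        pair_lists: list = [[] for _ in range(len(acrs))]
        for p in assoc.itertuples(index=False):
            pair_lists[p.acr_index].append(
                (tss_map[p.gene_id], sign_map[p.gene_id]))
        self._pair_tss = [np.array([t for t, _ in lst], dtype=float)
                          for lst in pair_lists]
        self._pair_sign = [np.array([s for _, s in lst], dtype=float)
                           for lst in pair_lists]
        # fast path when every ACR maps to at most one gene
        self._simple = all(len(lst) <= 1 for lst in pair_lists)
        if self._simple:
            self._tss1 = np.array([lst[0] if lst.size else np.nan
                                   for lst in self._pair_tss])
            self._sign1 = np.array([lst[0] if lst.size else 0.0
                                    for lst in self._pair_sign])

    def distances(self, flat_positions: np.ndarray) -> np.ndarray:
        """Signed TSS distances generated by pseudo-occurrences at the given
        concatenated-ACR coordinates."""
        acr_i = np.searchsorted(self._cum, flat_positions, side="right") - 1
        pos = self._acr_start[acr_i] + (flat_positions - self._cum[acr_i])
        if self._simple:
            t = self._tss1[acr_i]
            d = self._sign1[acr_i] * (pos - t)
            return d[~np.isnan(t)]
        out = []
        for a, g in zip(acr_i, pos):
            t = self._pair_tss[a]
            if t.size:
                out.append(self._pair_sign[a] * (g - t))
        return np.concatenate(out) if out else np.empty(0)

    def sample_mads(self, n_occurrences: int,
                    n_shuffles: int = _DIR["n_shuffles"],
                    seed: int | np.random.Generator = 0) -> np.ndarray:
        """MAD of each of ``n_shuffles`` uniform placements of
        ``n_occurrences`` pseudo-occurrences."""
        if n_occurrences <= 0:
            raise ValueError("need at least one occurrence to shuffle")
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        mads = np.empty(n_shuffles)
        for s in range(n_shuffles):
            u = rng.integers(0, self.total_length, size=n_occurrences)
            mads[s] = mad(self.distances(u))
        return mads


def shuffle_controls(n_occurrences: int, acrs: pd.DataFrame, ann: pd.DataFrame,
                     n_shuffles: int = _DIR["n_shuffles"], seed: int = 0,
                     chrom_sizes: dict | None = None) -> np.ndarray:
    """Convenience wrapper: control MADs for one occurrence count."""
    return TssShuffler(acrs, ann, chrom_sizes).sample_mads(
        n_occurrences, n_shuffles, seed)


def classify_directionality(
    occurrences: pd.DataFrame,
    shuffler: TssShuffler,
    n_shuffles: int = _DIR["n_shuffles"],
    sd_factor: float = _DIR["sd_factor"],
    seed: int = 0,
) -> pd.Series:
    """Classify one motif from its occurrence table (distance, orientation).

    Controls are drawn per orientation with the matched occurrence count,
    so a sparsely occurring orientation faces an appropriately noisy null.
    Returns a Series with MADs, control statistics, the class and the
    effective targeting radius.
    """
    rng = np.random.default_rng(seed)
    out: dict = {}
    passes: dict = {}
    for orient in ("forward", "reverse"):
        d = occurrences.loc[occurrences["orientation"] == orient, "distance"]
        d = d.to_numpy(dtype=float)
        if d.size == 0:
            out[f"mad_{orient}"] = np.nan
            out[f"control_mean_{orient}"] = np.nan
            out[f"control_sd_{orient}"] = np.nan
            passes[orient] = False
            continue
        m = mad(d)
        ctrl = shuffler.sample_mads(d.size, n_shuffles, rng)
        mean, sd = float(np.mean(ctrl)), float(np.std(ctrl, ddof=1))
        out[f"mad_{orient}"] = m
        out[f"control_mean_{orient}"] = mean
        out[f"control_sd_{orient}"] = sd
        passes[orient] = bool(m < mean - sd_factor * sd)
    n_pass = sum(passes.values())
    if n_pass == 0:
        out["class"] = NON_ENRICHED
        out["radius"] = np.nan
    elif n_pass == 1:
        out["class"] = DIRECTIONAL
        orient = "forward" if passes["forward"] else "reverse"
        out["radius"] = out[f"mad_{orient}"]
        out["direction"] = orient
    else:
        out["class"] = NON_DIRECTIONAL
        out["radius"] = min(out["mad_forward"], out["mad_reverse"])
    out["pass_forward"] = passes["forward"]
    out["pass_reverse"] = passes["reverse"]
    return pd.Series(out)


def assign_targets(
    call: pd.Series,
    occurrences: pd.DataFrame,
    cluster_mean_cpm: pd.DataFrame,
    expressed_cpm: float = ANALYSIS_DEFAULTS["motifs"]["expressed_cpm"],
) -> pd.Index:
    """Target genes of a TSS-enriched motif by the MAD-radius rule.

    Targets are expressed genes (mean CPM > 1 in at least one cell
    cluster) with an occurrence whose |signed TSS distance| is strictly
    below the motif's effective MAD radius.  Calling this for a
    non-enriched motif is an error.
    """
    if call["class"] == NON_ENRICHED:
        raise ValueError("motif is not enriched around the TSS; no radius")
    radius = call["radius"]
    expressed = cluster_mean_cpm.index[(cluster_mean_cpm > expressed_cpm).any(axis=1)]
    close = occurrences.loc[
        np.abs(occurrences["distance"].to_numpy()) < radius, "gene_id"]
    return pd.Index(sorted(set(close))).intersection(expressed)
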