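"""k-mer scanning, per-cell motif statistics, Moran's I and enrichment."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from fibrorhythm import motifs as mo
from tests.conftest import make_adata

COMP = str.maketrans("ACGT", "TGCA")


def rc(s):
    return s.translate(COMP)[::-1]


def test_kmer_code_round_trip():
    rng = np.random.default_rng(0)
    for _ in range(50):
        kmer = "".join(rng.choice(list("ACGT"), 8))
        assert mo.kmer_string(mo.kmer_code(kmer)) == kmer
        assert mo.kmer_string(mo.revcomp_code(mo.kmer_code(kmer))) == rc(kmer)


def toy_scan(seq, strand="+", tss_offset=0, acr_span=None):
    """Run the scanner on a single-gene single-ACR toy chromosome."""
    L = len(seq)
    acr_span = acr_span or (0, L)
    if strand == "+":
        gene = {"gene_id": "g1", "chrom": "c", "start": tss_offset,
                "end": L, "strand": "+"}
    else:
        gene = {"gene_id": "g1", "chrom": "c", "start": 0,
                "end": L - tss_offset, "strand": "-"}
    ann = pd.DataFrame([gene])
    acrs = pd.DataFrame([{"chrom": "c", "start": acr_span[0],
                          "end": acr_span[1], "name": "a1"}])
    return mo.build_motif_gene_matrix({"c": seq}, acrs, ann, chrom_sizes={"c": L})


def naive_occurrences(seq, strand, tss, k=8):
    """Sliding-window string-scan oracle in the gene frame."""
    frame = seq if strand == "+" else rc(seq)
    out = []
    for i in range(len(frame) - k + 1):
        w = frame[i:i + k]
        if strand == "+":
            mid = i + k // 2
            d = mid - tss
        else:
            mid = len(seq) - 1 - (i + k // 2)
            d = tss - mid
        out.append((w, d, "forward"))
        out.append((rc(w), d, "reverse"))
    return sorted(out)


@pytest.mark.parametrize("seed,strand", [(s, st) for s in range(10)
                                         for st in "+-"])
def test_scan_matches_naive_oracle(seed, strand):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), 300))
    mgm = toy_scan(seq, strand=strand)
    tss = 0 if strand == "+" else len(seq) - 1
    got = sorted((mo.kmer_string(int(c)), int(d), o)
                 for c, d, o in zip(mgm.occurrences["motif_code"],
                                    mgm.occurrences["distance"],
                                    mgm.occurrences["orientation"]))
    assert got == naive_occurrences(seq, strand, tss)


def test_planted_kmer_found_at_minus_fifty_forward():
    rng = np.random.default_rng(3)
    motif = "TGGGCCTA"
    # gene starts at position 200 (TSS), ACR covers the upstream promoter
    seq = list("".join(rng.choice(list("ACGT"), 400)))
    tss = 200
    d = -50
    start = tss + d - 4  # midpoint convention: start + k//2 at distance d
    seq[start:start + 8] = motif
    mgm = toy_scan("".join(seq), strand="+", tss_offset=200)
    occ = mgm.occurrences_of(motif)
    fwd = occ[occ["orientation"] == "forward"]
    assert mgm.motif_row(motif)[0] == 1
    assert -50 in set(fwd["distance"])


def test_absent_kmer_has_all_zero_row():
    mgm = toy_scan("ACACACACACACACACAC")
    assert mgm.motif_row("TTTTTTTT").sum() == 0
    assert len(mgm.occurrences_of("TTTTTTTT")) == 0


def test_acr_outside_chromosome_is_error():
    ann = pd.DataFrame([{"gene_id": "g", "chrom": "c", "start": 0, "end": 10,
                         "strand": "+"}])
    acrs = pd.DataFrame([{"chrom": "c", "start": 5, "end": 40, "name": "a"}])
    with pytest.raises(ValueError, match="bounds"):
        mo.build_motif_gene_matrix({"c": "ACGT" * 5}, acrs, ann)


# ---------------------------------------------------------------------------
# per-cell statistics
# ---------------------------------------------------------------------------

def _mgm_with_targets(genes, target_map, k=8):
    """Minimal MotifGeneMatrix with prescribed targets."""
    rows, cols = [], []
    occ = []
    gi = {g: i for i, g in enumerate(genes)}
    for kmer, targets in target_map.items():
        for g in targets:
            rows.append(mo.kmer_code(kmer))
            cols.append(gi[g])
            occ.append({"motif_code": mo.kmer_code(kmer), "gene_id": g,
                        "acr_id": "a", "distance": 0, "orientation": "forward"})
    inc = sp.csr_matrix((np.ones(len(rows)), (rows, cols)),
                        shape=(4 ** k, len(genes)))
    return mo.MotifGeneMatrix(k=k, genes=pd.Index(genes, name="gene_id"),
                              occurrences=pd.DataFrame(occ), incidence=inc)


def test_per_cell_stats_hand_case():
    adata = make_adata(np.array([[2, 0, 5], [1, 3, 0]]),
                       genes=["g1", "g2", "g3"])
    mgm = _mgm_with_targets(["g1", "g2", "g3"], {"AAAAAAAA": ["g1", "g2"]})
    counts, umis = mo.per_cell_motif_stats(mgm, adata, motifs=["AAAAAAAA"])
    assert counts.loc["AAAAAAAA"].tolist() == [1, 2]
    assert umis.loc["AAAAAAAA"].tolist() == [2, 4]


def test_all_gene_targets_equal_library_stats():
    rng = np.random.default_rng(0)
    x = rng.poisson(1, (5, 4))
    adata = make_adata(x, genes=list("wxyz"))
    mgm = _mgm_with_targets(list("wxyz"), {"CCCCCCCC": list("wxyz")})
    counts, umis = mo.per_cell_motif_stats(mgm, adata, motifs=["CCCCCCCC"])
    np.testing.assert_array_equal(counts.loc["CCCCCCCC"], (x >= 1).sum(axis=1))
    np.testing.assert_array_equal(umis.loc["CCCCCCCC"], x.sum(axis=1))


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

def morans_oracle(values, coords, k):
    """Brute-force double sum with independently built kNN weights."""
    n = len(values)
    w = np.zeros((n, n))
    for i in range(n):
        d = [(np.hypot(*(coords[i] - coords[j])), j) for j in range(n) if j != i]
        for _, j in sorted(d)[:k]:
            w[i, j] = 1
    w = np.maximum(w, w.T)
    rs = w.sum(axis=1)
    rs[rs == 0] = 1
    w = w / rs[:, None]
    z = values - values.mean()
    num = sum(w[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return n / w.sum() * num / (z @ z)


def test_constant_vector_is_undefined():
    coords = np.random.default_rng(0).normal(size=(10, 2))
    val, status = mo.morans_i(np.ones(10), coords, graph_k=3)
    assert status == "undefined"
    assert val == 0.0


@pytest.mark.parametrize("seed", range(10))
def test_morans_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 80))
    coords = rng.normal(size=(n, 2))
    values = rng.normal(size=n)
    k = int(rng.integers(2, 8))
    got, status = mo.morans_i(values, coords, graph_k=k)
    assert status == "ok"
    assert got == pytest.approx(morans_oracle(values, coords, k), abs=1e-10)


def test_two_blobs_are_strongly_autocorrelated():
    rng = np.random.default_rng(1)
    coords = np.vstack([rng.normal(0, 0.3, (40, 2)),
                        rng.normal(5, 0.3, (40, 2))])
    values = np.array([1.0] * 40 + [0.0] * 40)
    got, _ = mo.morans_i(values, coords, graph_k=10)
    assert got > 0.8
    assert got == pytest.approx(morans_oracle(values, coords, 10), abs=1e-10)


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def test_selection_is_intersection_of_top_five_percent():
    rng = np.random.default_rng(0)
    n = 100
    count_i = np.arange(n, dtype=float)
    umi_i = rng.permutation(n).astype(float)
    table = pd.DataFrame({"moran_count": count_i, "moran_umi": umi_i,
                          "status": "ok"},
                         index=[f"m{i}" for i in range(n)])
    sel = mo.select_cell_specific_motifs(table)
    top_c = set(table.sort_values("moran_count").index[-5:])
    top_u = set(table.sort_values("moran_umi").index[-5:])
    # linear-interpolation 95th percentile admits the top five of each rank
    assert set(sel) == top_c & top_u


def test_undefined_motifs_never_selected():
    table = pd.DataFrame({"moran_count": [9.0, 0.1], "moran_umi": [9.0, 0.1],
                          "status": ["undefined", "ok"]}, index=["dead", "ok"])
    assert "dead" not in set(mo.select_cell_specific_motifs(table))


# ---------------------------------------------------------------------------
# motif grouping
# ---------------------------------------------------------------------------

def test_disjoint_programmes_split_and_duplicates_stay_together():
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(40)]
    counts = np.zeros((60, 40), dtype=int)
    counts[:30, :20] = rng.poisson(5, (30, 20))     # programme A in cells 0-29
    counts[30:, 20:] = rng.poisson(5, (30, 20))     # programme B in cells 30-59
    adata = make_adata(counts, genes=genes)
    part = pd.Series([0] * 30 + [1] * 30, index=adata.obs_names)
    fam_a = {f"AAAAAAA{b}": genes[:20] for b in "ACG"}
    fam_b = {f"CCCCCCC{b}": genes[20:] for b in "ACG"}
    mgm = _mgm_with_targets(genes, {**fam_a, **fam_b})
    selected = sorted(fam_a) + sorted(fam_b)
    out = mo.cluster_motifs(selected, mgm, adata, part, fiber_cluster=1)
    groups_a = set(out.loc[sorted(fam_a), "group"])
    groups_b = set(out.loc[sorted(fam_b), "group"])
    assert groups_a == {"M1"} and groups_b == {"M2"}


# ---------------------------------------------------------------------------
# cluster enrichment
# ---------------------------------------------------------------------------

def log_hypergeom_tail_oracle(k, N, K, n):
    """P(X >= k) for X ~ Hypergeom(N, K, n) via log-binomial summation."""
    from math import lgamma, exp

    def lchoose(a, b):
        if b < 0 or b > a:
            return -np.inf
        return lgamma(a + 1) - lgamma(b + 1) - lgamma(a - b + 1)

    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += exp(lchoose(K, x) + lchoose(N - K, n - x) - lchoose(N, n))
    return total


def test_obs_exp_two_and_fisher_p_matches_hypergeometric_oracle():
    genes = [f"g{i}" for i in range(1000)]
    max_cluster = pd.Series(["c3"] * 200 + ["other"] * 800, index=genes)
    targets = genes[:40] + genes[200:260]  # 40 in-cluster of 100 targets
    out = mo.cluster_enrichment(targets, max_cluster, genes, n_random=2000,
                                seed=0)
    row = out.loc["c3"]
    assert row["obs_exp"] == pytest.approx(2.0)
    assert row["fisher_p"] == pytest.approx(
        log_hypergeom_tail_oracle(40, 1000, 200, 100), rel=1e-9)
    assert row["call"] == "enriched"


def test_proportional_targets_not_called():
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(1000)]
    max_cluster = pd.Series(["c3"] * 200 + ["other"] * 800, index=genes)
    targets = list(rng.choice(genes, 100, replace=False))
    out = mo.cluster_enrichment(targets, max_cluster, genes, n_random=500,
                                seed=0)
    assert out.loc["c3", "call"] == "none" or \
        0.67 <= out.loc["c3", "obs_exp"] <= 1.5


def test_fisher_p_symmetric_under_complement():
    genes = [f"g{i}" for i in range(300)]
    max_cluster = pd.Series(["a"] * 120 + ["b"] * 180, index=genes)
    targets = genes[:50] + genes[120:140]
    out = mo.cluster_enrichment(targets, max_cluster, genes, n_random=100,
                                seed=0)
    # a-enrichment tail equals b-depletion tail in a two-cluster universe
    assert out.loc["a", "fisher_p"] == pytest.approx(out.loc["b", "fisher_p"],
                                                     rel=1e-9)


def test_random_control_mean_near_one():
    genes = [f"g{i}" for i in range(1000)]
    max_cluster = pd.Series((["c"] * 250 + ["d"] * 750), index=genes)
    targets = genes[::10]
    out = mo.cluster_enrichment(targets, max_cluster, genes, n_random=10_000,
                                seed=1)
    for c in ("c", "d"):
        mean = out.loc[c, "control_mean_obs_exp"]
        sd = out.loc[c, "control_sd_obs_exp"]
        assert abs(mean - 1.0) < 3 * sd / np.sqrt(10_000) + 1e-3


def test_empty_expressed_set_is_error():
    with pytest.raises(ValueError):
        mo.cluster_enrichment(["g1"], pd.Series(dtype=object), [])
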