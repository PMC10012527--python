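"""Cell filters, modularity folds, the MEG gene distance and cluster merging."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from fibrorhythm import preprocess as pp
from tests.conftest import make_adata


# ---------------------------------------------------------------------------
# filter_cells
# ---------------------------------------------------------------------------

def test_filter_identical_totals_removes_none_by_umi_rule():
    counts = np.full((6, 3), 4)
    out, report = pp.filter_cells(make_adata(counts))
    assert out.n_obs == 6
    assert len(report) == 0


def test_filter_mad_zero_removes_only_outlier():
    # totals [10]*6 + [100]: median 10, MAD 0 -> only the 100-total cell goes
    counts = np.array([[10]] * 6 + [[100]])
    out, report = pp.filter_cells(make_adata(counts))
    assert out.n_obs == 6
    assert report["cell_id"].tolist() == ["c6"]
    assert report["reason"].iloc[0] == "umi_total_above_median_2mad"


def test_filter_quantile_rule_matches_brute_force_oracle():
    # 100 cells with detected-gene counts 1..100 (counts of 2 => detected
    # and expressed coincide); equal totals so the UMI rule removes nobody
    n = 100
    counts = np.zeros((n, n + 1), dtype=int)
    for i in range(n):
        counts[i, : i + 1] = 2
        counts[i, n] = 2 * (n - i - 1)  # equalise totals
    out, report = pp.filter_cells(make_adata(counts))

    # independent oracle: linear-interpolation quantiles from sorted order
    def quantile(sorted_vals, q):
        pos = q * (len(sorted_vals) - 1)
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        frac = pos - lo
        return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac

    detected = np.array([i + 2 for i in range(n - 1)] + [n])  # incl. filler gene
    detected_all = np.sort((counts >= 1).sum(axis=1))
    lo = quantile(detected_all, 0.025)
    hi = quantile(detected_all, 0.975)
    keep = [(c >= lo) and (c <= hi) for c in (counts >= 1).sum(axis=1)]
    assert out.n_obs == sum(keep)
    kept_ids = {f"c{i}" for i in range(n) if keep[i]}
    assert set(out.obs_names) == kept_ids


def test_filter_requires_four_cells():
    with pytest.raises(ValueError):
        pp.filter_cells(make_adata(np.ones((3, 2))))


def test_filter_output_is_subset_and_report_exact(filtered, sc_data):
    adata, _ = sc_data
    out, report = filtered
    assert set(out.obs_names) <= set(adata.obs_names)
    assert set(out.obs_names) | set(report["cell_id"]) == set(adata.obs_names)
    assert len(set(report["cell_id"]) & set(out.obs_names)) == 0


# ---------------------------------------------------------------------------
# modularity fold
# ---------------------------------------------------------------------------

def brute_force_fold(edges, n, members):
    """Edge-enumeration oracle for the observed/expected intra-set fold."""
    members = set(members)
    deg = np.zeros(n)
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    m = len(edges)
    observed = sum(1 for u, v in edges if u in members and v in members)
    d_s = sum(deg[list(members)])
    expected = d_s ** 2 / (4.0 * m)
    return observed / expected


def test_modularity_fold_matches_edge_enumeration_oracle():
    # 6-cell toy graph, expressing set = one triangle
    edges = [(0, 1), (1, 2), (0, 2), (2, 3), (3, 4), (4, 5), (3, 5)]
    n = 6
    a = sp.lil_matrix((n, n))
    for u, v in edges:
        a[u, v] = a[v, u] = 1
    fold = pp.modularity_fold(a.tocsr(), np.array([0, 1, 2]))
    oracle = brute_force_fold(edges, n, [0, 1, 2])
    assert abs(fold - oracle) < 1e-12


def test_uniformly_expressed_set_has_fold_one():
    rng = np.random.default_rng(0)
    coords = rng.normal(size=(50, 2))
    from fibrorhythm.graphs import knn_adjacency
    a = knn_adjacency(coords, 5)
    assert abs(pp.modularity_fold(a, np.arange(50)) - 1.0) < 1e-9


def test_planted_focal_genes_detected_as_megs(meg_table, sc_data):
    _, truth = sc_data
    focal = set(truth.marker_map.loc[truth.marker_map["kind"] == "focal", "gene"])
    megs = set(meg_table.loc[meg_table["is_meg"], "gene"])
    assert len(megs & focal) >= 0.8 * len(focal)
    assert len(megs - focal) == 0  # nothing else is spatially coherent


def test_empty_candidate_pool_warns():
    adata = make_adata(np.ones((20, 3)), coords=np.random.default_rng(0).normal(size=(20, 2)))
    with pytest.warns(UserWarning):
        out = pp.find_megs(adata, seed=0)
    assert len(out) == 0


# ---------------------------------------------------------------------------
# MEG gene distance
# ---------------------------------------------------------------------------

def emb(points: dict) -> pd.DataFrame:
    return pd.DataFrame(points, index=["x", "y"]).T


def test_distance_three_four_five_triangle():
    e = emb({"A": (0, 0), "B": (3, 4)})
    assert pp.meg_gene_distance(["A"], ["B"], e) == pytest.approx(5.0)


def test_distance_identical_singletons_is_zero():
    e = emb({"A": (1, 2)})
    assert pp.meg_gene_distance(["A"], ["A"], e) == 0.0


def test_distance_three_cell_case():
    e = emb({"A": (0, 0), "B": (0, 1), "C": (1, 0)})
    d = pp.meg_gene_distance(["A", "B"], ["C"], e, k=5)
    assert d == pytest.approx((1 + np.sqrt(2)) / 2)


def brute_force_distance(ids_i, ids_j, coords, k):
    """Double-loop oracle for the directed/symmetric MEG distance."""
    def directed(src, dst):
        acc, used = 0.0, 0
        for m in src:
            cand = [c for c in dst if c != m]
            if not cand:
                continue
            ds = sorted((np.hypot(coords[m][0] - coords[c][0],
                                  coords[m][1] - coords[c][1]), c) for c in cand)
            kk = min(k, len(cand))
            acc += np.mean([d for d, _ in ds[:kk]])
            used += 1
        return acc / used if used else None
    parts = [p for p in (directed(ids_i, ids_j), directed(ids_j, ids_i))
             if p is not None]
    return float(np.mean(parts)) if parts else 0.0


@pytest.mark.parametrize("trial", range(20))
def test_distance_matches_brute_force_oracle(trial):
    rng = np.random.default_rng(trial)
    n = rng.integers(2, 12)
    ids = [f"c{i}" for i in range(n)]
    coords = {c: tuple(rng.normal(size=2)) for c in ids}
    e = emb(coords)
    size_i = int(rng.integers(1, n + 1))
    size_j = int(rng.integers(1, n + 1))
    ec_i = list(rng.choice(ids, size=size_i, replace=False))
    ec_j = list(rng.choice(ids, size=size_j, replace=False))
    k = int(rng.integers(1, 7))
    got = pp.meg_gene_distance(ec_i, ec_j, e, k=k)
    want = brute_force_distance(ec_i, ec_j, coords, k)
    assert got == pytest.approx(want, abs=1e-10)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000), st.floats(0.1, 10), st.floats(-5, 5))
def test_distance_symmetry_translation_and_scaling(seed, scale, shift):
    rng = np.random.default_rng(seed)
    ids = [f"c{i}" for i in range(8)]
    pts = rng.normal(size=(8, 2))
    e = pd.DataFrame(pts, index=ids, columns=["x", "y"])
    ec_i, ec_j = ids[:4], ids[3:]
    d = pp.meg_gene_distance(ec_i, ec_j, e)
    d_rev = pp.meg_gene_distance(ec_j, ec_i, e)
    assert d == pytest.approx(d_rev)
    e2 = e * scale + shift
    assert pp.meg_gene_distance(ec_i, ec_j, e2) == pytest.approx(scale * d, rel=1e-9)


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def test_merge_never_splits_fine_clusters(filtered, merged_partition):
    adata, _ = filtered
    fine = adata.obs["fine_cluster"]
    df = pd.DataFrame({"fine": fine.to_numpy(),
                       "merged": merged_partition.to_numpy()})
    assert (df.groupby("fine")["merged"].nunique() == 1).all()


def test_merge_with_no_megs_gives_single_cluster(filtered):
    adata, _ = filtered
    out = pp.merge_fine_clusters(adata, adata.obs["fine_cluster"],
                                 pd.DataFrame())
    assert out.nunique() == 1


def test_merge_recovers_planted_clusters(merged_partition, filtered, sc_data):
    from sklearn.metrics import adjusted_rand_score
    adata, _ = filtered
    _, truth = sc_data
    ari = adjusted_rand_score(truth.cell_clusters.loc[adata.obs_names],
                              merged_partition)
    assert ari == 1.0
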