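"""Sign-alternation REG calling, significance windows, grouping and
differential rhythm."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from fibrorhythm import rhythm as rh


def make_timecourse(mean_profiles: dict, n_reps=2, conditions=("wt",),
                    spacing=12.0, seed=0, dispersion=0.02):
    """Counts + sheet from per-gene per-timepoint means."""
    rng = np.random.default_rng(seed)
    genes = list(mean_profiles)
    n_t = len(next(iter(mean_profiles.values())))
    cols, rows = {}, []
    for cond in conditions:
        for rep in range(1, n_reps + 1):
            for t in range(n_t):
                name = f"{cond}_R{rep}_T{t}"
                cols[name] = [
                    rng.negative_binomial(1 / dispersion,
                                          1 / (1 + dispersion * mean_profiles[g][t]))
                    for g in genes]
                rows.append({"sample": name, "condition": cond,
                             "replicate": rep, "timepoint_h": t * spacing})
    return pd.DataFrame(cols, index=genes), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# adjacent pairs
# ---------------------------------------------------------------------------

def test_constant_counts_give_zero_signs_and_high_fdr():
    genes = [f"g{i}" for i in range(30)]
    _, sheet = make_timecourse({g: [500] * 5 for g in genes})
    counts = pd.DataFrame(500, index=genes, columns=sheet["sample"])
    stats = rh.adjacent_pair_changes(counts, sheet)
    assert (stats.sign["wt"].to_numpy() == 0).all()
    assert (stats.fdr["wt"].to_numpy() > 0.95).all()


def test_alternating_means_give_alternating_signs():
    profiles = {"osc": [1000, 2000, 1000, 2000], "flat": [1500] * 4}
    counts, sheet = make_timecourse(profiles, dispersion=1e-6, seed=1)
    stats = rh.adjacent_pair_changes(counts, sheet)
    assert stats.sign["wt"].loc["osc"].tolist() == [1, -1, 1]


def test_single_replicate_is_an_error():
    profiles = {"g": [10] * 4}
    counts, sheet = make_timecourse(profiles, n_reps=1)
    with pytest.raises(ValueError):
        rh.adjacent_pair_changes(counts, sheet)


def test_sign_accuracy_on_planted_pairs(timecourse):
    """>= 99% of the planted alternating pair directions are recovered
    (well over 1000 planted pairs at the default configuration)."""
    counts, sheet, truth = timecourse
    stats = rh.adjacent_pair_changes(counts, sheet)
    planted = truth.rhythmic.set_index("gene")
    genes = planted.index[planted["rhythmic"]]
    signs = stats.sign["wt"].loc[genes].to_numpy()
    phase = planted.loc[genes, "phase"].to_numpy()
    n_pairs = signs.shape[1]
    expected = -phase[:, None] * (-1.0) ** np.arange(n_pairs)[None, :]
    assert signs.size >= 1000
    assert (signs == expected).mean() >= 0.99


# ---------------------------------------------------------------------------
# the REG rule vs exhaustive enumeration
# ---------------------------------------------------------------------------

def oracle_has_alternating_run(signs, need):
    """Window-by-window brute force over every start position."""
    n = len(signs)
    for start in range(n - need + 1):
        w = signs[start: start + need]
        if all(v != 0 for v in w) and all(w[i] == -w[i - 1] for i in range(1, need)):
            return True
    return False


def test_run_rule_equals_exhaustive_enumeration_up_to_length_10():
    for L in range(1, 11):
        for s in product((-1, 0, 1), repeat=L):
            got = rh.longest_alternating_run(s)[0] >= 6
            assert got == oracle_has_alternating_run(s, 6), s


@pytest.mark.parametrize("signs,expected", [
    ([1, -1, 1, -1, 1, -1, 1, -1], True),     # fully alternating
    ([1, 1, 1, 1, 1, 1, 1, 1], False),        # monotone
    ([1, -1, 1, -1, 1, 1, 1, -1], False),     # longest run only 4
    ([1, -1, 1, 0, -1, 1, -1, 1], False),     # zero breaks the run
])
def test_reg_rule_examples(signs, expected):
    assert (rh.longest_alternating_run(signs)[0] >= 6) == expected


def test_call_regs_flags_and_pattern_match(timecourse):
    counts, sheet, truth = timecourse
    stats = rh.adjacent_pair_changes(counts, sheet)
    regs = rh.call_regs(stats)
    planted = truth.rhythmic.set_index("gene")
    genes = planted.index[planted["rhythmic"]]
    assert regs.loc[genes, "reg_wt"].mean() >= 0.95
    both = regs["reg_wt"] & regs["reg_fl"]
    matches = regs.loc[both & regs.index.isin(genes), "pattern_match"]
    assert matches.astype(bool).all()  # damped, but same day-night pattern


# ---------------------------------------------------------------------------
# significance window
# ---------------------------------------------------------------------------

def _manual_pairstats(sign, fdr, fc):
    sign = pd.DataFrame([sign], index=["g"])
    return rh.PairStats(sign={"wt": sign},
                        fdr={"wt": pd.DataFrame([fdr], index=["g"])},
                        fold_change={"wt": pd.DataFrame([fc], index=["g"])},
                        log2fc={"wt": np.log2(pd.DataFrame([fc], index=["g"]))},
                        timepoints=np.arange(len(sign.columns) + 1) * 12.0,
                        spacing_h=12.0)


def test_reg_with_weak_fold_change_is_not_significant():
    stats = _manual_pairstats([1, -1, 1, -1, 1, -1, 1, -1],
                              [1e-6] * 8, [1.2, 1 / 1.2] * 4)
    regs = rh.significant_regs(rh.call_regs(stats), stats)
    assert bool(regs["reg_wt"].iloc[0])
    assert not bool(regs["significant_wt"].iloc[0])


def test_four_consecutive_strong_pairs_make_significance():
    fdr = [0.5, 0.5, 0.01, 0.01, 0.01, 0.01, 0.5, 0.5]
    fc = [2.0, 0.5] * 4
    stats = _manual_pairstats([1, -1, 1, -1, 1, -1, 1, -1], fdr, fc)
    regs = rh.significant_regs(rh.call_regs(stats), stats)
    assert bool(regs["significant_wt"].iloc[0])
    # significant implies REG
    assert bool(regs["reg_wt"].iloc[0])


def test_significant_subset_of_regs(timecourse):
    counts, sheet, _ = timecourse
    stats = rh.adjacent_pair_changes(counts, sheet)
    regs = rh.significant_regs(rh.call_regs(stats), stats)
    for cond in ("wt", "fl"):
        assert not (regs[f"significant_{cond}"] & ~regs[f"reg_{cond}"]).any()


def test_null_genes_rarely_significant(timecourse):
    counts, sheet, truth = timecourse
    stats = rh.adjacent_pair_changes(counts, sheet)
    regs = rh.significant_regs(rh.call_regs(stats), stats)
    null = truth.rhythmic.loc[~truth.rhythmic["rhythmic"], "gene"]
    rate = regs.loc[null, "significant_any"].mean()
    n = len(null)
    assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)


# ---------------------------------------------------------------------------
# pattern grouping
# ---------------------------------------------------------------------------

def test_orthogonal_archetypes_recovered_with_purity_one():
    rng = np.random.default_rng(0)
    archetypes = [
        [4000, 100, 100, 100, 4000, 100, 100, 100, 4000],
        [100, 4000, 100, 100, 100, 4000, 100, 100, 100],
        [100, 100, 4000, 100, 100, 100, 4000, 100, 100],
        [100, 100, 100, 4000, 100, 100, 100, 4000, 100],
    ]
    profiles, labels = {}, {}
    for a, arch in enumerate(archetypes):
        for i in range(100):
            g = f"a{a}_g{i}"
            profiles[g] = arch
            labels[g] = a
    counts, sheet = make_timecourse(profiles, seed=5)
    out = rh.classify_patterns(counts, sheet, list(profiles), k=4, seed=0)
    merged = out.assign(truth=[labels[g] for g in out["gene"]])
    purity = merged.groupby("group")["truth"] \
        .apply(lambda s: s.value_counts().iloc[0] / len(s))
    assert (purity == 1.0).all()


def test_pattern_group_count_is_configurable(timecourse):
    counts, sheet, truth = timecourse
    genes = truth.rhythmic.loc[truth.rhythmic["rhythmic"], "gene"]
    out = rh.classify_patterns(counts, sheet, genes, k=3, seed=0)
    assert out["group"].nunique() == 3
    with pytest.raises(ValueError):
        rh.classify_patterns(counts, sheet, genes[:2], k=4, seed=0)


def test_default_mixture_purity(timecourse):
    """Planted phase classes are not mixed within k-means groups."""
    counts, sheet, truth = timecourse
    planted = truth.rhythmic.set_index("gene")
    genes = planted.index[planted["rhythmic"]]
    out = rh.classify_patterns(counts, sheet, genes, seed=0)
    merged = out.assign(phase=planted.loc[out["gene"], "phase"].to_numpy())
    purity = merged.groupby("group")["phase"] \
        .apply(lambda s: s.value_counts().iloc[0] / len(s))
    total = (purity * merged.groupby("group").size()).sum() / len(merged)
    assert total >= 0.9


# ---------------------------------------------------------------------------
# differential rhythm
# ---------------------------------------------------------------------------

def test_identical_conditions_give_ratio_one_and_uniformish_p():
    rng = np.random.default_rng(3)
    profiles = {f"g{i}": list(rng.uniform(200, 2000, 5)) for i in range(60)}
    counts, sheet = make_timecourse(profiles, conditions=("wt", "fl"), seed=3)
    out = rh.differential_rhythm(counts, sheet, n_perm=200, seed=0)
    assert np.nanmedian(out["amplitude_ratio"]) == pytest.approx(1.0, abs=0.15)
    assert 0.3 < out["p_perm"].mean() < 0.7
    assert (out["p_perm"] < 0.05).mean() <= 0.1


def test_damped_mutant_detected_with_power(timecourse):
    counts, sheet, truth = timecourse
    genes = truth.rhythmic.loc[truth.rhythmic["rhythmic"], "gene"][:100]
    out = rh.differential_rhythm(counts, sheet, genes=genes, n_perm=500, seed=0)
    assert (out["p_perm"] < 0.05).mean() >= 0.8
    assert (out["amplitude_wt"] > out["amplitude_fl"]).mean() >= 0.9


def independent_exhaustive_oracle(blocks, n_a):
    """Re-enumeration of all within-timepoint label assignments with an
    independently coded amplitude statistic."""
    from itertools import combinations, product as iproduct

    def amp(profile):
        return float(np.mean(np.abs(np.diff(profile))))

    def stat(assignment):
        # blocks are (n_samples,) vectors per timepoint for one gene
        ma = [b[list(sel)].mean() for b, sel in zip(blocks, assignment)]
        mb = [b[[j for j in range(len(b)) if j not in sel]].mean()
              for b, sel in zip(blocks, assignment)]
        return amp(ma) - amp(mb)

    obs = stat([tuple(range(n_a))] * len(blocks))
    per_tp = list(combinations(range(len(blocks[0])), n_a))
    hits, total = 0, 0
    for assignment in iproduct(per_tp, repeat=len(blocks)):
        total += 1
        hits += abs(stat(list(assignment))) >= abs(obs) - 1e-12
    return hits / total


def test_permutation_p_matches_exhaustive_enumeration():
    profiles = {"g": [300, 900, 300]}
    counts, sheet = make_timecourse(profiles, conditions=("wt", "fl"), seed=9,
                                    dispersion=0.05)
    out = rh.differential_rhythm(counts, sheet, exhaustive=True)
    cpm = counts / counts.sum() * 1e6
    log = np.log2(cpm + 1.0)
    sh = sheet.set_index("sample")
    blocks = []
    for t in sorted(sh["timepoint_h"].unique()):
        cols = (sh.index[(sh["condition"] == "fl") & (sh["timepoint_h"] == t)])
        cols_a = sh.index[(sh["condition"] == "fl") & (sh["timepoint_h"] == t)]
        cols_b = sh.index[(sh["condition"] == "wt") & (sh["timepoint_h"] == t)]
        blocks.append(log.loc["g", list(cols_a) + list(cols_b)].to_numpy())
    oracle_p = independent_exhaustive_oracle(blocks, 2)
    assert out["p_perm"].iloc[0] == pytest.approx(oracle_p, abs=1e-12)


def test_mismatched_timepoints_error():
    profiles = {"g": [10, 10, 10]}
    counts, sheet = make_timecourse(profiles, conditions=("wt", "fl"))
    sheet = sheet[~((sheet["condition"] == "fl")
                    & (sheet["timepoint_h"] == 0.0))]
    counts = counts[sheet["sample"]]
    with pytest.raises(ValueError):
        rh.differential_rhythm(counts, sheet)
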