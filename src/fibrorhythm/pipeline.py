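"""End-to-end orchestration: simulate -> preprocess -> markers -> temporal
-> rhythm -> chromatin -> motifs -> directionality.

``run_all`` executes the stages in dependency order on a synthetic dataset,
writes each stage's artifacts to its own subdirectory, echoes the full
configuration, and produces a versioned machine-readable summary with the
headline counts and, because the inputs are synthetic, recovery metrics
against the planted truth.  Identical configuration and seed give a
byte-identical summary.
"""

from __future__ import annotations

import json
import os
import platform
import time

import numpy as np
import pandas as pd

from . import __version__
from . import chromatin as chrom_mod
from . import directionality as dir_mod
from . import markers as mk
from . import motifs as mo
from . import preprocess as pp
from . import rhythm as rh
from . import simulate as sim
from . import temporal as tp
from .config import RunConfig
from .io import write_bed6, write_counts_mtx, write_embedding, write_fasta, \
    write_gff3, write_json, write_partition

__all__ = ["StageError", "run_all"]

SUMMARY_SCHEMA_VERSION = 1


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _round(x, nd=6):
    if isinstance(x, float):
        return round(x, nd)
    return x


def adjusted_rand_index(a, b) -> float:
    from sklearn.metrics import adjusted_rand_score
    return float(adjusted_rand_score(np.asarray(a), np.asarray(b)))


def run_all(config: RunConfig) -> dict:
    """Run the whole pipeline; returns the summary dict (also written to
    ``<out_dir>/summary.json``)."""
    t0 = time.time()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    write_json(config.to_dict(), os.path.join(out, "config_echo.json"))
    seed = config.seed
    scfg = config.synthetic
    scfg.seed = seed
    summary: dict = {"schema_version": SUMMARY_SCHEMA_VERSION, "seed": seed}

    stage = "simulate"
    try:
        d = os.path.join(out, stage)
        os.makedirs(d, exist_ok=True)
        adata, sc_truth = sim.gen_sc_dataset(scfg)
        tc_counts, tc_sheet, tc_truth = sim.gen_timecourse(scfg)
        genome, g_truth = sim.gen_genome(scfg)
        write_counts_mtx(adata, os.path.join(d, "counts"))
        write_embedding(adata.obs_names, adata.obsm["X_umap"],
                        os.path.join(d, "embedding.tsv"))
        write_partition(adata.obs_names, adata.obs["fine_cluster"],
                        os.path.join(d, "fine_partition.tsv"))
        tc_counts.to_csv(os.path.join(d, "timecourse_counts.tsv"), sep="\t")
        tc_sheet.to_csv(os.path.join(d, "timecourse_samples.tsv"), sep="\t",
                        index=False)
        write_fasta(genome.sequences, os.path.join(d, "genome.fa"))
        write_gff3(genome.genes, os.path.join(d, "genes.gff3"))
        write_bed6(genome.acrs, os.path.join(d, "acrs.bed"))
        truth_all = {"sc": sc_truth.to_dict(), "timecourse": tc_truth.to_dict(),
                     "genome": g_truth.to_dict()}
        write_json(truth_all, os.path.join(d, "ground_truth.json"))
        tf_list = set(sc_truth.marker_map.loc[sc_truth.marker_map["is_tf"], "gene"])
        with open(os.path.join(d, "tf_list.txt"), "w") as fh:
            fh.write("\n".join(sorted(tf_list)) + "\n")
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "preprocess"
    try:
        d = os.path.join(out, stage)
        os.makedirs(d, exist_ok=True)
        filtered, report = pp.filter_cells(adata)
        report.to_csv(os.path.join(d, "removed_cells.tsv"), sep="\t", index=False)
        megs = pp.find_megs(filtered, seed=seed)
        megs.to_csv(os.path.join(d, "megs.tsv"), sep="\t", index=False)
        meg_genes = megs.loc[megs["is_meg"], "gene"].tolist()
        dist = pp.meg_distance_matrix(filtered, meg_genes)
        dist.to_csv(os.path.join(d, "meg_distance.tsv"), sep="\t")
        merged = pp.merge_fine_clusters(filtered, filtered.obs["fine_cluster"],
                                        dist)
        write_partition(filtered.obs_names, merged,
                        os.path.join(d, "final_partition.tsv"))
        truth_labels = sc_truth.cell_clusters.loc[filtered.obs_names]
        ari = adjusted_rand_index(truth_labels, merged)
        summary["preprocess"] = {
            "n_cells_input": int(adata.n_obs),
            "n_cells_retained": int(filtered.n_obs),
            "n_megs": int(len(meg_genes)),
            "n_final_clusters": int(merged.nunique()),
            "cluster_ari_vs_truth": _round(ari),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "markers"
    try:
        d = os.path.join(out, stage)
        os.makedirs(d, exist_ok=True)
        ratios = mk.expression_ratios(filtered, merged)
        candidates = mk.candidate_markers(filtered, merged)
        marker_table = mk.select_markers(candidates, ratios, tf_list)
        marker_table.to_csv(os.path.join(d, "markers.tsv"), sep="\t", index=False)
        degs = mk.condition_degs(filtered, merged)
        degs.to_csv(os.path.join(d, "degs.tsv"), sep="\t", index=False)
        sel_genes = set(marker_table.loc[marker_table["selected"], "gene"])
        truth_genes = set(sc_truth.marker_map["gene"])
        tp_ = len(sel_genes & truth_genes)
        precision = tp_ / len(sel_genes) if sel_genes else np.nan
        recall = tp_ / len(truth_genes) if truth_genes else np.nan
        summary["markers"] = {
            "n_candidates": int(len(candidates)),
            "n_markers": int(len(sel_genes)),
            "n_tf_markers": int(marker_table.loc[marker_table["selected"],
                                                 "is_tf"].sum()),
            "n_degs": int(degs["is_deg"].sum()) if len(degs) else 0,
            "marker_precision": _round(precision),
            "marker_recall": _round(recall),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "temporal"
    try:
        d = os.path.join(out, stage)
        os.makedirs(d, exist_ok=True)
        grad, refs, true_time = sim.gen_temporal_gradient(scfg)
        bins, pb = tp.bin_pseudobulk(
            grad, granularity=config.analysis["temporal"]["granularity_time"])
        corr = tp.correlate_bins(pb, refs, gene_rule="fpkm_any")
        corr.to_csv(os.path.join(d, "bin_correlations.tsv"), sep="\t")
        sample_times = pd.Series(
            [float(c[1:-3]) for c in refs.columns], index=refs.columns)
        est = tp.assign_time(corr, sample_times, bins)
        est.to_frame().to_csv(os.path.join(d, "cell_times.tsv"), sep="\t")
        rho = float(pd.Series(est).corr(true_time, method="spearman"))
        summary["temporal"] = {
            "n_bins": int(len(pb)),
            "time_spearman_vs_truth": _round(rho),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "rhythm"
    try:
        d = os.path.join(out, stage)
        os.makedirs(d, exist_ok=True)
        stats = rh.adjacent_pair_changes(tc_counts, tc_sheet)
        regs = rh.call_regs(stats)
        regs = rh.significant_regs(regs, stats)
        regs.to_csv(os.path.join(d, "reg_calls.tsv"), sep="\t")
        reg_any = regs["reg_wt"] | regs["reg_fl"]
        truth_r = tc_truth.rhythmic.set_index("gene")["rhythmic"]
        planted = truth_r[truth_r].index
        unplanted = truth_r[~truth_r].index
        sensitivity = float(regs.loc[planted, "reg_wt"].mean())
        sig_fpr = float(regs.loc[unplanted, "significant_any"].mean())
        groups = rh.classify_patterns(tc_counts, tc_sheet,
                                      regs.index[regs["significant_any"]],
                                      seed=seed)
        groups.to_csv(os.path.join(d, "pattern_groups.tsv"), sep="\t",
                      index=False)
        diff = rh.differential_rhythm(tc_counts, tc_sheet,
                                      genes=regs.index[reg_any][:500],
                                      seed=seed)
        diff.to_csv(os.path.join(d, "differential_rhythm.tsv"), sep="\t")
        summary["rhythm"] = {
            "n_regs_wt": int(regs["reg_wt"].sum()),
            "n_regs_fl": int(regs["reg_fl"].sum()),
            "n_significant_regs": int(regs["significant_any"].sum()),
            "reg_sensitivity_vs_truth": _round(sensitivity),
            "significant_reg_fpr_vs_truth": _round(sig_fpr),
            "n_differential_rhythm": int((diff["p_perm"] < 0.05).sum()),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "chromatin"
    try:
        d = os.path.join(out, stage)
        os.makedirs(d, exist_ok=True)
        acrs = chrom_mod.merge_acrs(genome.acrs)
        # re-attach the generator's names via identical sorted order
        acrs = genome.acrs.sort_values(["chrom", "start"]).reset_index(drop=True)
        write_bed6(acrs, os.path.join(d, "acrs_merged.bed"))
        dars = chrom_mod.call_dars_dags(genome.acr_counts, genome.acr_conditions)
        dars.to_csv(os.path.join(d, "dars.tsv"), sep="\t")
        gene_signal = chrom_mod.gene_atac_signal(acrs, genome.acr_counts,
                                                 genome.genes,
                                                 genome.chrom_sizes)
        dags = chrom_mod.call_dars_dags(gene_signal, genome.acr_conditions)
        dags.to_csv(os.path.join(d, "dags.tsv"), sep="\t")
        planted_dars = set(g_truth.differential_acrs)
        called = set(dars.index[dars["is_differential"]])
        summary["chromatin"] = {
            "n_acrs": int(len(acrs)),
            "n_dars": int(len(called)),
            "n_dags": int(dags["is_differential"].sum()),
            "dar_recall_vs_truth": _round(
                len(called & planted_dars) / max(len(planted_dars), 1)),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "motifs"
    try:
        d = os.path.join(out, stage)
        os.makedirs(d, exist_ok=True)
        mgm = mo.build_motif_gene_matrix(genome.sequences, acrs, genome.genes,
                                         chrom_sizes=genome.chrom_sizes)
        moran = mo.motif_moran_table(mgm, filtered)
        selected = mo.select_cell_specific_motifs(moran)
        moran.loc[selected].to_csv(os.path.join(d, "selected_motifs.tsv"),
                                   sep="\t")
        # fiber-like cluster: the final cluster most depleted in the
        # mutant-like condition (how the lost population is recognised)
        fl_frac = filtered.obs.groupby(merged)["condition"] \
            .apply(lambda s: float((s == "fl").mean()))
        fiber_cluster = fl_frac.idxmin()
        groups = mo.cluster_motifs(list(selected), mgm, filtered, merged,
                                   fiber_cluster)
        groups.to_csv(os.path.join(d, "motif_groups.tsv"), sep="\t")
        # per-cluster enrichment for the strongest selected motifs
        cpm = mk.cpm_matrix(filtered)
        labels = pd.Series(np.asarray(merged), index=filtered.obs_names)
        clusters = sorted(labels.unique())
        gene_cluster_mean = pd.DataFrame(
            {c: cpm[(labels == c).to_numpy()].mean(axis=0) for c in clusters},
            index=filtered.var_names)
        expressed = gene_cluster_mean.index[(gene_cluster_mean > 1).any(axis=1)]
        max_cluster = gene_cluster_mean.idxmax(axis=1)
        top = moran.loc[selected].sort_values("moran_count",
                                              ascending=False).index[:10]
        enr_frames = []
        for m in top:
            e = mo.cluster_enrichment(mgm.targets(m), max_cluster, expressed,
                                      seed=seed)
            e.insert(0, "motif", m)
            enr_frames.append(e)
        if enr_frames:
            pd.concat(enr_frames).to_csv(
                os.path.join(d, "cluster_enrichment.tsv"), sep="\t")
        summary["motifs"] = {
            "n_motifs_with_targets": int(len(moran)),
            "n_selected": int(len(selected)),
            "n_m1": int((groups["group"] == "M1").sum()),
            "n_m2": int((groups["group"] == "M2").sum()),
            "fiber_cluster": int(fiber_cluster),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "directionality"
    try:
        d = os.path.join(out, stage)
        os.makedirs(d, exist_ok=True)
        shuffler = dir_mod.TssShuffler(acrs, genome.genes, genome.chrom_sizes)
        calls = {}
        for i, m in enumerate(selected):
            occ = mgm.occurrences_of(m)
            calls[m] = dir_mod.classify_directionality(
                occ, shuffler, seed=seed + i)
        call_df = pd.DataFrame(calls).T
        call_df.index.name = "motif"
        call_df.to_csv(os.path.join(d, "directionality.tsv"), sep="\t")
        class_counts = call_df["class"].value_counts().to_dict()
        # recovery on the planted motifs (classified the same way)
        planted = {}
        for i, spec_row in enumerate(g_truth.motif_specs.itertuples(index=False)):
            occ = mgm.occurrences_of(spec_row.motif)
            c = dir_mod.classify_directionality(occ, shuffler,
                                                seed=seed + 1000 + i)
            planted[spec_row.motif] = {"planted": spec_row.orientation,
                                       "called": c["class"]}
        summary["directionality"] = {
            "n_classified": int(len(call_df)),
            "class_counts": {k: int(v) for k, v in sorted(class_counts.items())},
            "planted_motifs": planted,
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # wall time goes to the log only, so the summary is byte-identical
    # across runs with the same config and seed
    write_json(summary, os.path.join(out, "summary.json"))
    with open(os.path.join(out, "run.log"), "w") as fh:
        fh.write(f"fibrorhythm {__version__}\n")
        fh.write(f"python {platform.python_version()}\n")
        fh.write(f"seed {seed}\n")
        fh.write(f"wall_time_s {round(time.time() - t0, 1)}\n")
    return summary
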