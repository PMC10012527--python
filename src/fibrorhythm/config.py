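"""Configuration objects for the fibrorhythm pipeline.

Two kinds of configuration live here:

* :class:`SyntheticConfig` — parameters of the synthetic data generators
  (cell numbers, planted effect sizes, genome layout).
* :data:`ANALYSIS_DEFAULTS` — the fixed analysis cutoffs of the pipeline.
  Every printed threshold of the published analysis is registered here once
  and read by the analysis modules, so that a run can echo the exact
  numerical contract it executed under.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import yaml

__all__ = [
    "SyntheticConfig",
    "PlantedMotif",
    "RunConfig",
    "ANALYSIS_DEFAULTS",
    "load_config",
]


# ---------------------------------------------------------------------------
# Fixed analysis cutoffs.
# ---------------------------------------------------------------------------
#: Numerical contract of the analysis stages.  These are constants of the
#: method, not tunables; modules import them as defaults so that the echoed
#: configuration of a run is authoritative.
ANALYSIS_DEFAULTS: dict = {
    # cell quality filters
    "cell_filter": {
        "umi_rule": "total > median + 2*MAD removed",
        "umi_mad_factor": 2.0,
        "gene_quantile_low": 0.025,
        "gene_quantile_high": 0.975,
        "detected_umi_min": 1,
        "expressed_umi_min": 2,
    },
    # modularity-enriched genes
    "meg": {
        "graph_k": 25,
        "candidate_min_cells": 100,
        "candidate_max_cell_fraction": 0.5,
        "fold_over_background": 10.0,
        "n_background": 100,
        "distance_knn_k": 5,
        "merge_linkage": "complete",
        "merge_n_groups": 4,
        "merge_ratio_floor": 0.1,
    },
    # marker genes
    "markers": {
        "candidate_fdr": 1e-9,
        "candidate_fold_change": 2.0,
        "ratio_min_own": 0.01,
        "ratio_own_over_other": 1.5,
        "ratio_max_other": 0.1,
        "deg_fdr": 0.05,
        "deg_fold_change": 2.0,
    },
    # pseudo-bulk temporal mapping
    "temporal": {
        "granularity_identity": 0.5,
        "granularity_time": 0.2,
        "correlation": "spearman",
    },
    # rhythmic gene calling
    "rhythm": {
        "reg_window_h": 72.0,
        "significant_window_h": 48.0,
        "pair_fdr": 0.05,
        "pair_fold_change": 1.5,
        "n_pattern_groups": 4,
    },
    # chromatin accessibility
    "chromatin": {
        "promoter_bp": 1000,
        "dar_fold_change": 2.0,
        "dar_p": 0.01,
        "norm_per": 10_000,
    },
    # k-mer motif discovery
    "motifs": {
        "k": 8,
        "moran_graph_k": 25,
        "top_fraction": 0.05,
        "cluster_linkage": "ward.D2",
        "cluster_metric": "euclidean",
        "obs_exp_high": 1.5,
        "obs_exp_low": 0.67,
        "enrichment_p": 0.05,
        "n_random_controls": 10_000,
        "expressed_cpm": 1.0,
    },
    # TSS directionality
    "directionality": {
        "n_shuffles": 100,
        "sd_factor": 2.0,
        "mad_scaling": "raw",
    },
}


@dataclass(frozen=True)
class PlantedMotif:
    """A ground-truth 8-mer planted into ACR sequence.

    ``orientation`` is one of ``forward``, ``reverse``, ``both`` (half of the
    target genes get each orientation) or ``uniform`` (placed uniformly over
    ACR positions with no TSS preference, serving as a null motif).
    Distances are signed gene-frame distances of the occurrence midpoint to
    the TSS (negative = upstream).
    """

    sequence: str
    orientation: str = "forward"
    n_target_genes: int = 140
    distance_mean: float = -50.0
    distance_sd: float = 20.0

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"motif sequence must be ACGT only: {self.sequence}")
        if self.orientation not in {"forward", "reverse", "both", "uniform"}:
            raise ValueError(f"unknown orientation {self.orientation!r}")


def _default_motifs() -> tuple:
    return (
        PlantedMotif("TGGGCCTA", "forward", 140, -50.0, 20.0),
        PlantedMotif("TAGGGCTA", "forward", 140, -80.0, 25.0),
        PlantedMotif("ACGGTCAT", "both", 140, -60.0, 20.0),
        PlantedMotif("TTGACCGA", "reverse", 140, -50.0, 20.0),
        PlantedMotif("GATCGGTA", "uniform", 140, 0.0, 0.0),
    )


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic data generators.

    The defaults describe the study conditions the pipeline is designed for:
    two conditions (a wild-type-like sample with five cell populations and a
    mutant-like sample lacking the fiber-like population), a 2 condition x
    2 replicate x 9 timepoint diurnal series at 12-h spacing, and a toy
    two-chromosome genome carrying promoter/gene-body ACRs with planted
    8-mers at controlled TSS distances.
    """

    # --- single-cell dataset -------------------------------------------------
    n_genes: int = 2000
    n_cells_wt: int = 1500
    n_cells_fl: int = 1500
    n_clusters: int = 5
    missing_cluster_in_fl: int = 3
    markers_per_cluster: int = 40
    marker_fold: float = 8.0
    nb_dispersion: float = 0.5

    #: cluster composition of the WT-like condition; the last cluster is the
    #: dominant population without planted markers (no-MEG population).
    cluster_props_wt: Sequence[float] = (0.17, 0.17, 0.17, 0.18, 0.31)

    #: per cluster, how many of ``markers_per_cluster`` are "focal" on/off
    #: genes expressed in a contiguous patch of the embedding (these drive
    #: MEG detection); the remainder are "broad" whole-cluster markers with
    #: out-of-cluster mean = in-cluster mean / marker_fold.
    focal_markers_per_cluster: int = 10
    #: mean expression of a broad marker outside its cluster; in-cluster mean
    #: is marker_fold times this.
    broad_marker_base_mean: float = 0.06
    #: out-of-cluster leak mean of focal on/off markers.
    focal_off_mean: float = 0.004
    #: steepness of the focal on/off response: on = off * fold**exponent.
    focal_exponent: float = 3.55
    #: number of expressing cells targeted by a focal gene's spatial patch
    #: (sized so the patch stays above the 100-cell candidate floor after
    #: the ~20% attrition of the quality filters, while keeping the
    #: expressing set compact enough for a strong modularity fold).
    focal_patch_cells: int = 170
    #: genes with a condition-specific (WT-enriched) shift in one cluster.
    n_condition_degs: int = 25
    condition_deg_fold: float = 4.0
    condition_deg_cluster: int = 0
    #: log-normal parameters of background gene means (natural-log space).
    background_log_mean: float = -1.39
    background_log_sd: float = 1.0
    #: log-normal sigma of per-cell library size factors (UMI depth spread).
    library_size_sd: float = 0.35

    # --- diurnal time course -------------------------------------------------
    n_timepoints: int = 9
    timepoint_spacing_h: float = 12.0
    n_replicates: int = 2
    n_rhythmic: int = 200
    rhythm_fold: float = 3.0
    #: multiplier on the mutant's log-amplitude (1.0 = no damping).
    fl_rhythm_damping: float = 0.5
    #: NB dispersion of bulk replicate noise (much lower than single-cell).
    timecourse_dispersion: float = 0.05
    timecourse_log_mean: float = 5.3
    timecourse_log_sd: float = 0.8

    # --- toy genome ----------------------------------------------------------
    n_chromosomes: int = 2
    chromosome_length: int = 500_000
    planted_motifs: Sequence[PlantedMotif] = field(default_factory=_default_motifs)
    #: fraction of genes that also carry a gene-body ACR.
    gene_body_acr_fraction: float = 0.5
    n_atac_cells_per_condition: int = 200
    n_differential_acrs: int = 100
    differential_acr_fold: float = 4.0

    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_cells_wt": self.n_cells_wt,
            "n_cells_fl": self.n_cells_fl,
            "n_clusters": self.n_clusters,
            "markers_per_cluster": self.markers_per_cluster,
            "n_timepoints": self.n_timepoints,
            "n_replicates": self.n_replicates,
            "n_chromosomes": self.n_chromosomes,
            "chromosome_length": self.chromosome_length,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not (0 <= self.missing_cluster_in_fl < self.n_clusters):
            raise ValueError("missing_cluster_in_fl must index a cluster")
        if self.marker_fold <= 0 or self.nb_dispersion <= 0:
            raise ValueError("marker_fold and nb_dispersion must be positive")
        if len(self.cluster_props_wt) != self.n_clusters:
            raise ValueError("cluster_props_wt must have n_clusters entries")
        if abs(sum(self.cluster_props_wt) - 1.0) > 1e-9:
            raise ValueError("cluster_props_wt must sum to 1")
        if self.focal_markers_per_cluster > self.markers_per_cluster:
            raise ValueError("focal_markers_per_cluster exceeds markers_per_cluster")
        span = self.timepoint_spacing_h * (self.n_timepoints - 1)
        if span < 96.0:
            raise ValueError(
                "time course must span at least 96 h so the 72-h rhythm window "
                f"is testable (got {span} h)"
            )
        seqs = [m.sequence for m in self.planted_motifs]
        if len(set(seqs)) != len(seqs):
            raise ValueError("planted motif sequences must be distinct")

    # -- serialisation -------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted_motifs"] = [dataclasses.asdict(m) for m in self.planted_motifs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        motifs = d.pop("planted_motifs", None)
        cfg = cls(**{k: v for k, v in d.items()})
        if motifs is not None:
            object.__setattr__  # noqa: B018 -- dataclass is mutable, plain set ok
            cfg.planted_motifs = tuple(PlantedMotif(**m) for m in motifs)
        return cfg


@dataclass
class RunConfig:
    """End-to-end pipeline run configuration (simulate -> ... -> direction)."""

    seed: int = 0
    out_dir: str = "fibrorhythm_run"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    analysis: dict = field(default_factory=lambda: json.loads(json.dumps(ANALYSIS_DEFAULTS)))

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "synthetic": self.synthetic.to_dict(),
            "analysis": self.analysis,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {"seed", "out_dir", "synthetic", "analysis"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls()
        if "seed" in d:
            cfg.seed = int(d["seed"])
        if "out_dir" in d:
            cfg.out_dir = str(d["out_dir"])
        if "synthetic" in d:
            syn = d["synthetic"]
            default = SyntheticConfig().to_dict()
            unknown = set(syn) - set(default)
            if unknown:
                raise ValueError(f"unknown synthetic config keys: {sorted(unknown)}")
            cfg.synthetic = SyntheticConfig.from_dict(syn)
        if "analysis" in d:
            base = json.loads(json.dumps(ANALYSIS_DEFAULTS))
            for section, values in d["analysis"].items():
                if section not in base:
                    raise ValueError(f"unknown analysis section {section!r}")
                unknown = set(values) - set(base[section])
                if unknown:
                    raise ValueError(
                        f"unknown analysis keys in {section}: {sorted(unknown)}"
                    )
                base[section].update(values)
            cfg.analysis = base
        return cfg


def load_config(path: str) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)
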