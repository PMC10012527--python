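"""Synthetic data generators with planted ground truth.

Every pipeline input can be generated here with the statistical structure
the analysis assumes, so each downstream stage is testable against a known
answer without external downloads:

* :func:`gen_sc_dataset` — a two-condition UMI count matrix with five cell
  populations (one absent from the mutant-like condition), a blob embedding,
  an over-split fine partition and planted marker genes.
* :func:`gen_timecourse` — a replicated diurnal bulk count table with
  planted alternating-sign rhythmic genes.
* :func:`gen_genome` — a toy two-chromosome genome with annotated genes,
  promoter and gene-body ACRs, per-cell ACR counts, and 8-mers planted at
  controlled TSS distances and orientations.
* :func:`gen_temporal_gradient` — cells interpolating a time-labelled
  reference expression series, for temporal-mapping recovery tests.

Counts are negative binomial (mean ``mu``, dispersion ``alpha``, variance
``mu + alpha*mu**2``).  Each generator draws from its own RNG stream derived
from the master seed by a fixed offset, so generators can be called
independently and reproducibly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import SyntheticConfig

__all__ = [
    "GroundTruth",
    "GenomeData",
    "gen_sc_dataset",
    "gen_timecourse",
    "gen_genome",
    "gen_temporal_gradient",
    "nb_sample",
]

_SC_STREAM = 11
_TC_STREAM = 22
_GENOME_STREAM = 33
_GRADIENT_STREAM = 44

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def nb_sample(rng: np.random.Generator, mean, dispersion: float):
    """Negative-binomial draw with mean/dispersion parameterisation."""
    mean = np.asarray(mean, dtype=float)
    r = 1.0 / dispersion
    p = 1.0 / (1.0 + dispersion * mean)
    return rng.negative_binomial(r, p, size=mean.shape)


def _nb_p_expressed(mean: float, dispersion: float) -> float:
    """P(count >= 1) under the NB model."""
    return 1.0 - (1.0 + dispersion * mean) ** (-1.0 / dispersion)


@dataclass
class GroundTruth:
    """Planted truth of a synthetic dataset (sections filled per generator)."""

    cell_clusters: pd.Series | None = None
    marker_map: pd.DataFrame | None = None          # gene, cluster, kind
    condition_degs: pd.DataFrame | None = None      # gene, cluster, fold
    rhythmic: pd.DataFrame | None = None            # gene, rhythmic, phase
    motif_plants: pd.DataFrame | None = None        # motif, gene, distance, orientation
    motif_specs: pd.DataFrame | None = None         # motif-level plan
    acr_gene: pd.DataFrame | None = None            # acr_id, gene_id (intended)
    differential_acrs: pd.Series | None = None

    def to_dict(self) -> dict:
        out: dict = {}
        if self.cell_clusters is not None:
            out["cell_clusters"] = {str(k): int(v) for k, v in self.cell_clusters.items()}
        if self.marker_map is not None:
            out["marker_map"] = self.marker_map.to_dict(orient="records")
        if self.condition_degs is not None:
            out["condition_degs"] = self.condition_degs.to_dict(orient="records")
        if self.rhythmic is not None:
            out["rhythmic"] = self.rhythmic.to_dict(orient="records")
        if self.motif_plants is not None:
            out["motif_plants"] = self.motif_plants.to_dict(orient="records")
        if self.motif_specs is not None:
            out["motif_specs"] = self.motif_specs.to_dict(orient="records")
        if self.acr_gene is not None:
            out["acr_gene"] = self.acr_gene.to_dict(orient="records")
        if self.differential_acrs is not None:
            out["differential_acrs"] = list(map(str, self.differential_acrs))
        return out


# ---------------------------------------------------------------------------
# single-cell dataset
# ---------------------------------------------------------------------------

def _cluster_proportions(config: SyntheticConfig, condition: str) -> np.ndarray:
    props = np.asarray(config.cluster_props_wt, dtype=float).copy()
    if condition == "fl":
        lost = props[config.missing_cluster_in_fl]
        props[config.missing_cluster_in_fl] = 0.0
        props[-1] += lost  # reallocated to the dominant background population
    return props


def _exact_counts(props: np.ndarray, n: int) -> np.ndarray:
    """Deterministic integer split of n cells by proportions."""
    counts = np.floor(props * n).astype(int)
    rema = props * n - counts
    for i in np.argsort(-rema)[: n - counts.sum()]:
        counts[i] += 1
    return counts


def gen_sc_dataset(config: SyntheticConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Generate the two-condition UMI matrix, embedding and fine partition.

    Planted structure: ``n_clusters`` Gaussian blobs on the embedding, the
    last one a dominant population without planted markers; each of the
    other clusters carries ``markers_per_cluster`` marker genes, split into
    switch-like "focal" genes expressed in a contiguous spatial patch
    (these are what a modularity-enrichment scan can find) and "broad"
    markers whose out-of-cluster mean is 1/``marker_fold`` of the in-cluster
    mean.  The mutant-like condition has zero cells in
    ``missing_cluster_in_fl``.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, _SC_STREAM])
    n_clusters = cfg.n_clusters

    # --- cells and cluster labels -------------------------------------
    parts = []
    for condition, n_cells in (("wt", cfg.n_cells_wt), ("fl", cfg.n_cells_fl)):
        counts = _exact_counts(_cluster_proportions(cfg, condition), n_cells)
        labels = np.repeat(np.arange(n_clusters), counts)
        labels = rng.permutation(labels)
        ids = [f"{condition.upper()}_{i:05d}" for i in range(n_cells)]
        parts.append(pd.DataFrame({"cell_id": ids, "condition": condition,
                                   "true_cluster": labels}))
    obs = pd.concat(parts, ignore_index=True).set_index("cell_id")
    obs["batch"] = rng.choice(["v2", "v3"], size=len(obs))
    n_cells = len(obs)
    labels = obs["true_cluster"].to_numpy()

    # --- embedding: one blob per cluster ------------------------------
    centers = np.zeros((n_clusters, 2))
    sds = np.full(n_clusters, 0.8)
    angles = 2 * np.pi * np.arange(n_clusters - 1) / (n_clusters - 1)
    centers[:-1, 0] = 8.0 * np.cos(angles)
    centers[:-1, 1] = 8.0 * np.sin(angles)
    sds[-1] = 1.5  # dominant central population
    coords = centers[labels] + rng.normal(size=(n_cells, 2)) * sds[labels][:, None]

    # --- gene programme -------------------------------------------------
    genes = np.array([f"G{i:04d}" for i in range(cfg.n_genes)])
    marker_clusters = list(range(n_clusters - 1))
    marker_idx = _marker_indices(cfg)
    marker_rows = []
    base_means = rng.lognormal(cfg.background_log_mean, cfg.background_log_sd,
                               size=cfg.n_genes)
    # per-cluster mean matrix for broad structure
    cluster_means = np.tile(base_means, (n_clusters, 1))

    focal_on = cfg.focal_off_mean * cfg.marker_fold ** cfg.focal_exponent
    broad_on = cfg.broad_marker_base_mean * cfg.marker_fold
    p_on = _nb_p_expressed(focal_on, cfg.nb_dispersion)
    focal_cells: dict[int, np.ndarray] = {}

    pos = 0
    for c in marker_clusters:
        gene_block = marker_idx[pos: pos + cfg.markers_per_cluster]
        pos += cfg.markers_per_cluster
        focal_block = gene_block[: cfg.focal_markers_per_cluster]
        broad_block = gene_block[cfg.focal_markers_per_cluster:]
        cluster_means[:, broad_block] = cfg.broad_marker_base_mean
        cluster_means[c, broad_block] = broad_on
        cluster_means[:, focal_block] = cfg.focal_off_mean
        # focal genes get a per-cell patch, assigned below
        for g in focal_block:
            marker_rows.append({"gene": genes[g], "cluster": c, "kind": "focal"})
        for g in broad_block:
            marker_rows.append({"gene": genes[g], "cluster": c, "kind": "broad"})
        # spatial patches: nearest cells around a random anchor in the blob
        cluster_cells = np.flatnonzero(labels == c)
        n_patch = min(len(cluster_cells),
                      int(round(cfg.focal_patch_cells / max(p_on, 1e-9))))
        for g in focal_block:
            anchor = rng.choice(cluster_cells)
            d = np.linalg.norm(coords[cluster_cells] - coords[anchor], axis=1)
            patch = cluster_cells[np.argsort(d, kind="stable")[:n_patch]]
            focal_cells[g] = patch

    marker_map = pd.DataFrame(marker_rows, columns=["gene", "cluster", "kind"])
    # every fifth marker is tagged as a transcription factor, mirroring the
    # TF/non-TF split the marker-selection rules distinguish
    marker_map["is_tf"] = np.arange(len(marker_map)) % 5 == 0

    # condition-specific genes: WT-enriched shift in one cluster (these are
    # what the per-cluster WT-vs-mutant differential test should recover)
    non_marker = np.setdiff1d(np.arange(cfg.n_genes), marker_idx)
    deg_idx = rng.choice(non_marker, size=min(cfg.n_condition_degs,
                                              non_marker.size), replace=False)

    # --- counts ---------------------------------------------------------
    mean_matrix = cluster_means[labels]  # cells x genes view-copy
    for g, patch in focal_cells.items():
        mean_matrix[patch, g] = focal_on
    wt_in_deg_cluster = ((obs["condition"] == "wt").to_numpy()
                         & (labels == cfg.condition_deg_cluster))
    mean_matrix[np.ix_(wt_in_deg_cluster, deg_idx)] *= cfg.condition_deg_fold
    # per-cell library size factors: depth varies between cells far more
    # than any biological programme shifts a cell's total
    size_factors = rng.lognormal(0.0, cfg.library_size_sd, size=n_cells)
    mean_matrix = mean_matrix * size_factors[:, None]
    counts = nb_sample(rng, mean_matrix, cfg.nb_dispersion).astype(np.int32)
    x = sp.csr_matrix(counts)

    adata = ad.AnnData(X=x, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene_id")))
    adata.obsm["X_umap"] = coords

    # --- over-split fine partition (2-3 spatial slices per blob) -------
    fine = np.full(n_cells, -1)
    next_label = 0
    subs_cycle = [2, 2, 3, 2, 3]
    for c in range(n_clusters):
        cells_c = np.flatnonzero(labels == c)
        if len(cells_c) == 0:
            continue
        n_sub = subs_cycle[c % len(subs_cycle)]
        theta = np.arctan2(coords[cells_c, 1] - centers[c, 1],
                           coords[cells_c, 0] - centers[c, 0])
        edges = np.quantile(theta, np.linspace(0, 1, n_sub + 1)[1:-1])
        sub = np.searchsorted(edges, theta, side="right")
        fine[cells_c] = next_label + sub
        next_label += n_sub
    adata.obs["fine_cluster"] = fine

    truth = GroundTruth(
        cell_clusters=pd.Series(labels, index=adata.obs_names, name="true_cluster"),
        marker_map=marker_map,
        condition_degs=pd.DataFrame({
            "gene": genes[deg_idx],
            "cluster": cfg.condition_deg_cluster,
            "fold": cfg.condition_deg_fold,
        }),
    )
    return adata, truth


# ---------------------------------------------------------------------------
# diurnal time course
# ---------------------------------------------------------------------------

def gen_timecourse(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Replicated two-condition diurnal count table.

    Rhythmic genes alternate between ``base*sqrt(fold)`` and
    ``base/sqrt(fold)`` at adjacent timepoints (phase +1 starts high);
    the mutant-like condition's log-amplitude is multiplied by
    ``fl_rhythm_damping``.  Non-rhythmic genes are constant or drift
    monotonically.  Returns (counts, sample sheet, truth).
    """
    cfg = config
    if cfg.n_timepoints < 7:
        raise ValueError("need at least 7 timepoints for a 72-h rhythm window")
    rng = np.random.default_rng([cfg.seed, _TC_STREAM])
    genes = np.array([f"G{i:04d}" for i in range(cfg.n_genes)])

    base = rng.lognormal(cfg.timecourse_log_mean, cfg.timecourse_log_sd, cfg.n_genes)
    rhythmic_idx = rng.choice(cfg.n_genes, size=cfg.n_rhythmic, replace=False)
    phase = rng.choice([1, -1], size=cfg.n_rhythmic)
    drift = np.where(rng.random(cfg.n_genes) < 0.5, 0.0,
                     rng.uniform(-0.05, 0.05, cfg.n_genes))

    t_idx = np.arange(cfg.n_timepoints)
    log_amp_wt = 0.5 * np.log(cfg.rhythm_fold)
    amp = {"wt": log_amp_wt, "fl": log_amp_wt * cfg.fl_rhythm_damping}

    samples, columns = [], []
    for condition in ("wt", "fl"):
        # gene x timepoint mean matrix
        means = base[:, None] * np.exp(drift[:, None] * t_idx[None, :])
        osc = np.zeros((cfg.n_genes, cfg.n_timepoints))
        osc[rhythmic_idx] = phase[:, None] * (-1.0) ** t_idx[None, :] * amp[condition]
        means = means * np.exp(osc)
        for rep in range(1, cfg.n_replicates + 1):
            for t in t_idx:
                hours = float(t * cfg.timepoint_spacing_h)
                name = f"{condition.upper()}_R{rep}_T{int(hours):03d}"
                counts = nb_sample(rng, means[:, t], cfg.timecourse_dispersion)
                columns.append(pd.Series(counts, index=genes, name=name))
                samples.append({"sample": name, "condition": condition,
                                "replicate": rep, "timepoint_h": hours})

    counts = pd.concat(columns, axis=1)
    sheet = pd.DataFrame(samples)
    flags = np.zeros(cfg.n_genes, dtype=bool)
    flags[rhythmic_idx] = True
    phases = np.zeros(cfg.n_genes, dtype=int)
    phases[rhythmic_idx] = phase
    truth = GroundTruth(rhythmic=pd.DataFrame(
        {"gene": genes, "rhythmic": flags, "phase": phases}))
    return counts, sheet, truth


# ---------------------------------------------------------------------------
# toy genome with ACRs and planted motifs
# ---------------------------------------------------------------------------

@dataclass
class GenomeData:
    """Toy genome bundle: sequences, gene models, ACRs and ACR counts."""

    sequences: dict
    genes: pd.DataFrame          # gene_id, chrom, start, end, strand (0-based half-open)
    acrs: pd.DataFrame           # chrom, start, end, name
    acr_counts: pd.DataFrame     # acr x atac-cell counts
    acr_conditions: pd.Series    # condition per atac cell
    chrom_sizes: dict = field(default_factory=dict)


# fixed slot layout (relative offsets within a gene slot); the pitch keeps
# every gene's 1-kb promoter window clear of neighbouring genes' ACRs
_SLOT = 1320
_BODY = (640, 760)            # gene body within slot
_PROM_ACR = (-180, -20)       # promoter ACR in gene-frame TSS coordinates
_BODY_ACR_LEN = 100
_MARGIN = 700


def _gene_frame_to_genomic(strand: str, tss: int, d: np.ndarray) -> np.ndarray:
    """Genomic position of gene-frame offset d (vectorised)."""
    d = np.asarray(d)
    return tss + d if strand == "+" else tss - d


def gen_genome(config: SyntheticConfig) -> tuple[GenomeData, GroundTruth]:
    """Toy genome with genes on both strands, promoter/gene-body ACRs and
    planted 8-mers at configured signed TSS distances and orientations.

    Gene identifiers reuse the single-cell gene universe; all planted marker
    genes are guaranteed a slot so that motif target sets can be tied to
    cell populations.  Ground-truth occurrence lists are produced from the
    placement records; because the background is i.i.d. uniform A/C/G/T a
    planted 8-mer may also occur by chance elsewhere — callers detect those
    with the scanning pipeline itself.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, _GENOME_STREAM])

    per_chrom = (cfg.chromosome_length - 2 * _MARGIN) // _SLOT
    capacity = per_chrom * cfg.n_chromosomes
    n_genes = min(cfg.n_genes, capacity)

    # choose which sc genes get a genomic slot: marker genes first (so motif
    # target sets can align with cell populations), then a random fill
    all_genes = np.array([f"G{i:04d}" for i in range(cfg.n_genes)])
    sc_truth_markers = _marker_gene_ids(cfg)
    fill = np.setdiff1d(all_genes, sc_truth_markers, assume_unique=False)
    fill = rng.permutation(fill)
    chosen = np.concatenate([sc_truth_markers, fill])[:n_genes]
    chosen = rng.permutation(chosen)  # random genomic order

    sequences = {}
    seq_arrays = {}
    for i in range(cfg.n_chromosomes):
        arr = rng.integers(0, 4, size=cfg.chromosome_length, dtype=np.int8)
        seq_arrays[f"chr{i + 1}"] = arr
    bases = np.array(list("ACGT"))

    gene_rows, acr_rows = [], []
    for gi, gene_id in enumerate(chosen):
        chrom = f"chr{gi // per_chrom + 1}"
        slot = _MARGIN + (gi % per_chrom) * _SLOT
        start, end = slot + _BODY[0], slot + _BODY[1]
        strand = "+" if rng.random() < 0.5 else "-"
        gene_rows.append({"gene_id": gene_id, "chrom": chrom, "start": start,
                          "end": end, "strand": strand})
        tss = start if strand == "+" else end - 1
        if strand == "+":
            p0, p1 = tss + _PROM_ACR[0], tss + _PROM_ACR[1]
        else:
            p0, p1 = tss - _PROM_ACR[1] + 1, tss - _PROM_ACR[0] + 1
        acr_rows.append({"chrom": chrom, "start": int(p0), "end": int(p1),
                         "name": f"acr_{gene_id}_prom", "gene_id": gene_id,
                         "kind": "promoter"})
        if rng.random() < cfg.gene_body_acr_fraction:
            b0 = start + 10
            acr_rows.append({"chrom": chrom, "start": int(b0),
                             "end": int(b0 + _BODY_ACR_LEN),
                             "name": f"acr_{gene_id}_body", "gene_id": gene_id,
                             "kind": "body"})
    genes = pd.DataFrame(gene_rows)
    acrs = pd.DataFrame(acr_rows).sort_values(["chrom", "start"]).reset_index(drop=True)

    # --- plant motifs ---------------------------------------------------
    k = 8
    half = k // 2
    gene_info = genes.set_index("gene_id")
    prom_acrs = acrs[acrs["kind"] == "promoter"].set_index("gene_id")
    available = rng.permutation(genes["gene_id"].to_numpy())
    plant_rows, spec_rows = [], []
    cursor = 0
    cluster_cycle = list(range(cfg.n_clusters - 1))
    marker_df = pd.DataFrame({"gene": sc_truth_markers,
                              "cluster": _marker_gene_clusters(cfg)})
    tss_motif_i = 0
    for motif in cfg.planted_motifs:
        n_t = min(motif.n_target_genes, len(available) - cursor)
        if n_t <= 0:
            raise ValueError("not enough genes to host all planted motifs")
        if motif.orientation != "uniform":
            # bias targets toward one cluster's markers so some motifs are
            # genuinely cell-specific
            c = cluster_cycle[tss_motif_i % len(cluster_cycle)]
            tss_motif_i += 1
            cluster_markers = marker_df.loc[marker_df["cluster"] == c, "gene"]
            pool = available[cursor:]
            preferred = [g for g in pool if g in set(cluster_markers)]
            others = [g for g in pool if g not in set(cluster_markers)]
            ordered = np.array(preferred + others)
            targets = ordered[:n_t]
            # keep `available` consistent: consume the chosen genes
            remaining = np.array([g for g in pool if g not in set(targets)])
            available = np.concatenate([available[:cursor], targets, remaining])
        targets = available[cursor: cursor + n_t]
        cursor += n_t
        spec_rows.append({"motif": motif.sequence,
                          "orientation": motif.orientation,
                          "distance_mean": motif.distance_mean,
                          "distance_sd": motif.distance_sd,
                          "n_target_genes": int(n_t)})
        for j, gene_id in enumerate(targets):
            g = gene_info.loc[gene_id]
            tss = g["start"] if g["strand"] == "+" else g["end"] - 1
            if motif.orientation == "both":
                orient = "forward" if j % 2 == 0 else "reverse"
            elif motif.orientation == "uniform":
                orient = "forward" if rng.random() < 0.5 else "reverse"
            else:
                orient = motif.orientation
            gene_acrs = acrs[acrs["gene_id"] == gene_id]
            if motif.orientation == "uniform":
                # uniform over ALL of this gene's ACR positions (promoter
                # and gene body alike), matching the shuffle null exactly
                usable = (gene_acrs["end"] - gene_acrs["start"] - k + 1).to_numpy()
                a = gene_acrs.iloc[int(rng.choice(len(gene_acrs),
                                                  p=usable / usable.sum()))]
                # midpoint bounds valid for either strand (the k-window is
                # asymmetric around the midpoint)
                g_mid = int(rng.integers(a["start"] + half, a["end"] - half))
                d = int(g_mid - tss) if g["strand"] == "+" else int(tss - g_mid)
                host = a
            else:
                d = int(np.clip(round(rng.normal(motif.distance_mean, motif.distance_sd)),
                                _PROM_ACR[0] + half, _PROM_ACR[1] - (k - half) - 1))
                host = prom_acrs.loc[gene_id]
            seq_in_frame = motif.sequence if orient == "forward" else revcomp(motif.sequence)
            # gene-frame positions of the k bases, midpoint at distance d
            frame_pos = np.arange(d - half, d - half + k)
            gpos = _gene_frame_to_genomic(g["strand"], int(tss), frame_pos)
            written = seq_in_frame if g["strand"] == "+" else revcomp(seq_in_frame)
            lo, hi = int(gpos.min()), int(gpos.max()) + 1
            if lo < host["start"] or hi > host["end"]:
                raise ValueError(
                    f"planted motif for {gene_id} at distance {d} falls outside "
                    f"its host ACR"
                )
            arr = seq_arrays[g["chrom"]]
            arr[lo:hi] = [("ACGT".index(b)) for b in written]
            plant_rows.append({"motif": motif.sequence, "gene": gene_id,
                               "distance": d, "orientation": orient})

    for name, arr in seq_arrays.items():
        sequences[name] = "".join(bases[arr])

    # --- ACR count matrix (bulk-like scATAC) ----------------------------
    n_acrs = len(acrs)
    acc = rng.lognormal(0.0, 0.5, size=n_acrs)
    n_per = cfg.n_atac_cells_per_condition
    conditions = pd.Series(["wt"] * n_per + ["fl"] * n_per,
                           index=[f"ATAC_WT_{i:04d}" for i in range(n_per)]
                           + [f"ATAC_FL_{i:04d}" for i in range(n_per)])
    diff_idx = rng.choice(n_acrs, size=min(cfg.n_differential_acrs, n_acrs),
                          replace=False)
    mean_wt = np.tile(acc, (n_per, 1))
    mean_fl = np.tile(acc, (n_per, 1))
    mean_wt[:, diff_idx] *= cfg.differential_acr_fold
    means = np.vstack([mean_wt, mean_fl])
    counts = nb_sample(rng, means, cfg.nb_dispersion).astype(np.int32)
    acr_counts = pd.DataFrame(counts.T, index=acrs["name"].to_numpy(),
                              columns=conditions.index)

    genome = GenomeData(
        sequences=sequences,
        genes=genes,
        acrs=acrs[["chrom", "start", "end", "name"]].copy(),
        acr_counts=acr_counts,
        acr_conditions=conditions,
        chrom_sizes={c: cfg.chromosome_length for c in sequences},
    )
    truth = GroundTruth(
        motif_plants=pd.DataFrame(plant_rows,
                                  columns=["motif", "gene", "distance", "orientation"]),
        motif_specs=pd.DataFrame(spec_rows),
        acr_gene=acrs[["name", "gene_id"]].rename(columns={"name": "acr_id"}),
        differential_acrs=pd.Series(acrs["name"].to_numpy()[diff_idx]),
    )
    return genome, truth


def _marker_indices(cfg: SyntheticConfig) -> np.ndarray:
    """Which gene indices are planted markers.

    Drawn from a dedicated sub-stream of the master seed so that
    gen_sc_dataset and gen_genome agree on marker identities without one
    having to replay the other's random draws.
    """
    rng = np.random.default_rng([cfg.seed, _SC_STREAM, 7])
    n_markers = cfg.markers_per_cluster * (cfg.n_clusters - 1)
    return rng.choice(cfg.n_genes, size=n_markers, replace=False)


def _marker_gene_ids(cfg: SyntheticConfig) -> np.ndarray:
    return np.array([f"G{i:04d}" for i in _marker_indices(cfg)])


def _marker_gene_clusters(cfg: SyntheticConfig) -> np.ndarray:
    return np.repeat(np.arange(cfg.n_clusters - 1), cfg.markers_per_cluster)


# ---------------------------------------------------------------------------
# temporal gradient
# ---------------------------------------------------------------------------

def gen_temporal_gradient(
    config: SyntheticConfig,
    n_cells: int = 600,
    timepoints: tuple = (-3.0, -1.0, 0.0, 1.0, 3.0),
    n_genes: int = 500,
) -> tuple[ad.AnnData, pd.DataFrame, pd.Series]:
    """Cells whose expression interpolates a time-labelled reference series.

    Returns (cells AnnData with embedding, reference profile table in
    FPKM-like units, true continuous time per cell).  Cells are laid out
    along the embedding x-axis by true time, so grid bins group cells of
    similar developmental age.
    """
    rng = np.random.default_rng([config.seed, _GRADIENT_STREAM])
    genes = np.array([f"TG{i:04d}" for i in range(n_genes)])
    t = np.asarray(timepoints, dtype=float)
    n_t = len(t)
    # smooth profiles: random log-level at first and last timepoint
    lo = rng.normal(3.0, 1.2, size=n_genes)
    hi = rng.normal(3.0, 1.2, size=n_genes)
    w = np.linspace(0, 1, n_t)
    log_prof = lo[:, None] * (1 - w[None, :]) + hi[:, None] * w[None, :]
    refs = pd.DataFrame(np.exp(log_prof), index=genes,
                        columns=[f"T{i}" for i in range(n_t)])

    u = rng.uniform(0, n_t - 1, size=n_cells)  # true time in sample index units
    frac, base_i = np.modf(u)
    base_i = base_i.astype(int)
    nxt = np.minimum(base_i + 1, n_t - 1)
    cell_log = (log_prof[:, base_i] * (1 - frac) + log_prof[:, nxt] * frac).T
    mean = np.exp(cell_log)
    mean = mean / mean.sum(axis=1, keepdims=True) * 2000.0
    counts = nb_sample(rng, mean, 0.3).astype(np.int32)

    coords = np.column_stack([u * 2.0 + rng.normal(0, 0.15, n_cells),
                              rng.normal(0, 0.3, n_cells)])
    ids = [f"GRAD_{i:04d}" for i in range(n_cells)]
    adata = ad.AnnData(X=sp.csr_matrix(counts),
                       obs=pd.DataFrame(index=pd.Index(ids, name="cell_id")),
                       var=pd.DataFrame(index=pd.Index(genes, name="gene_id")))
    adata.obsm["X_umap"] = coords
    true_time = pd.Series(t[0] + u * (t[-1] - t[0]) / (n_t - 1), index=ids,
                          name="true_time")
    # reference samples carry their timepoint label
    refs.columns = pd.Index([f"T{tp:+.0f}dpa" for tp in t], name="sample")
    return adata, refs, true_time
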