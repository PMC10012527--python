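# Methods

`fibrorhythm` re-implements, as a tested and reusable library, the
computational procedures of a single-cell study of cotton ovule outer
integument (OI) cells: MEG-guided cell clustering with an explicit
gene-distance metric, a three-condition marker-gene filter, pseudo-bulk
temporal mapping, diurnal rhythmic-gene calling, chromatin-accessibility
quantification, and a cell-specific 8-mer cis-regulatory motif pipeline
with spatial-autocorrelation selection and TSS-directionality testing.
Every stage can be exercised end-to-end on synthetic inputs with planted
ground truth, so the whole analysis is testable without any external
download.

## Cell quality filters

Cells are filtered in two stages. First, cells whose total UMI count
exceeds `median + 2 × MAD` of the per-cell totals are removed; the MAD is
the raw (unscaled) median absolute deviation, the same estimator used by
the directionality test, so a single convention runs through the package.
Second, among the remaining cells, the numbers of detected (UMI ≥ 1) and
expressed (UMI ≥ 2) genes must both lie inside the 2.5–97.5% quantile
interval of the remaining cells; quantiles use linear interpolation
between order statistics (NumPy's default), and the same convention is
used by the independent oracle in the tests. Fewer than four cells is an
error, since the quantile interval would be meaningless.

## Modularity-enriched genes (MEGs) and cluster merging

A MEG is a gene whose expressing cells (UMI ≥ 1) occupy a coherent
territory of the embedding. The scan considers genes expressed in more
than 100 cells and in fewer than half of all cells. On a binary
k-nearest-neighbour graph of the 2-D embedding (k = 25, symmetrised by
max), the enrichment fold of a cell set S is

    fold(S) = observed intra-S edge weight / (d_S² / 4m),

the standard modularity null in which the expected intra-set weight is
proportional to the squared degree fraction (d_S = summed degree of S,
m = total edge weight). A set containing every vertex has fold exactly 1.
The background fold is the median over 100 seeded random cell subsets of
size |S|; a gene is a MEG iff its fold is at least 10× the background.
The per-gene statistic is a design choice — the original pairwise-cluster
modularity routine does not define one — and the observed/expected form
was chosen because it makes "enrichment fold" exact and oracle-checkable.

The distance between MEGs *i* and *j* averages, over expressing cells m
of *i*, the mean embedding distance from m to its k = 5 nearest
expressing cells of *j* (m is never its own neighbour; k shrinks to the
candidate count when the other set is small), symmetrised by averaging
both directions. Identical singleton sets have distance 0 by convention.
Neighbour ties are broken by cell order for determinism.

The MEG distance matrix is hierarchically clustered (complete linkage,
the cited routine's default) and cut into 4 groups. Each fine cluster of
the over-split input partition is assigned to the MEG group with the
highest mean expressing-cell fraction of its genes inside that fine
cluster, provided the fraction exceeds 0.1; unassigned fine clusters
merge into a single no-MEG cluster. Fine clusters are never split.

## Marker genes

Candidates come from a one-vs-rest two-sample rank-sum scan (normal
approximation with tie and continuity correction, validated against
SciPy) run separately on the WT-like, mutant-like and merged datasets,
with Benjamini–Hochberg FDR across genes; a candidate needs FDR < 1e−9
and fold change > 2 (cluster mean CPM with pseudocount 1) in every
dataset that contains the cluster. The distribution-free test was chosen
over the original packaged scan because it is reproducible and
oracle-checkable at these sample sizes.

The expression ratio of a gene in a cluster is the fraction of cluster
cells with UMI ≥ 1 (the "detected" threshold). Transcription factors keep
all their candidates; other genes must satisfy (1) minimum own-cluster
ratio across datasets > 0.01, (2) that minimum > 1.5× the maximum
other-cluster ratio, and (3) maximum other-cluster ratio < 0.1. A cluster
absent from a dataset (the fiber-like cluster is missing from the mutant)
is excluded from the min/max — otherwise no marker could exist for it.
Condition-wise differential expression per cluster uses the same rank-sum
machinery at FDR < 0.05 and fold change > 2.

## Pseudo-bulk temporal mapping

Cells are binned on the embedding into axis-aligned squares (granularity
0.5 for identity correlation with purified-cell references, 0.2 for time
mapping; grid origin fixed at 0 for reproducibility). Bin counts are
summed and normalised to CPM (sum-then-normalise, the standard pseudo-bulk
contract). Each bin profile is Spearman-correlated with each reference
sample over the reference gene set (time-course rule: expression > 1 in
at least one sample; purified-fiber rule: > 1 in all samples). Replicate
columns sharing a timepoint are averaged after correlation; each bin is
assigned the argmax timepoint with ties resolved to the earliest, and
cells inherit their bin's assignment. Zero-variance bins propagate a
missing label.

## Rhythmic gene calling

Adjacent-timepoint fold changes of mean CPM (pseudocount 1) are signed
(+/−/0; an exact fold change of 1 breaks an alternating run, taking strict
alternation at its word). Pair significance uses a negative-binomial Wald
test: a genome-wide dispersion is estimated by method of moments across
replicate groups and shared across genes, and the delta-method variance of
the log2 mean difference gives a normal z statistic, with BH-FDR across
genes per pair. The information sharing is what keeps an n = 2 replicate
design powered; per-gene Welch or moderated-t variants were measured and
lack the power to reach FDR < 0.05 at the planted 3-fold amplitude, so
they were rejected.

A gene is a potential REG in a condition when its sign string contains at
least 6 consecutive strictly alternating nonzero signs (72 h at 12-h
spacing; the window length is derived from the spacing). Genes rhythmic
in both conditions must agree in sign on the overlap of their alternating
windows, else they carry a pattern-mismatch flag. A REG is significant
when ≥ 4 consecutive pairs (48 h) inside its alternating window each have
FDR < 0.05 and fold change > 1.5; alternation is established first and
the significance window is sought inside it.

Note that the alternation rule alone is permissive: because adjacent fold
changes share the middle timepoint, replicate noise anti-correlates them
and roughly a third of null genes show a 72-h alternating run. The
significance criterion is what controls the false-positive rate (≈ 0 on
planted null genes), and downstream pattern grouping therefore operates on
significant REGs.

Pattern groups come from seeded k-means (k = 4 by default) on z-scored
log2 mean-CPM profiles of one condition, with groups labelled in order of
their centroid peak timepoint. Differential rhythm between conditions
uses, as amplitude, the mean absolute adjacent-pair log2 fold change of
the timepoint means (the max−min range is available as an option but has
measurably lower permutation power at the default damping), and a
permutation test that reassigns condition labels within each timepoint
(seeded, 1000 draws by default; exhaustive enumeration available for
small designs); the p-value is two-sided on |amplitude difference|.

## Chromatin accessibility

Peak sets are unioned into ACRs; overlapping or book-ended intervals
merge. Gene-level ATAC signal sums the counts of ACRs overlapping
(≥ 1 bp — the minimal, documented criterion) the gene body or the
strand-aware 1-kb promoter upstream of the TSS; an ACR overlapping two
genes counts toward both, since summation is per-gene and no exclusivity
rule is imposed. Differential regions/genes between conditions use
counts per 10,000 per cell, a two-sided rank-sum test across cells, and
cutoffs fold change ≥ 2, p < 0.01.

## Cell-specific k-mer motifs

Each gene-associated ACR sequence is scanned in the gene's 5′→3′ frame
for all 8-mers: a literal window is a forward occurrence of that 8-mer
and simultaneously a reverse occurrence of its reverse complement. This
gene-frame convention makes "forward/reverse relative to the gene"
well-defined on both strands; results are invariant to the alternative
genome-frame convention up to a label swap on minus-strand genes. Every
occurrence records the signed gene-frame distance of its midpoint
(window start + k//2, a documented constant — the anchor is otherwise
arbitrary) to the TSS, negative upstream. The 0/1 motif–gene incidence
matrix marks genes with at least one occurrence in either orientation.

Per cell, each motif is summarised by the number of its target genes
detected (UMI ≥ 1) and their total UMI. Moran's I of each statistic over
the embedding uses a row-normalised binary kNN graph (k = 25, mirroring
the embedding-graph parameter used elsewhere in the pipeline; weights are
otherwise unspecified in this class of analysis). Motifs in the top 5%
(≥ 95th percentile, linear-interpolation quantiles, ties included) for
*both* statistics are cell-specific. They are split into two groups by
Ward.D2 clustering on Euclidean distances between per-cluster summed
target expression vectors; the group depleted of fiber-cluster-maximal
target genes is labelled M1 (inhibitory-like), the other M2
(activating-like). The fiber-like cluster is recognised operationally as
the final cluster most depleted of mutant-condition cells.

Per-cluster target enrichment uses a 2×2 Fisher exact test one-sided in
the observed direction — exactly the hypergeometric tail, which is what
the closed-form oracle checks — with Obs/Exp =
(targets-in-cluster/targets)/(expressed-in-cluster/expressed), calls at
Obs/Exp > 1.5 or < 0.67 with p < 0.05, and 10,000 seeded same-size random
draws from the expressed universe (CPM > 1 in any cluster) as controls.

## TSS directionality

For each motif and orientation, the MAD (raw, no 1.4826 scaling — the
comparison is like-with-like so scaling cancels) of the signed TSS
distances is compared with 100 shuffled controls: the same number of
pseudo-occurrences placed uniformly over all ACR base positions, each
contributing one distance per gene associated with its ACR. Controls are
drawn per orientation with the matched occurrence count, so an
orientation with few occurrences faces an appropriately noisy null and
cannot pass spuriously. An orientation passes when its MAD is below the
control mean minus 2 control standard deviations (SD with ddof = 1).
One passing orientation → directional; both → non-directional; neither →
non-enriched around the TSS. The targeting radius is the passing MAD
(directional) or the smaller of the two (non-directional — the more
conservative pooling of an ambiguous case). Targets are expressed genes
(CPM > 1 in any cluster) with an occurrence strictly closer to the TSS
than the radius.

## Synthetic data

The generators produce every input with the statistical structure the
analysis assumes. Counts are negative binomial (mean μ, dispersion α,
variance μ + αμ²); each generator draws from its own RNG stream derived
from the master seed by a fixed offset, so generators are independently
reproducible and identical seeds give byte-identical files.

**Cells.** Two conditions of 1500 cells, five populations: four
marker-bearing populations (17/17/17/18% in WT) and a dominant background
population without markers — mirroring OI tissue, where cortical-like
cells dominate and carry no distinctive programme. The fiber-like
population (index 3) has zero cells in the mutant-like condition, its
share moving to the background. The embedding places one Gaussian blob
per population; the fine partition over-splits each blob into 2–3
spatially contiguous slices (12 fine clusters in total). Cells carry
log-normal library-size factors (σ = 0.35), the depth spread without
which the `median + 2·MAD` filter would preferentially remove
marker-laden cells.

Each marker cluster plants 40 markers of two kinds. *Broad* markers (30)
have out-of-cluster mean 0.06 and in-cluster mean `marker_fold` (8)
times that — the fold-faithful class that exercises the candidate scan
and ratio filter. *Focal* markers (10) are switch-like: off-mean 0.004,
on-state mean `0.004 · marker_fold^3.55` (≈ 6 at the default fold),
expressed in a contiguous spatial patch of ≈ 170 cells around a random
anchor in the blob. The steep on/off response models near-silent genes
on the steep part of their activation curve; setting `marker_fold = 1`
collapses both classes to the null. The two classes exist because a
single fold-8 coupling between on and off means cannot simultaneously
satisfy the 10×-background modularity criterion (which needs an almost
pure expressing set) and the < 0.1 other-cluster ratio ceiling; the patch
size keeps the expressing set above the 100-cell candidate floor after
the ≈ 20% attrition of the quality filters while staying compact enough
for a strong modularity fold. A further 25 genes carry a 4-fold
WT-specific shift in one cluster for the differential-expression stage.
Every fifth marker is tagged as a transcription factor.

**Time course.** 2 conditions × 2 replicates × 9 timepoints at 12-h
spacing (36 samples). 200 rhythmic genes alternate between
`base·√fold` and `base/√fold` (fold = 3) with random phase; the mutant's
log-amplitude is multiplied by 0.5 (the damping magnitude is not
constrained by any external value and is exposed as a knob).
Non-rhythmic genes are constant or drift monotonically (±5% per
timepoint). Base expression is log-normal (median ≈ 200 counts);
replicate dispersion is 0.05, a typical bulk RNA-seq value — far below
the single-cell dispersion of 0.5, as biological replicates of pooled
tissue average out cellular noise.

**Genome.** Two 500-kb chromosomes of i.i.d. uniform A/C/G/T. Genes
(120-bp bodies on random strands) sit on a 1320-bp pitch chosen so that
no gene's 1-kb promoter window reaches a neighbouring gene's ACRs —
keeping the ACR→gene association one-to-one and the planted TSS-distance
distributions clean. The pitch caps the annotation at 754 genes; marker
genes are guaranteed slots so motif target sets can align with cell
populations. Each gene has a promoter ACR at gene-frame [−180, −20) and
half the genes a 100-bp gene-body ACR. Five 8-mers are planted, 140
target genes each (disjoint sets): two forward-directional (−50 ± 20 and
−80 ± 25), one in both orientations, one reverse-directional, and one
placed uniformly over all ACR positions as a null that matches the
shuffle control exactly. Because the background is uniform, a planted
8-mer can also occur by chance (~3 extra occurrences per orientation
genome-wide); ground-truth occurrence lists therefore come from scanning
the final sequence rather than from the placement records alone.
Per-cell ACR counts for the chromatin stage are NB with log-normal
accessibility, 200 cells per condition, and 100 ACRs 4-fold more
accessible in the WT-like condition.

**What the generator does not emulate.** Doublets, ambient RNA, batch
effects (batch correction is out of scope), read-level error, intron
structure, realistic sequence composition, and linkage between the
chromatin counts and the expression counts. Passing recovery tests on
these data demonstrates that the implementations compute their stated
quantities and detect their stated structure at realistic noise levels —
not that the thresholds are optimal for any particular real dataset.

## Problem sizes and determinism

The default end-to-end run (3000 cells × 2000 genes, 36 bulk samples,
1-Mb genome, ~65k scanned motifs) completes in roughly one minute on a
single core; these sizes were chosen as the smallest at which every
statistical criterion of the pipeline is well inside its operating range
(e.g. the 100-cell MEG candidate floor). All randomness flows from one
seed; summaries are byte-identical across runs with the same
configuration, which the test suite asserts.

## Known limitations

* The modularity-fold background uses random subsets of matched size; a
  closed-form null would be faster but would not capture the blob
  geometry.
* The NB Wald pair test assumes a common dispersion; strongly
  gene-specific dispersion would call low-dispersion genes conservatively
  and high-dispersion genes liberally relative to an exact per-gene test.
* The alternation rule's permissiveness under replicate noise (see
  above) is a property of the method itself, faithfully reproduced.
* `cluster_enrichment` treats target sets as fixed; no correction is made
  for the selection step that produced them.
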