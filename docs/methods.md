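# Methods

This note documents the statistical procedures implemented in `pcs`, the
synthetic study the package generates to exercise them, and the numerical
choices made where the design was genuinely open.

## Coordinates and signal extraction

All coordinates are BED-convention 0-based half-open; a peak's center is
`floor((start + end) / 2)`. Coverage is stored as read counts per
fixed-width bin (default 50 bp). The signal matrix for a sample holds, per
peak, the binned counts over `[center − w, center + w)` (default
`w = 1000` bp for clustering and quantification; windows running off a
chromosome edge are zero-padded). A peak on a chromosome missing from a
track is a hard error rather than a silent zero, because silent zeros
propagate into wild-type-relative percentages undetected.

The common peak universe is built by union-merging per-antibody peak sets
(`merge_union`, gap 0), optionally after removing peaks supported by too
few companion marks (`exclude_solo_peaks`) — the filter that drops
"solo" sites of a single subunit, such as JARID2-only peaks, before any
joint analysis. Occupancy of a mark over a universe is the fraction of
peaks whose mean window signal exceeds `t ×` background (default
`t = 2`); the background estimate should come from the matched input
track, and occupancy is best judged on a summit-proximal window (±500 bp)
so that sharp low-amplitude marks are not diluted by a wide window.

## Normalization

RPKM is `count / ((length/10³)(library/10⁶))`; bin-wise RPKM uses the
factor `10⁹ / (bin_size × library)`, so the mean over a window's bins
equals the whole-window RPKM identically. Input subtraction is per-bin on
RPKM matrices, and negative values are **retained** — clamping before a
median biases cluster-level estimates; flooring at zero is left to heatmap
rendering. Wild-type-relative percentages (`wt_percent`) are computed on
cluster-level aggregate statistics, matching figure-level quantification.

Spike-in scaling multiplies a track by `ref_spike / spike`, where `spike`
is the sample's exogenous-genome read count. Under the
fixed-sequencing-depth approximation (see *Synthetic data*), per-million
normalization is blind to genome-wide occupancy shifts while spike-in
scaling recovers them; when no global shift exists the two normalizations
agree, which the `normalization_concordance` Pearson diagnostic makes
quantitative.

## Stratification: k-means under Pearson distance

Peaks are clustered on the concatenation of their ±1 kb windows across
all conditions, using Pearson correlation distance `d(x, y) = 1 − r(x, y)`.
For row-centered unit-norm vectors with unit-norm centroids,
`d(x, c) = ‖x̃ − c̃‖² / 2`, so Lloyd's algorithm under this distance is
spherical k-means on centered rows: assignment by maximum dot product,
centroid update by the normalized mean direction (which is the exact
minimizer of the summed distance for a fixed assignment). The reported
inertia is therefore exactly the summed Pearson distance. The equivalent
z-score-then-Euclidean route is used as an independent cross-check in the
test suite, not as the implementation.

Feature construction concatenates the condition blocks *without*
per-block standardization: the single row-wise centering/scaling implicit
in the correlation preserves relative amplitudes between conditions,
which is the only information separating two flat broad-domain profiles
(a flat window has no within-block shape at all). Per-block z-scoring is
available as an option for shape-only clustering of sharp peaks.

Details:

- **Initialization.** k-means++-style seeding under Pearson distance;
  best of `n_init` (default 10) seeded restarts by inertia. A
  `random-partition` mode seeds each restart from a uniformly random full
  partition instead; on very small inputs the global optimum can be a
  Lloyd fixed point whose basin contains no point-pair seeding, and
  partition seeding can reach every fixed point.
- **Empty clusters** are re-seeded at the point currently farthest from
  its centroid.
- **Zero-variance rows** (flat signal) have no defined correlation; they
  are excluded from fitting, assigned afterwards by Euclidean distance to
  the raw-space cluster means, and flagged.
- **Determinism.** All randomness flows from `random_state` through a
  `SeedSequence`; fits are bit-reproducible.
- **Relabeling.** Cluster ids from k-means are arbitrary;
  `relabel_clusters` renumbers them by a per-cluster statistic (default
  intent: signal sharpness), with ties broken by size then original id.

**Model selection.** `select_k_elbow` fits every k in a range and takes
the interior k maximizing the discrete second difference of the inertia
curve. A knee is flagged as *pronounced* only when that curvature reaches
half of the largest single-step inertia drop; smooth curves from
unstructured data flatten steadily and fail this test, while a genuine
knee — where the drop collapses after the true k — passes it easily.

## Bootstrap quantification

The exchangeable unit is the peak. For each (condition × cluster) cell,
`n_boot` (default 1000) with-replacement resamples of the member peaks'
normalized values are drawn; the cell is summarized by the median of the
resample medians (point estimate) and a central percentile interval —
linear interpolation between order statistics — of the resample *means*
at the requested level (default 99.9 %), mirroring the
dots-are-medians/CI-of-means convention of the figures this reproduces.
A switch (`ci_of="medians"`) gives the CI of the medians instead. The
percentile method is used throughout (no BCa); it is the minimal
assumption-free choice. Resampling uses integer indices only, making
results platform-independent for a fixed seed, and per-cell seeds are
derived from the global seed and the *sorted* peak order, so shuffling
peaks does not change any summary. Clusters with fewer than two peaks are
flagged and get no CI.

## Shape-conditioned GCG counting

Helix twist is predicted by a pentamer model: each 5-mer assigns a twist
(degrees) to the base-pair step at its center. A GCG occurrence matches
the recruitment-permissive shape when the mean twist of its two internal
steps is strictly below a threshold. Reverse-strand hits (CGC on the
forward strand) are evaluated on the reverse-complement sequence with its
own pentamers, which makes counts exactly strand-symmetric. Hits whose
pentamers run off the sequence end are excluded and tallied
(`flank_mode="strict"`; `"lenient"` averages the evaluable steps).

The twist threshold and averaging window are configuration parameters
with placeholder defaults (table-median twist; the two internal steps):
the calibrated values belong to an external pentamer table, which this
package does not ship. A synthetic table — a keyed hash of each pentamer
mapped uniformly to 30–40° — is bundled for tests and simulation; it is a
reproducible stand-in, not a physical shape model, so only *relative*
statements (class contrasts, oracle agreement, monotonicity) are
meaningful with it.

## Enrichment

Each peak is assigned to the gene with the nearest TSS within 10 kb of
the peak center (ties to the lexicographically smaller gene id); gene
sets are deduplicated. Terms are tested per cluster with the upper-tail
hypergeometric probability `P(X ≥ overlap)` against either background —
all genes, or PRC2-target genes (the union of peak-associated genes) —
with BH correction across terms within a cluster. Terms with fewer than
3 background genes are skipped and reported. The two-background design
separates "Polycomb-like in general" (enriched only against all genes)
from cluster-specific biology (enriched within targets as well).

## Synthetic data

The generator emulates the *design* of a multi-condition PRC2 ChIP-seq
study at desk scale, not any real genome:

- **Genome**: 2 chromosomes × 5 Mb, random sequence at 42 % GC, with all
  incidental GCG/CGC removed so planted motif densities are exact.
- **Peak universe**: six classes of 75 peaks each — four *narrow* classes
  (1–2 kb, Gaussian profile with σ = width/4, 8 shape-matching GCG/kb)
  and two *broad* classes (4–8 kb, flat plateau with 10 % edge taper,
  1 GCG/kb). Peaks are placed disjointly with ≥ 4 kb separation.
  Shape-matching GCGs are planted as 7-mers with A/T flanks drawn from
  the permissive-context set of the bundled twist table (decoy,
  non-matching GCGs are planted alongside), so planting can never create
  hits across junctions and the counter recovers the target densities
  exactly up to rounding.
- **Conditions**: a 14-sample antibody × genotype × treatment grid
  (EZH2/H3K27me3/MTF2/JARID2 in wild type, *Mtf2* and *Jarid2* mutants,
  EED-inhibitor treatment, and MTF2 in an *Eed* null). Each class carries
  a per-condition *residual fraction* — the share of its wild-type
  amplitude surviving the perturbation; wild-type conditions are 1.0
  everywhere. The quantified contrasts follow the study design this
  emulates: H3K27me3 after MTF2 loss retains 6–27 % at narrow vs 48–56 %
  at broad classes, EZH2 9–12 % vs 23–26 %, JARID2 11–19 % vs 30–34 %,
  and EED-inhibitor treatment leaves 77 % (EZH2), 85 % (MTF2) and 41 %
  (JARID2), read as residual levels (a switch flips the reading to
  amounts of reduction, since the figure-level phrasing is ambiguous).
- **Class separability.** The remaining, unquantified conditions carry
  full-swing subtype contrasts, and each class additionally has
  per-antibody wild-type amplitude multipliers (the relative weight of
  the marks differs per target class, which is the biology the
  stratification is about). The multipliers were chosen once, by a
  numeric search on the noise-free design, to make the six class profiles
  near-equidistant under Pearson distance (pairwise 0.64–0.86): with six
  comparably separated classes the inertia curve falls linearly to k = 6
  and flattens, so elbow selection is well-posed rather than dominated by
  a nested narrow/broad split.
- **Noise**: per-bin Poisson around the expected rate (background 1
  read/bin, library 2×10⁷), with an optional negative-binomial
  dispersion knob. **Spike-in**: sequencing depth is held fixed, so a
  global-efficiency change leaves the per-million track untouched and
  scales the spike-in read count inversely — exactly the regime where
  spike-in normalization sees what per-million normalization cannot.
- **Annotation**: one gene per peak (TSS jittered ±1 kb around the peak
  center) plus 2,000 background genes kept ≥ 15 kb from any peak; a
  planted broad-class term (the Hox-like compartment), an all-peaks
  "polycomb_target" term, a two-subclass "neural" term, and 20 random
  decoy terms.
- **Determinism**: one seed feeds a `SeedSequence`; children are spawned
  in a fixed order for placement, sequence, each condition's tracks
  (keyed by sample id, so adding conditions does not disturb others), and
  annotation. Identical seeds give byte-identical outputs.

What the generator does **not** emulate: mappability and GC bias,
fragment-length smearing, read-level artifacts, replicate structure,
overdispersion beyond the NB knob, CpG-island sequence composition
(`cpg_like` is a label, not a compositional model), or realistic
class-imbalance (75 peaks/class versus thousands). Passing tests
therefore demonstrate that the *procedures* are correct and
well-calibrated on data matching their assumptions — not that the
pipeline is robust to every artifact of real ChIP-seq.

## Problem sizes and tolerances

Default experiment sizes were chosen so the full synthetic analysis is
desk-scale: 450 peaks × 14 conditions for the study (≈ 560 clustering
features per peak), 300 peaks/class for parameter recovery, 500
replications × 400 resamples for CI calibration, 10⁵ resamples where a
bootstrap distribution is compared against exact enumeration. Monte-Carlo
assertions use 3-standard-error tolerances; enumeration and closed-form
oracles are exact to numerical precision (1e-8 or better). Parameter
recovery of planted residual fractions is accurate to within ~1
percentage point at 300 peaks/class, comfortably inside the ±5 pp
acceptance band.

## Known limitations

- The Pearson-distance k-means objective is non-convex; `n_init`
  restarts make solutions reproducible, not provably optimal (the
  exhaustive oracle check covers only tiny instances).
- The elbow criterion assumes comparably separated classes; strongly
  hierarchical structure yields a knee at the top split, which is a
  property of the method, not a bug in the implementation.
- The bundled twist table is synthetic; absolute shape-matching counts
  carry no physical meaning without a calibrated pentamer table.
- `wt_percent` inherits ratio noise from the wild-type denominator; for
  very small clusters the bootstrap CI, not the point estimate, is the
  honest summary.
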