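"""Fully synthetic PRC2 ChIP-seq study generator.

Emulates the design of a multi-condition Polycomb recruitment experiment
at desk scale: a small two-chromosome genome, a peak universe split into
*narrow* CpG-island-like classes (sharp Gaussian signal, high density of
shape-matching GCG trinucleotides) and *broad* domain classes (flat
plateaus, sparse GCGs), and one chip/input track pair per
(antibody × genotype × treatment) condition. Each peak class carries a
planted *residual signal fraction* per condition — the fraction of its
wild-type amplitude that survives the perturbation — which is exactly the
quantity the downstream WT-normalized quantification should recover.

Randomness: a single seed feeds a :class:`numpy.random.SeedSequence`
whose spawned children drive, in fixed order, (1) peak placement and
amplitudes, (2) genome sequence and motif planting, (3) each condition's
chip/input tracks, (4) gene and term annotation. Every output is
byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from pcs.coverage import CoverageTrack, write_bedgraph
from pcs.intervals import GenomicInterval, PeakSet, write_bed
from pcs.shape import ShapeTable, permissive_contexts, scan_gcg, synthetic_twist_table, write_shape_table

_AT = "AT"
_BASES = "ACGT"


@dataclass
class PeakClassSpec:
    """One planted peak class.

    ``label`` names the class (free-form; ``narrow*`` / ``broad*`` by
    convention). ``gcg_density`` is the target density of *shape-matching*
    GCG trinucleotides per kb of peak; ``decoy_gcg_density`` plants
    additional GCGs that fail the shape criterion, so total and matching
    counts differ. ``cpg_like`` marks CpG-island-like classes (narrow,
    bivalent-promoter-style targets).
    """

    label: str
    n_peaks: int
    width_range: tuple[int, int]
    amplitude_range: tuple[float, float]  # reads per bin at the profile peak
    profile: str  # "sharp-gaussian" | "flat-plateau"
    gcg_density: float = 0.0
    decoy_gcg_density: float = 2.0
    cpg_like: bool = False
    #: Per-antibody wild-type amplitude multiplier (absent antibody → 1.0).
    #: Encodes that the relative strength of the marks/subunits differs
    #: between target classes, independently of the perturbation residuals.
    antibody_scale: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_peaks <= 0:
            raise ValueError("n_peaks must be positive")
        if not (0 < self.width_range[0] <= self.width_range[1]):
            raise ValueError("invalid width_range")
        if self.profile not in ("sharp-gaussian", "flat-plateau"):
            raise ValueError(f"unknown profile {self.profile!r}")


@dataclass
class ConditionSpec:
    """One (antibody, genotype, treatment) sample.

    ``residual_fraction_by_class`` maps class label → fraction of the
    class's wild-type amplitude this condition retains (wild type: all
    fractions 1). ``global_efficiency`` emulates a genome-wide occupancy
    change invisible to per-million scaling: sequencing depth is held
    fixed, so the chip track itself does not change with it, while the
    exogenous spike-in read count varies inversely
    (``spike_in_reads = spike_base / global_efficiency``).
    """

    sample_id: tuple[str, str, str]
    residual_fraction_by_class: dict[str, float]
    background_rate: float = 1.0  # reads per bin
    library_size: float = 2e7
    global_efficiency: float = 1.0
    spike_base: float = 1e5
    dispersion: float = 0.0  # negative-binomial dispersion; 0 = Poisson

    def __post_init__(self) -> None:
        for label, f in self.residual_fraction_by_class.items():
            if f < 0:
                raise ValueError(f"negative residual fraction for {label!r}")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.global_efficiency <= 0:
            raise ValueError("global_efficiency must be positive")

    @property
    def spike_in_reads(self) -> float:
        return round(self.spike_base / self.global_efficiency)


@dataclass
class PlantedPeak:
    interval: GenomicInterval
    class_label: str
    amplitude: float
    width: int
    profile: str
    antibody_scale: dict[str, float] = field(default_factory=dict)


@dataclass
class Universe:
    """Peak universe plus genome sequence and planted ground truth."""

    peaks: PeakSet
    sequences: dict[str, str]
    planted: list[PlantedPeak]
    genome: dict[str, int]
    class_labels: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.class_labels = [p.class_label for p in self.planted]

    def class_of(self) -> dict[str, str]:
        return {p.interval.name: p.class_label for p in self.planted}


def _scrub_gcg(seq: np.ndarray, rng: np.random.Generator) -> None:
    """Remove every GCG/CGC from a base array (in place).

    Replaces the middle base of each hit with A or T and rescans until
    clean (A/T substitutions can never create a new all-G/C triplet, so
    this terminates after one pass); the synthetic background therefore
    contains no incidental GCG hits and planted densities are exact.
    """
    while True:
        g = seq == "G"
        c = seq == "C"
        fwd = g[:-2] & c[1:-1] & g[2:]
        rev = c[:-2] & g[1:-1] & c[2:]
        mids = np.flatnonzero(fwd | rev) + 1
        if mids.size == 0:
            break
        seq[mids] = np.array(list(_AT))[rng.integers(2, size=mids.size)]


def _plant_motifs(seq_arr: np.ndarray, start: int, end: int, n_sites: int,
                  contexts: Sequence[str], rng: np.random.Generator) -> None:
    """Write ``n_sites`` 7-mer GCG contexts at disjoint slots in [start, end)."""
    if n_sites == 0:
        return
    width = end - start
    n_slots = width // 7
    if n_sites > n_slots:
        raise ValueError("region too small for requested motif density")
    slots = rng.choice(n_slots, size=n_sites, replace=False)
    for slot in slots:
        ctx = contexts[rng.integers(len(contexts))]
        pos = start + int(slot) * 7
        seq_arr[pos:pos + 7] = list(ctx)


def generate_universe(class_specs: Sequence[PeakClassSpec],
                      genome: Mapping[str, int],
                      seed: int,
                      shape_table: ShapeTable | None = None,
                      min_separation: int = 4000,
                      edge_margin: int = 6000,
                      gc_content: float = 0.42) -> Universe:
    """Place disjoint class-labeled peaks and synthesize their sequences.

    Peaks are shuffled across classes, distributed over chromosomes
    proportionally to length, and placed left to right with random slack
    so that neighbours are at least ``min_separation`` bp apart. Sequences
    are random at the requested GC content, scrubbed of incidental
    GCG/CGC, then re-planted with shape-matching GCG contexts at each
    class's target density (plus non-matching decoys), using 7-mers with
    A/T flanks so planting can never create hits across junctions.

    Peak BED names encode the class as ``<label>|<index>``.
    """
    if shape_table is None:
        shape_table = synthetic_twist_table()
    threshold = shape_table.median_twist()
    good_ctx = [c for c in permissive_contexts(shape_table, threshold)
                if all(b in _AT for b in (c[0], c[1], c[5], c[6]))
                and len(scan_gcg(c)) == 1]
    all_at_ctx = [f"{x}{y}GCG{u}{v}"
                  for x in _AT for y in _AT for u in _AT for v in _AT]
    bad_ctx = [c for c in all_at_ctx
               if c not in good_ctx and len(scan_gcg(c)) == 1]
    if not good_ctx or not bad_ctx:
        raise ValueError("shape table leaves no usable planting contexts")

    root = np.random.SeedSequence(entropy=seed, spawn_key=(0,))
    rng_place, rng_seq = (np.random.default_rng(s) for s in root.spawn(2))
    spec_lookup = {s.label: s for s in class_specs}

    # draw every peak's class, width, amplitude; then place
    draws: list[tuple[str, int, float, str]] = []
    for spec in class_specs:
        widths = rng_place.integers(spec.width_range[0], spec.width_range[1] + 1,
                                    size=spec.n_peaks)
        amps = rng_place.uniform(*spec.amplitude_range, size=spec.n_peaks)
        for w, a in zip(widths, amps):
            draws.append((spec.label, int(w), float(a), spec.profile))
    rng_place.shuffle(draws)

    chroms = sorted(genome)
    total_len = sum(genome.values())
    n_total = len(draws)
    # proportional split of peaks over chromosomes
    counts = [int(round(genome[c] / total_len * n_total)) for c in chroms]
    counts[-1] = n_total - sum(counts[:-1])

    planted: list[PlantedPeak] = []
    idx = 0
    peak_counter = 0
    for chrom, count in zip(chroms, counts):
        chunk = draws[idx: idx + count]
        idx += count
        occupied = sum(w for _, w, _, _ in chunk)
        slack = genome[chrom] - 2 * edge_margin - occupied - (count - 1) * min_separation
        if slack < 0:
            raise ValueError(
                f"genome too small: {chrom} cannot hold {count} peaks disjointly"
            )
        gaps = rng_place.multinomial(int(slack), np.ones(count + 1) / (count + 1))
        pos = edge_margin
        for (label, width, amp, profile), gap in zip(chunk, gaps[:-1]):
            pos += int(gap)
            name = f"{label}|{peak_counter:05d}"
            iv = GenomicInterval(chrom, pos, pos + width, name=name)
            planted.append(PlantedPeak(iv, label, amp, width, profile,
                                       dict(spec_lookup[label].antibody_scale)))
            pos += width + min_separation
            peak_counter += 1
    if idx != n_total:
        raise AssertionError("peak placement lost peaks")

    # sequences: random -> scrub -> plant
    spec_by_label = {s.label: s for s in class_specs}
    p_gc = gc_content / 2
    p = np.array([(1 - gc_content) / 2, p_gc, p_gc, (1 - gc_content) / 2])
    sequences: dict[str, str] = {}
    for chrom in chroms:
        arr = np.array(list(_BASES))[rng_seq.choice(4, size=genome[chrom], p=p)]
        _scrub_gcg(arr, rng_seq)
        for pk in planted:
            if pk.interval.chrom != chrom:
                continue
            spec = spec_by_label[pk.class_label]
            kb = pk.width / 1000.0
            n_good = int(round(spec.gcg_density * kb))
            n_bad = int(round(spec.decoy_gcg_density * kb))
            # shape-matching sites in the left half, decoys in the right:
            # the slot grids stay disjoint and counts remain exact
            mid = (pk.interval.start + pk.interval.end) // 2
            _plant_motifs(arr, pk.interval.start, mid, n_good, good_ctx, rng_seq)
            _plant_motifs(arr, mid, pk.interval.end, n_bad, bad_ctx, rng_seq)
        sequences[chrom] = "".join(arr)

    peaks = PeakSet([p.interval for p in planted], source="planted",
                    genome=dict(genome))
    planted_sorted = sorted(planted, key=lambda p: p.interval.sort_key())
    return Universe(peaks=peaks, sequences=sequences, planted=planted_sorted,
                    genome=dict(genome))


def _profile_rates(pk: PlantedPeak, bin_size: int, nbins: int) -> tuple[int, np.ndarray]:
    """Expected reads-per-bin contribution of one peak; (first_bin, rates)."""
    start_bin = pk.interval.start // bin_size
    end_bin = (pk.interval.end - 1) // bin_size + 1
    end_bin = min(end_bin, nbins)
    centers = (np.arange(start_bin, end_bin) + 0.5) * bin_size
    if pk.profile == "sharp-gaussian":
        sigma = pk.width / 4.0
        mu = pk.interval.center
        rates = pk.amplitude * np.exp(-0.5 * ((centers - mu) / sigma) ** 2)
    else:  # flat-plateau with 10% linear edge taper
        taper = 0.10 * pk.width
        left = np.clip((centers - pk.interval.start) / taper, 0.0, 1.0)
        right = np.clip((pk.interval.end - centers) / taper, 0.0, 1.0)
        rates = pk.amplitude * np.minimum(left, right)
    return start_bin, rates


def expected_rates(universe: Universe, condition: ConditionSpec,
                   bin_size: int = 50) -> dict[str, np.ndarray]:
    """Noise-free expected chip reads per bin for one condition."""
    rates = {}
    for chrom, length in universe.genome.items():
        nbins = -(-length // bin_size)
        arr = np.full(nbins, float(condition.background_rate))
        rates[chrom] = arr
    antibody = condition.sample_id[0]
    for pk in universe.planted:
        frac = condition.residual_fraction_by_class.get(pk.class_label)
        if frac is None:
            raise KeyError(f"no residual fraction for class {pk.class_label!r}")
        scale = frac * pk.antibody_scale.get(antibody, 1.0)
        if scale == 0:
            continue
        start_bin, contrib = _profile_rates(pk, bin_size, rates[pk.interval.chrom].size)
        rates[pk.interval.chrom][start_bin:start_bin + contrib.size] += scale * contrib
    return rates


def _draw_counts(rate: np.ndarray, dispersion: float,
                 rng: np.random.Generator) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(rate).astype(float)
    # gamma-Poisson mixture: mean = rate, variance = rate + dispersion * rate^2
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, rate * dispersion)
    return rng.poisson(lam).astype(float)


def simulate_coverage(universe: Universe, condition: ConditionSpec,
                      seed: int, bin_size: int = 50) -> tuple[CoverageTrack, CoverageTrack]:
    """Draw a (chip, input) track pair for one condition.

    Chip bins are Poisson with rate ``background + fraction × amplitude ×
    profile(bin)``; input bins are Poisson at the background rate alone.
    An optional negative-binomial dispersion adds overdispersion.
    """
    root = np.random.SeedSequence(entropy=seed,
                                  spawn_key=(1, _condition_key(condition)))
    rng_chip, rng_input = (np.random.default_rng(s) for s in root.spawn(2))
    chip_depth = {}
    input_depth = {}
    for chrom, rate in expected_rates(universe, condition, bin_size).items():
        chip_depth[chrom] = _draw_counts(rate, condition.dispersion, rng_chip)
        bg = np.full(rate.size, float(condition.background_rate))
        input_depth[chrom] = _draw_counts(bg, condition.dispersion, rng_input)
    chip = CoverageTrack(chip_depth, bin_size=bin_size,
                         library_size=condition.library_size,
                         sample_id=condition.sample_id,
                         spike_in_reads=condition.spike_in_reads,
                         genome=universe.genome)
    inp = CoverageTrack(input_depth, bin_size=bin_size,
                        library_size=condition.library_size,
                        sample_id=(condition.sample_id[0], condition.sample_id[1],
                                   condition.sample_id[2] + "+input"),
                        spike_in_reads=condition.spike_in_reads,
                        genome=universe.genome)
    return chip, inp


def _condition_key(condition: ConditionSpec) -> int:
    """Stable small integer derived from the sample id, for stream splitting."""
    s = "/".join(condition.sample_id)
    return int.from_bytes(s.encode(), "little") % (2 ** 31)


# ---------------------------------------------------------------------------
# default study design
# ---------------------------------------------------------------------------

#: The six planted signal classes: four narrow CpG-island-like classes and
#: two broad-domain classes (75 peaks each → 300 narrow + 150 broad).
#: The per-antibody amplitude multipliers make the six condition-profiles
#: roughly equidistant under Pearson distance (pairwise profile distances
#: 0.64-0.86 in the noise-free design), so the stratification problem has
#: six well-separated planted classes rather than a nested two-level split.
DEFAULT_CLASSES = (
    PeakClassSpec("narrow1", 75, (1000, 2000), (15.0, 30.0), "sharp-gaussian",
                  gcg_density=8.0, cpg_like=True,
                  antibody_scale={"EZH2": 0.41, "H3K27me3": 1.60,
                                  "MTF2": 0.20, "JARID2": 0.60}),
    PeakClassSpec("narrow2", 75, (1000, 2000), (15.0, 30.0), "sharp-gaussian",
                  gcg_density=8.0, cpg_like=True,
                  antibody_scale={"EZH2": 1.33, "H3K27me3": 0.65,
                                  "MTF2": 0.20, "JARID2": 0.52}),
    PeakClassSpec("narrow3", 75, (1000, 2000), (15.0, 30.0), "sharp-gaussian",
                  gcg_density=8.0, cpg_like=True,
                  antibody_scale={"EZH2": 0.65, "H3K27me3": 0.30,
                                  "MTF2": 0.80, "JARID2": 1.60}),
    PeakClassSpec("narrow4", 75, (1000, 2000), (15.0, 30.0), "sharp-gaussian",
                  gcg_density=8.0, cpg_like=True,
                  antibody_scale={"EZH2": 0.55, "H3K27me3": 1.42,
                                  "MTF2": 1.52, "JARID2": 0.42}),
    PeakClassSpec("broad5", 75, (4000, 8000), (8.0, 16.0), "flat-plateau",
                  gcg_density=1.0, cpg_like=False,
                  antibody_scale={"EZH2": 1.09, "H3K27me3": 0.69,
                                  "MTF2": 1.49, "JARID2": 0.67}),
    PeakClassSpec("broad6", 75, (4000, 8000), (8.0, 16.0), "flat-plateau",
                  gcg_density=1.0, cpg_like=False,
                  antibody_scale={"EZH2": 0.53, "H3K27me3": 0.92,
                                  "MTF2": 0.42, "JARID2": 0.90}),
)

DEFAULT_GENOME = {"chrS1": 5_000_000, "chrS2": 5_000_000}

# Per-condition residual fractions by class. Wild-type tracks carry 1.0
# everywhere (WT-relative percentages are per-cluster, so absolute
# class-to-class amplitude differences live in the amplitude ranges).
# Mutant/treatment fractions follow the quantified ranges of the study
# design this generator emulates: H3K27me3 in the Mtf2 mutant retains
# 6%-27% at narrow classes vs 48%-56% at broad ones, EZH2 9%-12% vs
# 23%-26%, JARID2 11%-19% vs 30%-34%, and EED-inhibitor treatment leaves
# 77% (EZH2), 85% (MTF2) and 41% (JARID2) residual binding, read as
# residual levels (see ``eed_inhibitor_as_reduction`` to flip the
# interpretation). The remaining contrasts distinguish the four narrow
# subclasses pairwise (each pair differs strongly in at least two
# conditions) and the two broad subclasses.
_F = {
    #                       n1    n2    n3    n4    b5    b6
    ("EZH2", "WT", "none"):          (1.00, 1.00, 1.00, 1.00, 1.00, 1.00),
    ("EZH2", "Mtf2GT", "none"):      (0.09, 0.10, 0.11, 0.12, 0.23, 0.26),
    ("EZH2", "Jarid2KO", "none"):    (0.90, 0.90, 0.05, 0.05, 0.70, 0.10),
    ("EZH2", "WT", "EED226"):        (0.77, 0.77, 0.77, 0.77, 0.50, 0.60),
    ("H3K27me3", "WT", "none"):      (1.00, 1.00, 1.00, 1.00, 1.00, 1.00),
    ("H3K27me3", "Mtf2GT", "none"):  (0.06, 0.27, 0.06, 0.27, 0.48, 0.56),
    ("H3K27me3", "Jarid2KO", "none"): (0.90, 0.05, 0.90, 0.05, 0.80, 0.25),
    ("MTF2", "WT", "none"):          (1.00, 1.00, 1.00, 1.00, 1.00, 1.00),
    ("MTF2", "Jarid2KO", "none"):    (0.90, 0.05, 0.05, 0.90, 0.25, 0.05),
    ("MTF2", "WT", "EED226"):        (0.85, 0.85, 0.85, 0.85, 0.40, 0.10),
    ("MTF2", "EedKO", "none"):       (0.90, 0.05, 0.90, 0.05, 0.05, 0.03),
    ("JARID2", "WT", "none"):        (1.00, 1.00, 1.00, 1.00, 1.00, 1.00),
    ("JARID2", "Mtf2GT", "none"):    (0.11, 0.14, 0.17, 0.19, 0.30, 0.34),
    ("JARID2", "WT", "EED226"):      (0.41, 0.41, 0.41, 0.41, 0.41, 0.41),
}

_CLASS_ORDER = ("narrow1", "narrow2", "narrow3", "narrow4", "broad5", "broad6")


def default_conditions(eed_inhibitor_as_reduction: bool = False) -> list[ConditionSpec]:
    """The 14-condition antibody × genotype × treatment grid.

    ``eed_inhibitor_as_reduction`` flips the reading of the EED-inhibitor
    percentages from residual levels (default) to amounts of reduction
    (residual = 1 − value) — both readings of an ambiguous figure-level
    statement are supported.
    """
    conditions = []
    for sample_id, fracs in _F.items():
        fracs = dict(zip(_CLASS_ORDER, fracs))
        if eed_inhibitor_as_reduction and sample_id[2] == "EED226":
            fracs = {k: 1.0 - v for k, v in fracs.items()}
        conditions.append(ConditionSpec(sample_id=sample_id,
                                        residual_fraction_by_class=fracs))
    return conditions


@dataclass
class StudyBundle:
    """In-memory synthetic study: ground truth, tracks and annotation."""

    universe: Universe
    conditions: list[ConditionSpec]
    tracks: dict[tuple[str, str, str], tuple[CoverageTrack, CoverageTrack]]
    shape_table: ShapeTable
    tss: list[tuple[str, str, int, str]]  # (gene_id, chrom, tss, strand)
    terms: dict[str, set[str]]
    peak_to_gene_truth: dict[str, str]
    seed: int
    bin_size: int


def _annotate_genes(universe: Universe, seed: int,
                    n_background_genes: int = 2000,
                    tss_jitter: int = 1000,
                    clearance: int = 15000):
    """One gene per peak (TSS jittered around the peak center) plus
    background genes kept clear of every peak."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))
    tss: list[tuple[str, str, int, str]] = []
    peak_to_gene: dict[str, str] = {}
    for pk in universe.planted:
        gene = f"g{pk.interval.name.replace('|', '_')}"
        pos = pk.interval.center + int(rng.integers(-tss_jitter, tss_jitter + 1))
        pos = max(0, min(pos, universe.genome[pk.interval.chrom] - 1))
        strand = "+-"[rng.integers(2)]
        tss.append((gene, pk.interval.chrom, pos, strand))
        peak_to_gene[pk.interval.name] = gene

    starts = {c: np.array(sorted(p.interval.start for p in universe.planted
                                 if p.interval.chrom == c))
              for c in universe.genome}
    ends = {c: np.array(sorted(p.interval.end for p in universe.planted
                               if p.interval.chrom == c))
            for c in universe.genome}
    chroms = sorted(universe.genome)
    placed = 0
    while placed < n_background_genes:
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(0, universe.genome[chrom]))
        i = np.searchsorted(starts[chrom], pos)
        near = False
        if i < starts[chrom].size and starts[chrom][i] - pos < clearance:
            near = True
        if i > 0 and pos - ends[chrom][i - 1] < clearance:
            near = True
        if near:
            continue
        strand = "+-"[rng.integers(2)]
        tss.append((f"bg{placed:05d}", chrom, pos, strand))
        placed += 1
    return tss, peak_to_gene, rng


def _build_terms(universe: Universe, peak_to_gene: dict[str, str],
                 tss: list[tuple[str, str, int, str]],
                 rng: np.random.Generator,
                 n_decoy_terms: int = 20, decoy_size: int = 50):
    """Planted term structure.

    ``body_plan_patterning`` collects the genes of the broad classes (the
    Hox-like compartment: enriched both against all genes and within
    PRC2-target genes). ``polycomb_target`` spans *all* peak genes, so it
    is enriched against the all-genes background but flat within PRC2
    targets. ``neural_structures`` marks two narrow subclasses. Decoy
    terms are random gene draws.
    """
    class_of = universe.class_of()
    all_genes = [g for g, _, _, _ in tss]
    peak_genes = set(peak_to_gene.values())
    broad = {g for p, g in peak_to_gene.items()
             if class_of[p].startswith("broad")}
    neural = {g for p, g in peak_to_gene.items()
              if class_of[p] in ("narrow2", "narrow4")}
    terms: dict[str, set[str]] = {
        "body_plan_patterning": set(broad),
        "polycomb_target": set(peak_genes),
        "neural_structures": set(neural),
    }
    for t in range(n_decoy_terms):
        pick = rng.choice(len(all_genes), size=decoy_size, replace=False)
        terms[f"decoy_{t:02d}"] = {all_genes[i] for i in pick}
    return terms


def simulate_study(seed: int,
                   class_specs: Sequence[PeakClassSpec] = DEFAULT_CLASSES,
                   genome: Mapping[str, int] = DEFAULT_GENOME,
                   conditions: Sequence[ConditionSpec] | None = None,
                   bin_size: int = 50,
                   shape_seed: int = 0) -> StudyBundle:
    """Generate the full study in memory (no files written)."""
    table = synthetic_twist_table(seed=shape_seed)
    universe = generate_universe(class_specs, genome, seed, shape_table=table)
    if conditions is None:
        conditions = default_conditions()
    labels_present = {s.label for s in class_specs}
    for cond in conditions:
        missing = labels_present - set(cond.residual_fraction_by_class)
        if missing:
            raise KeyError(f"{cond.sample_id}: no residual fraction for {missing}")
    tracks = {
        cond.sample_id: simulate_coverage(universe, cond, seed, bin_size)
        for cond in conditions
    }
    tss, peak_to_gene, rng = _annotate_genes(universe, seed)
    terms = _build_terms(universe, peak_to_gene, tss, rng)
    return StudyBundle(universe=universe, conditions=list(conditions),
                       tracks=tracks, shape_table=table, tss=tss, terms=terms,
                       peak_to_gene_truth=peak_to_gene, seed=seed,
                       bin_size=bin_size)


def write_study(bundle: StudyBundle, outdir: str | Path) -> dict:
    """Write a :class:`StudyBundle` to disk; returns the manifest.

    Emits peaks BED (class label in the name field), genome FASTA,
    per-condition chip/input bedGraph pairs, a sample sheet TSV, TSS BED,
    term→gene TSV, the pentamer twist table, and ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bed(bundle.universe.peaks, outdir / "peaks.bed")
    with open(outdir / "genome.fa", "w") as fh:
        for chrom in sorted(bundle.universe.sequences):
            fh.write(f">{chrom}\n")
            seq = bundle.universe.sequences[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    write_shape_table(bundle.shape_table, outdir / "twist.tsv")

    rows = []
    for cond in bundle.conditions:
        chip, inp = bundle.tracks[cond.sample_id]
        stem = "_".join(cond.sample_id).replace("+", "")
        chip_path = outdir / f"{stem}.chip.bedgraph"
        input_path = outdir / f"{stem}.input.bedgraph"
        write_bedgraph(chip, chip_path)
        write_bedgraph(inp, input_path)
        rows.append((stem, *cond.sample_id, chip_path.name, input_path.name,
                     f"{cond.library_size:g}", f"{cond.spike_in_reads:g}"))
    with open(outdir / "samples.tsv", "w") as fh:
        fh.write("sample_id\tantibody\tgenotype\ttreatment\tchip_track\t"
                 "input_track\tlibrary_size\tspike_in_reads\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")

    with open(outdir / "tss.bed", "w") as fh:
        for gene, chrom, pos, strand in sorted(
                bundle.tss, key=lambda t: (t[1], t[2], t[0])):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{gene}\t0\t{strand}\n")
    with open(outdir / "terms.tsv", "w") as fh:
        for term in sorted(bundle.terms):
            for gene in sorted(bundle.terms[term]):
                fh.write(f"{term}\t{gene}\n")

    manifest = {
        "seed": bundle.seed,
        "bin_size": bundle.bin_size,
        "genome": bundle.universe.genome,
        "classes": [
            {"label": s, "n_peaks": int(sum(p.class_label == s
                                            for p in bundle.universe.planted))}
            for s in sorted({p.class_label for p in bundle.universe.planted})
        ],
        "conditions": [
            {"sample_id": list(c.sample_id),
             "residual_fraction_by_class": c.residual_fraction_by_class,
             "background_rate": c.background_rate,
             "library_size": c.library_size,
             "global_efficiency": c.global_efficiency,
             "spike_in_reads": c.spike_in_reads,
             "dispersion": c.dispersion}
            for c in bundle.conditions
        ],
        "files": sorted(p.name for p in outdir.iterdir()
                        if p.name != "manifest.json"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def default_study(outdir: str | Path, seed: int) -> StudyBundle:
    """Generate the default 6-class, 14-condition study and write it."""
    bundle = simulate_study(seed)
    write_study(bundle, outdir)
    return bundle


def recovery_study(fractions: Sequence[float], seed: int,
                   n_peaks: int = 300,
                   antibody: str = "EZH2") -> StudyBundle:
    """A single-class study for residual-fraction parameter recovery.

    One narrow class of ``n_peaks`` peaks; one wild-type condition plus
    one condition per requested fraction, all sharing the input design.
    """
    class_specs = [PeakClassSpec("narrow1", n_peaks, (1000, 2000),
                                 (15.0, 30.0), "sharp-gaussian",
                                 gcg_density=8.0, cpg_like=True)]
    genome = {"chrS1": 4_000_000 + n_peaks * 7000}
    conditions = [ConditionSpec((antibody, "WT", "none"), {"narrow1": 1.0})]
    for f in fractions:
        conditions.append(ConditionSpec(
            (antibody, f"mut_f{int(round(1000 * f)):04d}", "none"),
            {"narrow1": float(f)}))
    return simulate_study(seed, class_specs=class_specs, genome=genome,
                          conditions=conditions)
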