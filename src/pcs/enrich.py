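"""Peak-to-gene assignment and hypergeometric term enrichment.

Each peak is associated with the gene whose TSS is nearest to the peak
center (within ``max_distance``); per-cluster gene sets are then tested
for term over-representation with the upper-tail hypergeometric test,
against either the all-genes background or the PRC2-target (peak-gene)
background, with Benjamini-Hochberg correction across terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from pcs.intervals import PeakSet


@dataclass
class GeneAnnotation:
    """Gene id → (chrom, tss, strand); TSS is a single base position."""

    tss: dict[str, tuple[str, int, str]]

    def __post_init__(self) -> None:
        if not self.tss:
            raise ValueError("annotation is empty")

    @classmethod
    def from_bed(cls, path: str | Path) -> "GeneAnnotation":
        """Read a 6-column TSS BED (1 bp intervals; strand column 6)."""
        tss = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith(("track", "browser", "#")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: need chrom/start/end/name")
                chrom, start = fields[0], int(fields[1])
                gene = fields[3]
                strand = fields[5] if len(fields) > 5 else "+"
                if gene in tss:
                    raise ValueError(f"{path}:{lineno}: duplicate gene id {gene!r}")
                tss[gene] = (chrom, start, strand)
        return cls(tss)


def assign_peaks_to_genes(peaks: PeakSet, annotation: GeneAnnotation,
                          max_distance: int = 10_000) -> tuple[dict[str, str], list[str]]:
    """Map each peak to the gene with the nearest TSS within range.

    Distance is measured from the peak center; ties resolve to the
    lexicographically smaller gene id. Returns (peak_id → gene_id,
    list of unassigned peak ids).
    """
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for gene, (chrom, pos, _strand) in annotation.tss.items():
        by_chrom.setdefault(chrom, []).append((pos, gene))
    arrays = {}
    for chrom, entries in by_chrom.items():
        entries.sort()
        arrays[chrom] = (np.array([p for p, _ in entries]),
                         [g for _, g in entries])

    mapping: dict[str, str] = {}
    unassigned: list[str] = []
    for i, iv in enumerate(peaks):
        pid = iv.name if iv.name is not None else f"peak_{i:06d}"
        if iv.chrom not in arrays:
            unassigned.append(pid)
            continue
        positions, genes = arrays[iv.chrom]
        center = iv.center
        j = int(np.searchsorted(positions, center))
        best: tuple[int, str] | None = None
        for cand in (j - 1, j, j + 1):
            if 0 <= cand < positions.size:
                d = abs(int(positions[cand]) - center)
                key = (d, genes[cand])
                if best is None or key < best:
                    best = key
        # same-position duplicates: scan neighbours at the best distance
        if best is not None and best[0] <= max_distance:
            d_best = best[0]
            lo = int(np.searchsorted(positions, center - d_best, side="left"))
            hi = int(np.searchsorted(positions, center + d_best, side="right"))
            for cand in range(lo, hi):
                d = abs(int(positions[cand]) - center)
                key = (d, genes[cand])
                if key < best:
                    best = key
            mapping[pid] = best[1]
        else:
            unassigned.append(pid)
    return mapping, unassigned


@dataclass
class EnrichmentResult:
    """Hypergeometric enrichment of one term in one foreground set."""

    term: str
    cluster: int | None
    overlap: int
    fg_size: int
    term_size: int
    bg_size: int
    fold: float
    p: float
    q: float | None = None

    def __post_init__(self) -> None:
        if self.overlap > min(self.fg_size, self.term_size):
            raise ValueError("overlap exceeds set sizes")


def hypergeometric_enrichment(fg_genes: set, term_genes: set, bg_genes: set,
                              term: str = "", cluster: int | None = None) -> EnrichmentResult:
    """Upper-tail hypergeometric probability of the observed overlap.

    ``p = P(X >= overlap)`` for X hypergeometric with population
    ``bg_size``, ``term ∩ bg`` successes and ``fg_size`` draws. The
    foreground must be a subset of the background; the term is restricted
    to the background before testing. Fold enrichment is
    ``(overlap/fg) / (term/bg)``.
    """
    if not bg_genes:
        raise ValueError("background is empty")
    if not fg_genes <= bg_genes:
        raise ValueError("foreground must be a subset of the background")
    term_in_bg = term_genes & bg_genes
    overlap = len(fg_genes & term_in_bg)
    fg, t, bg = len(fg_genes), len(term_in_bg), len(bg_genes)
    if fg == 0 or t == 0:
        p, fold = 1.0, 0.0
    else:
        p = float(stats.hypergeom.sf(overlap - 1, bg, t, fg))
        fold = (overlap / fg) / (t / bg)
    return EnrichmentResult(term=term, cluster=cluster, overlap=overlap,
                            fg_size=fg, term_size=t, bg_size=bg,
                            fold=fold, p=min(p, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (capped at 1).

    Zero is accepted as the underflowed limit of an extremely small tail
    probability; negative or >1 values are rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cluster_enrichment(cluster_genes: dict[int, set],
                       terms: dict[str, set],
                       background: set,
                       min_term_size: int = 3) -> pd.DataFrame:
    """Test every (cluster × term) pair against one background.

    ``background`` is either all genes or the PRC2-target genes (the union
    of peak-associated genes); foregrounds are intersected with it. Terms
    with fewer than ``min_term_size`` background genes are skipped and
    reported in ``DataFrame.attrs["skipped_terms"]``. q-values are BH
    across terms within each cluster.
    """
    rows = []
    skipped = sorted(t for t, genes in terms.items()
                     if len(genes & background) < min_term_size)
    for cluster in sorted(cluster_genes):
        fg = cluster_genes[cluster] & background
        results = [
            hypergeometric_enrichment(fg, terms[t], background, term=t,
                                      cluster=cluster)
            for t in sorted(terms) if t not in skipped
        ]
        if not results:
            continue
        q = bh_adjust([r.p for r in results])
        for r, qv in zip(results, q):
            rows.append({"cluster": cluster, "term": r.term,
                         "overlap": r.overlap, "fg_size": r.fg_size,
                         "term_size": r.term_size, "bg_size": r.bg_size,
                         "fold": r.fold, "p": r.p, "q": float(qv)})
    table = pd.DataFrame(rows)
    table.attrs["skipped_terms"] = skipped
    return table


def read_term_map(path: str | Path) -> dict[str, set]:
    """Read a two-column TSV (term, gene) into term → gene-set."""
    terms: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            terms.setdefault(fields[0], set()).add(fields[1])
    return terms
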