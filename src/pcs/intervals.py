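"""Genomic intervals and peak sets.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
The center of an interval is ``floor((start + end) / 2)``; one convention is
used throughout the package so that window extraction, peak-to-gene distance
and motif positions never drift by one base.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class PeakSet:
    """An ordered collection of peaks, sorted by (chrom, start, end).

    Parameters
    ----------
    intervals:
        The peaks; they are sorted on construction.
    source:
        A label for provenance — an antibody name, or ``"common"`` for a
        merged multi-mark universe.
    genome:
        Optional chromosome-name → length map. When given, every interval
        must fit inside its chromosome.
    """

    intervals: list[GenomicInterval] = field(default_factory=list)
    source: str = ""
    genome: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=GenomicInterval.sort_key)
        if self.genome is not None:
            for iv in self.intervals:
                if iv.chrom not in self.genome:
                    raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
                if iv.end > self.genome[iv.chrom]:
                    raise ValueError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                        f"chromosome length {self.genome[iv.chrom]}"
                    )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def names(self) -> list[str | None]:
        return [iv.name for iv in self.intervals]

    def subset(self, indices: Iterable[int], source: str | None = None) -> "PeakSet":
        ivs = [self.intervals[i] for i in indices]
        return PeakSet(ivs, source=source or self.source, genome=self.genome)


def read_bed(path: str | Path, source: str = "",
             genome: Mapping[str, int] | None = None) -> PeakSet:
    """Read a BED file (>= 3 tab-separated columns) into a :class:`PeakSet`.

    Malformed lines raise; they are never silently skipped. Blank lines and
    ``track``/``browser``/``#`` header lines are ignored.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, score))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(intervals, source=source or path.stem, genome=genome)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write a :class:`PeakSet` as BED. Round-trips coordinates bit-exactly."""
    with open(path, "w") as fh:
        for iv in peaks:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                cols.append(repr(iv.score))
            fh.write("\t".join(cols) + "\n")


def merge_union(peak_sets: list[PeakSet], gap: int = 0,
                source: str = "common") -> PeakSet:
    """Union-merge several peak sets into one non-overlapping universe.

    Intervals closer than or equal to ``gap`` bp (or overlapping/bookended)
    are fused. Output intervals are pairwise separated by more than ``gap``
    and jointly cover exactly the union of the input base pairs (plus the
    fused gaps). Names and scores are dropped: a merged region is a new
    object, not any single input peak.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    genomes = [ps.genome for ps in peak_sets if ps.genome is not None]
    for g in genomes[1:]:
        if dict(g) != dict(genomes[0]):
            raise ValueError("peak sets come from inconsistent genomes")
    genome = genomes[0] if genomes else None

    all_ivs = sorted(
        (iv for ps in peak_sets for iv in ps), key=GenomicInterval.sort_key
    )
    merged: list[GenomicInterval] = []
    for iv in all_ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end + gap:
            if iv.end > merged[-1].end:
                merged[-1] = replace(merged[-1], end=iv.end, name=None, score=None)
        else:
            merged.append(replace(iv, name=None, score=None))
    return PeakSet(merged, source=source, genome=genome)
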