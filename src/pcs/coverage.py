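"""Binned coverage tracks and peak-centered signal matrices.

A :class:`CoverageTrack` stores read depth per fixed-size bin for each
chromosome, together with the library metadata (total mapped reads,
optional spike-in read count) needed for normalization.
:func:`extract_signal_matrix` turns a track plus a peak set into the
peaks × bins matrix that clustering and quantification operate on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from pcs.intervals import PeakSet

#: Allowed normalization tags, in the order transitions may occur.
NORMALIZATION_TAGS = ("raw", "rpkm", "input_subtracted", "wt_normalized", "spikein_scaled")


@dataclass
class CoverageTrack:
    """Read depth at fixed bin resolution, per chromosome.

    ``depth[chrom][i]`` is the read count assigned to bin
    ``[i * bin_size, (i+1) * bin_size)`` (reads whose assigned position
    falls inside the bin). Arrays cover the chromosome:
    ``len(depth[chrom]) * bin_size >= genome[chrom]``.
    """

    depth: dict[str, np.ndarray]
    bin_size: int
    library_size: float
    sample_id: tuple[str, str, str] = ("", "", "")  # (antibody, genotype, treatment)
    spike_in_reads: float | None = None
    genome: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        for chrom, arr in self.depth.items():
            arr = np.asarray(arr, dtype=float)
            if (arr < 0).any():
                raise ValueError(f"negative depth on {chrom}")
            self.depth[chrom] = arr
            if self.genome is not None and chrom in self.genome:
                if arr.size * self.bin_size < self.genome[chrom]:
                    raise ValueError(
                        f"{chrom}: {arr.size} bins of {self.bin_size} bp do not "
                        f"cover chromosome length {self.genome[chrom]}"
                    )

    def scaled(self, factor: float) -> "CoverageTrack":
        """Return a copy with every depth multiplied by ``factor``."""
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return CoverageTrack(
            {c: a * factor for c, a in self.depth.items()},
            bin_size=self.bin_size,
            library_size=self.library_size,
            sample_id=self.sample_id,
            spike_in_reads=self.spike_in_reads,
            genome=self.genome,
        )

    def mean_depth(self) -> float:
        """Track-wide mean per-bin depth (the background estimate)."""
        total = sum(float(a.sum()) for a in self.depth.values())
        nbins = sum(a.size for a in self.depth.values())
        return total / nbins if nbins else 0.0


@dataclass
class SignalMatrix:
    """Peaks × bins signal for one sample, peak-centered.

    Row ``i`` is the binned mean depth over
    ``[center_i - window_half_width, center_i + window_half_width)``.
    Row order matches the :class:`~pcs.intervals.PeakSet` it was built from.
    """

    values: np.ndarray
    peak_ids: list[str]
    window_half_width: int
    bin_size: int
    sample_id: tuple[str, str, str] = ("", "", "")
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (peaks x bins)")
        expected = 2 * self.window_half_width // self.bin_size
        if self.values.shape[1] != expected:
            raise ValueError(
                f"expected {expected} columns for half-width "
                f"{self.window_half_width} at {self.bin_size} bp bins, "
                f"got {self.values.shape[1]}"
            )
        if len(self.peak_ids) != self.values.shape[0]:
            raise ValueError("one peak_id per row required")
        if self.normalization not in NORMALIZATION_TAGS:
            raise ValueError(f"unknown normalization tag {self.normalization!r}")

    @property
    def n_peaks(self) -> int:
        return self.values.shape[0]

    def row_means(self) -> np.ndarray:
        return self.values.mean(axis=1)

    def save(self, path: str | Path) -> None:
        """Archive to ``.npz``; all fields round-trip."""
        meta = {
            "peak_ids": self.peak_ids,
            "window_half_width": self.window_half_width,
            "bin_size": self.bin_size,
            "sample_id": list(self.sample_id),
            "normalization": self.normalization,
        }
        np.savez(path, values=self.values, meta=json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "SignalMatrix":
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["meta"]))
            return cls(
                values=npz["values"],
                peak_ids=list(meta["peak_ids"]),
                window_half_width=int(meta["window_half_width"]),
                bin_size=int(meta["bin_size"]),
                sample_id=tuple(meta["sample_id"]),
                normalization=meta["normalization"],
            )


def read_bedgraph(path: str | Path, genome: Mapping[str, int], bin_size: int,
                  library_size: float,
                  sample_id: tuple[str, str, str] = ("", "", ""),
                  spike_in_reads: float | None = None) -> CoverageTrack:
    """Read a 4-column bedGraph (0-based half-open) into a binned track.

    Each bedGraph record's value is spread over the bins it covers,
    weighted by overlap, so the binned track preserves per-bp means.
    """
    depth = {
        chrom: np.zeros(-(-length // bin_size), dtype=float)
        for chrom, length in genome.items()
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: fewer than 4 bedGraph columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in depth:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if not (0 <= start < end <= genome[chrom]):
                raise ValueError(f"{path}:{lineno}: bad interval [{start}, {end})")
            first, last = start // bin_size, (end - 1) // bin_size
            for b in range(first, last + 1):
                lo = max(start, b * bin_size)
                hi = min(end, (b + 1) * bin_size)
                depth[chrom][b] += value * (hi - lo) / bin_size
    return CoverageTrack(depth, bin_size=bin_size, library_size=library_size,
                         sample_id=sample_id, spike_in_reads=spike_in_reads,
                         genome=genome)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write one bedGraph record per bin (zero-depth bins are skipped).

    Consecutive equal-valued bins are collapsed into a single record.
    """
    if track.genome is None:
        raise ValueError("track needs a genome map to clip the last bin")
    with open(path, "w") as fh:
        for chrom in sorted(track.depth):
            arr = track.depth[chrom]
            length = track.genome[chrom]
            run_start = 0
            for i in range(1, arr.size + 1):
                if i == arr.size or arr[i] != arr[run_start]:
                    v = arr[run_start]
                    if v != 0.0:
                        s = run_start * track.bin_size
                        e = min(i * track.bin_size, length)
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
                    run_start = i


def read_bigwig(path: str | Path, bin_size: int, library_size: float,
                sample_id: tuple[str, str, str] = ("", "", ""),
                spike_in_reads: float | None = None) -> CoverageTrack:
    """Read a bigWig file into a binned track (requires pyBigWig)."""
    import pyBigWig  # optional dependency

    bw = pyBigWig.open(str(path))
    try:
        genome = dict(bw.chroms())
        depth = {}
        for chrom, length in genome.items():
            nbins = -(-length // bin_size)
            vals = bw.stats(chrom, 0, length, type="mean", nBins=nbins, exact=True)
            depth[chrom] = np.array([v if v is not None else 0.0 for v in vals])
    finally:
        bw.close()
    return CoverageTrack(depth, bin_size=bin_size, library_size=library_size,
                         sample_id=sample_id, spike_in_reads=spike_in_reads,
                         genome=genome)


def extract_signal_matrix(track: CoverageTrack, peaks: PeakSet,
                          half_window: int = 1000,
                          bin_size: int | None = None) -> SignalMatrix:
    """Extract the peak-centered binned signal matrix for one track.

    Row ``i`` holds the mean depth per bin over
    ``[center - half_window, center + half_window)`` of peak ``i``, where
    ``center = floor((start + end) / 2)``. Windows that extend past a
    chromosome edge are zero-padded. A peak on a chromosome the track does
    not cover is a hard error — silent zeros would corrupt downstream
    wild-type-relative percentages.
    """
    if bin_size is None:
        bin_size = track.bin_size
    if bin_size != track.bin_size:
        raise ValueError(
            f"requested bin_size {bin_size} != track bin_size {track.bin_size}; "
            "re-bin the track first"
        )
    if half_window % bin_size != 0:
        raise ValueError("half_window must be a multiple of bin_size")
    if len(peaks) == 0:
        raise ValueError("peak set is empty")

    nbins = 2 * half_window // bin_size
    half_bins = nbins // 2
    values = np.zeros((len(peaks), nbins), dtype=float)
    peak_ids = []
    for i, iv in enumerate(peaks):
        if iv.chrom not in track.depth:
            raise KeyError(f"peak chromosome {iv.chrom!r} absent from track")
        arr = track.depth[iv.chrom]
        center_bin = iv.center // bin_size
        lo, hi = center_bin - half_bins, center_bin + half_bins
        src_lo, src_hi = max(lo, 0), min(hi, arr.size)
        if src_hi > src_lo:
            values[i, src_lo - lo: src_hi - lo] = arr[src_lo:src_hi]
        peak_ids.append(iv.name if iv.name is not None else f"peak_{i:06d}")
    return SignalMatrix(values, peak_ids, half_window, bin_size,
                        sample_id=track.sample_id, normalization="raw")


def occupancy_fraction(query: SignalMatrix, background_mean: float,
                       enrichment_threshold: float = 2.0) -> float:
    """Fraction of peaks whose mean window signal exceeds the background.

    A row counts as occupied when its mean exceeds
    ``enrichment_threshold × background_mean``, where ``background_mean``
    is the track-wide mean depth (see :meth:`CoverageTrack.mean_depth`).
    Quantifies co-occupancy of a mark over a reference peak universe.
    """
    if background_mean <= 0:
        raise ValueError("background mean must be positive")
    return float(np.mean(query.row_means() > enrichment_threshold * background_mean))


def occupied_rows(query: SignalMatrix, background_mean: float,
                  enrichment_threshold: float = 2.0) -> np.ndarray:
    """Boolean per-row occupancy under the same criterion as
    :func:`occupancy_fraction`."""
    if background_mean <= 0:
        raise ValueError("background mean must be positive")
    return query.row_means() > enrichment_threshold * background_mean
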