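"""Signal normalization: RPKM, input subtraction, WT-relative percentages,
spike-in scaling, and the spike-in vs per-million concordance diagnostic.

The per-peak read count is derived from binned coverage — mean depth ×
region length in bins — so the coverage track is the single source of
truth and no BAM recount is needed. Negative input-subtracted values are
retained: clamping before medians would bias cluster-level quantification
(floor at zero only when rendering heatmaps).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from pcs.coverage import CoverageTrack, SignalMatrix


@dataclass(frozen=True)
class NormalizedValue:
    """A single quantified signal with its normalization provenance."""

    value: float
    normalization: str
    sample_id: tuple[str, str, str] = ("", "", "")
    region_id: str = ""


#: Legal normalization-tag transitions; a value is never WT-normalized twice.
_TRANSITIONS = {
    "raw": {"rpkm", "spikein_scaled"},
    "rpkm": {"input_subtracted"},
    "input_subtracted": {"wt_normalized", "spikein_scaled"},
    "spikein_scaled": set(),
    "wt_normalized": set(),
}


def rpkm(read_count: float, region_length: int, library_size: float) -> float:
    """Reads per kilobase of region per million mapped reads.

    ``read_count / ((region_length / 1e3) * (library_size / 1e6))``.
    """
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return read_count / ((region_length / 1e3) * (library_size / 1e6))


def matrix_rpkm(matrix: SignalMatrix, library_size: float) -> SignalMatrix:
    """RPKM-normalize a signal matrix bin-wise.

    Bin values are read counts, so each bin of length ``bin_size`` has
    RPKM ``count * 1e9 / (bin_size * library_size)``; the mean over a
    window's bins then equals the whole-window RPKM exactly.
    """
    if matrix.normalization != "raw":
        raise ValueError(f"expected a raw matrix, got {matrix.normalization!r}")
    factor = 1e9 / (matrix.bin_size * library_size)
    return replace(matrix, values=matrix.values * factor, normalization="rpkm")


def input_subtract(chip: SignalMatrix, input_: SignalMatrix) -> SignalMatrix:
    """Per-bin input subtraction of two RPKM matrices over the same peaks.

    Negative values are retained (no clamping).
    """
    for m, label in ((chip, "chip"), (input_, "input")):
        if m.normalization != "rpkm":
            raise ValueError(f"{label} matrix must be rpkm, got {m.normalization!r}")
    if chip.peak_ids != input_.peak_ids:
        raise ValueError("chip and input matrices cover different peaks")
    if chip.values.shape != input_.values.shape:
        raise ValueError("chip and input matrices have different shapes")
    return replace(chip, values=chip.values - input_.values,
                   normalization="input_subtracted")


def subtract_values(chip: NormalizedValue, input_: NormalizedValue) -> NormalizedValue:
    """Scalar form of :func:`input_subtract` for single-region values."""
    if chip.normalization != "rpkm" or input_.normalization != "rpkm":
        raise ValueError("both values must be rpkm-normalized")
    if chip.region_id != input_.region_id:
        raise ValueError("values quantify different regions")
    return NormalizedValue(chip.value - input_.value, "input_subtracted",
                           chip.sample_id, chip.region_id)


def wt_percent(condition_stat: float, wt_stat: float) -> float:
    """Express a condition-level statistic as a percentage of wild type."""
    if wt_stat == 0:
        raise ZeroDivisionError("wild-type statistic is zero; percentage undefined")
    return 100.0 * condition_stat / wt_stat


def spike_in_scale(track: CoverageTrack, reference_spike_reads: float) -> CoverageTrack:
    """Scale a track by its exogenous spike-in reads.

    Depths are multiplied by ``reference_spike_reads / track.spike_in_reads``,
    putting samples sequenced with the same spike-in ratio on a common
    absolute scale regardless of genome-wide signal loss.
    """
    if track.spike_in_reads is None or track.spike_in_reads <= 0:
        raise ValueError("track has no usable spike-in read count")
    if reference_spike_reads <= 0:
        raise ValueError("reference spike-in read count must be positive")
    return track.scaled(reference_spike_reads / track.spike_in_reads)


def normalization_concordance(values_a, values_b) -> float:
    """Pearson correlation of paired per-region quantifications.

    The diagnostic used to check that spike-in scaling and per-million
    (RPKM) scaling tell the same story across regions.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D and of equal length")
    if a.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in one of the inputs")
    return float(stats.pearsonr(a, b).statistic)


def peak_rpkm_values(chip: SignalMatrix, input_: SignalMatrix | None,
                     chip_library: float,
                     input_library: float | None = None) -> np.ndarray:
    """Per-peak (optionally input-subtracted) RPKM over the matrix window.

    Convenience for quantification: RPKM-normalizes chip (and input), does
    per-bin subtraction, then averages bins per peak.
    """
    chip_n = matrix_rpkm(chip, chip_library)
    if input_ is None:
        return chip_n.row_means()
    if input_library is None:
        raise ValueError("input_library required when an input matrix is given")
    input_n = matrix_rpkm(input_, input_library)
    return input_subtract(chip_n, input_n).row_means()
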