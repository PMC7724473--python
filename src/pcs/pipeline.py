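"""Convenience pipeline steps tying the modules together.

These helpers reproduce the standard analysis path on a synthetic
:class:`~pcs.simulate.StudyBundle`: extract peak-centered matrices per
condition, quantify per-peak input-subtracted RPKM, build the clustering
feature matrix, and express cluster-level bootstrap estimates relative to
wild type.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from pcs.bootstrap import summarize
from pcs.cluster import ClusterAssignment, build_feature_matrix, kmeans_correlation
from pcs.coverage import SignalMatrix, extract_signal_matrix
from pcs.normalize import peak_rpkm_values
from pcs.simulate import StudyBundle


def bundle_matrices(bundle: StudyBundle, half_window: int = 1000
                    ) -> dict[tuple[str, str, str], tuple[SignalMatrix, SignalMatrix]]:
    """Peak-centered (chip, input) signal matrices for every condition."""
    out = {}
    for cond in bundle.conditions:
        chip, inp = bundle.tracks[cond.sample_id]
        out[cond.sample_id] = (
            extract_signal_matrix(chip, bundle.universe.peaks, half_window),
            extract_signal_matrix(inp, bundle.universe.peaks, half_window),
        )
    return out


def per_peak_quant(bundle: StudyBundle, half_window: int = 1000
                   ) -> dict[tuple[str, str, str], np.ndarray]:
    """Per-peak input-subtracted RPKM over the quantification window."""
    values = {}
    for cond in bundle.conditions:
        chip, inp = bundle.tracks[cond.sample_id]
        chip_m = extract_signal_matrix(chip, bundle.universe.peaks, half_window)
        inp_m = extract_signal_matrix(inp, bundle.universe.peaks, half_window)
        values[cond.sample_id] = peak_rpkm_values(
            chip_m, inp_m, chip.library_size, inp.library_size)
    return values


def clustering_features(bundle: StudyBundle, half_window: int = 1000,
                        block_standardize: bool = False) -> np.ndarray:
    """Concatenated chip windows over all conditions, sample-sheet order."""
    matrices = [bundle_matrices(bundle, half_window)[c.sample_id][0]
                for c in bundle.conditions]
    return build_feature_matrix(matrices, block_standardize=block_standardize)


def cluster_bundle(bundle: StudyBundle, k: int, seed: int,
                   half_window: int = 1000, n_init: int = 10) -> ClusterAssignment:
    X = clustering_features(bundle, half_window)
    return kmeans_correlation(X, [iv.name for iv in bundle.universe.peaks],
                              k=k, seed=seed, n_init=n_init)


def quantify_clusters(bundle: StudyBundle, assignment: ClusterAssignment,
                      antibody: str, n_boot: int = 1000, level: float = 99.9,
                      seed: int = 0, half_window: int = 1000) -> pd.DataFrame:
    """Bootstrap cluster quantification for one antibody, WT-normalized.

    Returns the summary table with a ``wt_percent`` column relative to the
    same antibody's (WT, untreated) condition, per cluster.
    """
    values = {sid: v for sid, v in per_peak_quant(bundle, half_window).items()
              if sid[0] == antibody}
    wt_key = (antibody, "WT", "none")
    if wt_key not in values:
        raise KeyError(f"no wild-type condition for antibody {antibody!r}")
    return summarize(values, assignment, n_boot=n_boot, level=level,
                     seed=seed, wt_key=wt_key)
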