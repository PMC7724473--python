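"""Cluster-level bootstrap quantification.

Peaks are the exchangeable units: each bootstrap round resamples the peaks
of one cluster with replacement and records the median (and mean) of the
per-peak normalized signal. A cluster/condition cell is then reported as
the bootstrap-median point estimate with a central percentile confidence
interval. Following the figure convention this package reproduces, the
plotted dots are the bootstrapped *medians* while the interval is the
percentile CI of the bootstrapped *means*; a switch selects CI-of-medians
for users who prefer a single statistic throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pcs.cluster import ClusterAssignment
from pcs.normalize import wt_percent


def _resample_stats(values, n_boot: int,
                    seed: int | None) -> tuple[np.ndarray, np.ndarray]:
    """(medians, means) over with-replacement resamples, integer indices only."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    medians = np.empty(n_boot)
    means = np.empty(n_boot)
    # chunk to bound memory at ~8 MB regardless of n_boot
    chunk = max(1, min(n_boot, int(1e6) // max(values.size, 1) + 1))
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        idx = rng.integers(0, values.size, size=(m, values.size))
        draws = values[idx]
        medians[done:done + m] = np.median(draws, axis=1)
        means[done:done + m] = draws.mean(axis=1)
        done += m
    return medians, means


@dataclass
class BootstrapSummary:
    """Bootstrap distribution and CI for one (condition × cluster) cell."""

    condition: tuple[str, str, str]
    cluster: int
    n_peaks: int
    boot_medians: np.ndarray
    ci_low: float
    ci_high: float
    level: float
    n_boot: int
    seed: int | None
    point_estimate: float  # median of boot_medians
    ci_defined: bool = True


def bootstrap_medians(values, n_boot: int, seed: int | None) -> np.ndarray:
    """Medians of ``n_boot`` with-replacement resamples of ``values``.

    Resampling draws integer indices only, so results are bit-reproducible
    across platforms for a fixed seed.
    """
    medians, _ = _resample_stats(values, n_boot, seed)
    return medians


def ci_percentile(samples, level: float) -> tuple[float, float]:
    """Central percentile interval of a bootstrap distribution.

    Returns the ``(100 − level)/2`` and ``100 − (100 − level)/2``
    percentiles with linear interpolation between order statistics.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples")
    if not (0 < level < 100):
        raise ValueError("level must be in (0, 100)")
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(samples, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


def summarize(per_peak_values: dict[tuple[str, str, str], np.ndarray],
              assignment: ClusterAssignment,
              n_boot: int = 1000,
              level: float = 99.9,
              seed: int | None = 0,
              ci_of: str = "means",
              wt_key: tuple[str, str, str] | None = None) -> pd.DataFrame:
    """Bootstrap every (condition × cluster) cell of a quantification.

    Parameters
    ----------
    per_peak_values:
        Condition → per-peak normalized signal (e.g. input-subtracted
        RPKM), aligned with ``assignment.peak_ids``.
    assignment:
        Cluster labels over the same peak universe.
    ci_of:
        ``"means"`` (default) — CI is the percentile interval of the
        bootstrapped means; ``"medians"`` — of the bootstrapped medians.
    wt_key:
        When given, a ``wt_percent`` column expresses each cell's point
        estimate relative to the same cluster's cell for this condition.

    Bootstrap seeds derive deterministically from ``seed`` and the
    *canonical* (sorted) peak order within each cluster, so shuffling peak
    order leaves every summary unchanged. Clusters with fewer than 2 peaks
    are flagged (``ci_defined = False``) with an undefined CI.

    Returns a DataFrame with one row per (condition × cluster).
    """
    if ci_of not in ("means", "medians"):
        raise ValueError("ci_of must be 'means' or 'medians'")
    n = len(assignment.peak_ids)
    for cond, vals in per_peak_values.items():
        if np.asarray(vals).shape != (n,):
            raise ValueError(f"values for {cond} not aligned with peak universe")
    order = np.argsort(np.asarray(assignment.peak_ids, dtype=object))

    rows = []
    seed_seq = np.random.SeedSequence(seed)
    # one child stream per (condition, cluster), in deterministic order
    conditions = list(per_peak_values)
    children = iter(seed_seq.spawn(len(conditions) * assignment.k))
    summaries: list[BootstrapSummary] = []
    for cond in conditions:
        vals = np.asarray(per_peak_values[cond], dtype=float)[order]
        labels = assignment.labels[order]
        for cluster in range(1, assignment.k + 1):
            child = next(children)
            cluster_vals = vals[labels == cluster]
            cell_seed = int(child.generate_state(1)[0] % (2**31))
            if cluster_vals.size < 2:
                medians = np.full(n_boot, np.nan)
                if cluster_vals.size == 1:
                    medians[:] = cluster_vals[0]
                summary = BootstrapSummary(
                    condition=cond, cluster=cluster, n_peaks=cluster_vals.size,
                    boot_medians=medians, ci_low=np.nan, ci_high=np.nan,
                    level=level, n_boot=n_boot, seed=cell_seed,
                    point_estimate=float(np.median(medians)),
                    ci_defined=False,
                )
            else:
                medians, means = _resample_stats(cluster_vals, n_boot, cell_seed)
                ci = ci_percentile(means if ci_of == "means" else medians, level)
                summary = BootstrapSummary(
                    condition=cond, cluster=cluster, n_peaks=cluster_vals.size,
                    boot_medians=medians, ci_low=ci[0], ci_high=ci[1],
                    level=level, n_boot=n_boot, seed=cell_seed,
                    point_estimate=float(np.median(medians)),
                )
            summaries.append(summary)
            rows.append({
                "antibody": cond[0], "genotype": cond[1], "treatment": cond[2],
                "cluster": cluster, "n_peaks": summary.n_peaks,
                "point_estimate": summary.point_estimate,
                "ci_low": summary.ci_low, "ci_high": summary.ci_high,
                "ci_defined": summary.ci_defined,
            })
    table = pd.DataFrame(rows)
    if wt_key is not None:
        if wt_key not in per_peak_values:
            raise KeyError(f"wt condition {wt_key} not among the quantified conditions")
        wt_rows = table[(table.antibody == wt_key[0]) & (table.genotype == wt_key[1])
                        & (table.treatment == wt_key[2])]
        wt_by_cluster = dict(zip(wt_rows.cluster, wt_rows.point_estimate))
        table["wt_percent"] = [
            wt_percent(pe, wt_by_cluster[c])
            for pe, c in zip(table.point_estimate, table.cluster)
        ]
    table.attrs["summaries"] = summaries
    return table
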