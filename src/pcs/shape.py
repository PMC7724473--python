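"""DNA-shape-conditioned GCG trinucleotide counting.

MTF2 binding to unmethylated CpG-containing sequence prefers GCG sites
whose local DNA shape shows a *reduced helix twist*. Twist is predicted
from sequence with a pentamer model: every 5-mer over ACGT maps to the
twist (degrees) of the base-pair step at its center. A GCG occurrence
matches the shape requirement when the mean predicted twist over the two
base-pair steps internal to the trinucleotide falls strictly below a
threshold.

The twist threshold and averaging window are tunable; the defaults
(table-wide median twist; the two internal steps) are placeholders to be
replaced with values from a calibrated pentamer table when one is
available. A synthetic, deterministically generated table ships for
testing so no external shape database is required.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from statistics import median

_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class ShapeTable:
    """Pentamer → helix twist (degrees) at the central base-pair step.

    A pentamer ``b0 b1 b2 b3 b4`` assigns its twist to the step between
    ``b2`` and ``b3`` — i.e. the pentamer centered on base ``j`` predicts
    the twist of step ``(j, j+1)``.
    """

    twist: dict[str, float]

    def __post_init__(self) -> None:
        for pent, value in self.twist.items():
            if len(pent) != 5 or any(b not in _ALPHABET for b in pent):
                raise ValueError(f"invalid pentamer {pent!r}")
            if not (value == value and abs(value) != float("inf")):
                raise ValueError(f"non-finite twist for {pent!r}")
        if len(self.twist) != 4 ** 5:
            raise ValueError(
                f"expected {4**5} pentamers, got {len(self.twist)}; "
                "partial tables need an explicit default (not supported here)"
            )

    def __getitem__(self, pentamer: str) -> float:
        return self.twist[pentamer.upper()]

    def median_twist(self) -> float:
        return float(median(self.twist.values()))


def load_shape_table(path: str | Path) -> ShapeTable:
    """Load a two-column TSV (pentamer, twist). Duplicates are rejected."""
    twist: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            pent = fields[0].upper()
            if pent in twist:
                raise ValueError(f"{path}:{lineno}: duplicate pentamer {pent!r}")
            twist[pent] = float(fields[1])
    return ShapeTable(twist)


def write_shape_table(table: ShapeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pent in sorted(table.twist):
            fh.write(f"{pent}\t{table.twist[pent]!r}\n")


def synthetic_twist_table(seed: int = 0, low: float = 30.0,
                          high: float = 40.0) -> ShapeTable:
    """A synthetic pentamer twist table for tests and simulations.

    Twist values are generated deterministically from a keyed BLAKE2 hash
    of each pentamer, uniform over ``[low, high]`` degrees (a realistic
    B-DNA twist range centered near 35°). The table is *not* a physical
    shape model; it only provides a reproducible pentamer → twist map so
    the counting machinery and the synthetic-data generator can be
    exercised without an external shape database.
    """
    twist = {}
    key = seed.to_bytes(8, "little", signed=True)
    for bases in product(_ALPHABET, repeat=5):
        pent = "".join(bases)
        digest = hashlib.blake2b(pent.encode(), key=key, digest_size=8).digest()
        u = int.from_bytes(digest, "little") / 2 ** 64
        twist[pent] = low + (high - low) * u
    return ShapeTable(twist)


def scan_gcg(sequence: str) -> list[tuple[int, str]]:
    """0-based positions of GCG (forward) and CGC (reverse-strand) hits.

    CGC on the forward strand is GCG on the reverse strand and is reported
    with strand ``"-"`` at its forward-strand start. Matching is
    case-insensitive; windows containing N never match.
    """
    seq = sequence.upper()
    hits = []
    for i in range(len(seq) - 2):
        tri = seq[i:i + 3]
        if tri == "GCG":
            hits.append((i, "+"))
        elif tri == "CGC":
            hits.append((i, "-"))
    return hits


@dataclass
class MotifCount:
    """Per-region GCG counts under the shape criterion."""

    region_id: str
    total_gcg: int
    shape_matching_gcg: int
    density: float  # shape-matching GCG per kb of region
    edge_skipped: int = 0
    region_length: int = 0


def _step_twist(seq: str, j: int, table: ShapeTable) -> float | None:
    """Twist of step (j, j+1) from the pentamer centered on base j.

    Returns None when the pentamer runs off the sequence edge or contains N.
    """
    if j - 2 < 0 or j + 3 > len(seq):
        return None
    pent = seq[j - 2:j + 3]
    if any(b not in _ALPHABET for b in pent):
        return None
    return table[pent]


def _hit_mean_twist(seq: str, start: int, table: ShapeTable,
                    flank_mode: str) -> float | None:
    """Mean twist over the two steps internal to a GCG starting at ``start``.

    ``flank_mode="strict"`` requires both step pentamers to be available;
    ``"lenient"`` averages whatever steps are evaluable. None means the
    hit cannot be evaluated and must be edge-skipped.
    """
    twists = [_step_twist(seq, start, table), _step_twist(seq, start + 1, table)]
    available = [t for t in twists if t is not None]
    if flank_mode == "strict":
        if len(available) < 2:
            return None
    elif flank_mode == "lenient":
        if not available:
            return None
    else:
        raise ValueError(f"unknown flank_mode {flank_mode!r}")
    return sum(available) / len(available)


def count_shape_matching(sequence: str, table: ShapeTable,
                         twist_threshold: float | None = None,
                         flank_mode: str = "strict",
                         region_id: str = "") -> MotifCount:
    """Count GCG hits whose mean internal-step twist is below threshold.

    Forward hits are evaluated on the given sequence; reverse-strand hits
    (CGC) are evaluated on the reverse complement with its own pentamers,
    never by reusing forward-strand twist values. ``twist_threshold``
    defaults to the table-wide median twist. Hits that cannot be evaluated
    near the sequence edge are excluded and tallied in ``edge_skipped``.
    """
    if len(sequence) < 5:
        raise ValueError("sequence must be at least 5 bp")
    if twist_threshold is None:
        twist_threshold = table.median_twist()
    seq = sequence.upper()
    rc = reverse_complement(seq)
    n = len(seq)

    total = 0
    matching = 0
    edge_skipped = 0
    for pos, strand in scan_gcg(seq):
        total += 1
        if strand == "+":
            mean = _hit_mean_twist(seq, pos, table, flank_mode)
        else:
            mean = _hit_mean_twist(rc, n - 3 - pos, table, flank_mode)
        if mean is None:
            edge_skipped += 1
        elif mean < twist_threshold:
            matching += 1
    return MotifCount(
        region_id=region_id,
        total_gcg=total,
        shape_matching_gcg=matching,
        density=1000.0 * matching / n,
        edge_skipped=edge_skipped,
        region_length=n,
    )


def permissive_contexts(table: ShapeTable,
                        twist_threshold: float | None = None) -> list[str]:
    """All 7-mers ``xy GCG uv`` whose GCG passes the shape criterion.

    The two internal steps of the GCG are covered by the pentamers
    ``xyGCG`` and ``yGCGu``; the flanking 7-mer context therefore fully
    determines whether the hit matches. Used by the synthetic-data
    generator to plant shape-matching GCGs at a requested density.
    """
    if twist_threshold is None:
        twist_threshold = table.median_twist()
    out = []
    for x, y, u, v in product(_ALPHABET, repeat=4):
        heptamer = f"{x}{y}GCG{u}{v}"
        mean = (table[heptamer[0:5]] + table[heptamer[1:6]]) / 2
        if mean < twist_threshold:
            out.append(heptamer)
    return out
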