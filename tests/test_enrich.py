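"""Peak-gene assignment and hypergeometric enrichment, with exact oracles."""

from itertools import combinations
from math import comb

import numpy as np
import pytest

from pcs.enrich import (
    GeneAnnotation,
    assign_peaks_to_genes,
    bh_adjust,
    cluster_enrichment,
    hypergeometric_enrichment,
)
from pcs.intervals import GenomicInterval, PeakSet


def _annotation(entries):
    return GeneAnnotation({g: (c, p, "+") for g, c, p in entries})


def test_assign_exact_tss_hit():
    ann = _annotation([("gA", "chr1", 500), ("gB", "chr1", 5000)])
    peaks = PeakSet([GenomicInterval("chr1", 400, 600, name="p0")])
    mapping, unassigned = assign_peaks_to_genes(peaks, ann)
    assert mapping == {"p0": "gA"} and unassigned == []


def test_assign_out_of_range_unassigned():
    ann = _annotation([("gA", "chr1", 100_000)])
    peaks = PeakSet([GenomicInterval("chr1", 0, 200, name="p0")])
    mapping, unassigned = assign_peaks_to_genes(peaks, ann, max_distance=10_000)
    assert mapping == {} and unassigned == ["p0"]


def test_assign_tie_breaks_to_smaller_gene_id():
    ann = _annotation([("gB", "chr1", 900), ("gA", "chr1", 1100)])
    peaks = PeakSet([GenomicInterval("chr1", 950, 1050, name="p0")])  # center 1000
    mapping, _ = assign_peaks_to_genes(peaks, ann)
    assert mapping["p0"] == "gA"


def test_assign_matches_all_pairs_oracle(rng):
    genes = [(f"g{i:02d}", "chr1", int(p))
             for i, p in enumerate(rng.integers(0, 200_000, size=50))]
    ann = _annotation(genes)
    peaks = PeakSet([GenomicInterval("chr1", int(s), int(s) + 200, name=f"p{i:03d}")
                     for i, s in enumerate(rng.integers(0, 200_000, size=100))])
    mapping, unassigned = assign_peaks_to_genes(peaks, ann, max_distance=10_000)
    for iv in peaks:
        best = min(((abs(p - iv.center), g) for g, _, p in genes))
        if best[0] <= 10_000:
            assert mapping[iv.name] == best[1]
        else:
            assert iv.name in unassigned


def test_hypergeom_trivia():
    bg = {f"g{i}" for i in range(20)}
    fg = set(list(bg)[:5])
    r = hypergeometric_enrichment(fg, set(), bg)
    assert r.overlap == 0 and r.p == 1.0
    disjoint_term = bg - fg
    r2 = hypergeometric_enrichment(fg, disjoint_term, bg)
    assert r2.overlap == 0 and r2.p == 1.0


def test_hypergeom_perfect_overlap_closed_form():
    """bg=20, term=5, fg=5, overlap=5: p = 1 / C(20,5)."""
    bg = {f"g{i}" for i in range(20)}
    term = {f"g{i}" for i in range(5)}
    r = hypergeometric_enrichment(term, term, bg)
    assert r.p == pytest.approx(1 / comb(20, 5), rel=1e-9)
    assert r.fold == pytest.approx((5 / 5) / (5 / 20))


def test_hypergeom_matches_exhaustive_enumeration(rng):
    """For bg <= 12 the tail probability equals direct enumeration of all
    C(bg, fg) equally likely foreground draws."""
    bg = [f"g{i}" for i in range(12)]
    for _ in range(5):
        term = set(rng.choice(bg, size=rng.integers(1, 8), replace=False))
        fg_size = int(rng.integers(1, 7))
        fg = set(rng.choice(bg, size=fg_size, replace=False))
        observed = len(fg & term)
        hits = sum(1 for draw in combinations(bg, fg_size)
                   if len(set(draw) & term) >= observed)
        exact = hits / comb(12, fg_size)
        r = hypergeometric_enrichment(fg, term, set(bg))
        assert r.p == pytest.approx(exact, rel=1e-9)


def test_hypergeom_requires_subset():
    with pytest.raises(ValueError, match="subset"):
        hypergeometric_enrichment({"x"}, {"x"}, {"y"})
    with pytest.raises(ValueError, match="empty"):
        hypergeometric_enrichment(set(), set(), set())


def test_bh_adjust_values():
    assert bh_adjust([0.03]) == pytest.approx([0.03])
    np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.04, 0.05]),
                               [0.04, 0.04, 0.05, 0.05])
    q = bh_adjust([0.5, 0.9, 0.95, 1.0])
    assert np.all(q <= 1.0)
    with pytest.raises(ValueError):
        bh_adjust([-0.1, 0.5])
    with pytest.raises(ValueError):
        bh_adjust([1.5])


def test_bh_monotone_and_dominates_p(rng):
    p = rng.uniform(1e-6, 1, 40)
    q = bh_adjust(p)
    assert np.all(q >= p - 1e-12)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)


def test_small_terms_skipped():
    genes = {f"g{i}" for i in range(30)}
    table = cluster_enrichment({1: {"g1", "g2"}},
                               {"tiny": {"g1"}, "ok": {f"g{i}" for i in range(6)}},
                               background=genes)
    assert table.attrs["skipped_terms"] == ["tiny"]
    assert set(table.term) == {"ok"}


def test_background_switch_direction_on_study(study):
    """The broad-class term is enriched under both backgrounds; the
    all-peaks term is enriched only against the all-genes background."""
    b = study
    class_of = b.universe.class_of()
    peak_genes = set(b.peak_to_gene_truth.values())
    broad_genes = {g for p, g in b.peak_to_gene_truth.items()
                   if class_of[p].startswith("broad")}
    all_genes = {g for g, _, _, _ in b.tss}

    vs_all = cluster_enrichment({1: broad_genes, 2: peak_genes},
                                b.terms, background=all_genes)
    vs_prc2 = cluster_enrichment({1: broad_genes}, b.terms,
                                 background=peak_genes)

    body_all = vs_all[(vs_all.cluster == 1) & (vs_all.term == "body_plan_patterning")].iloc[0]
    body_prc2 = vs_prc2[vs_prc2.term == "body_plan_patterning"].iloc[0]
    assert body_all.q < 1e-10 and body_prc2.q < 1e-10

    pc_all = vs_all[(vs_all.cluster == 2) & (vs_all.term == "polycomb_target")].iloc[0]
    assert pc_all.q < 1e-10
    pc_prc2 = cluster_enrichment({1: broad_genes}, b.terms,
                                 background=peak_genes)
    row = pc_prc2[pc_prc2.term == "polycomb_target"].iloc[0]
    # the all-peaks term covers the whole PRC2 background: no enrichment
    assert row.fold == pytest.approx(1.0)
    assert row.p == pytest.approx(1.0)
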