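"""The synthetic study generator: determinism, planted-parameter contracts."""

import hashlib
import json

import numpy as np
import pytest

from pcs import simulate as sim
from pcs.coverage import extract_signal_matrix
from pcs.intervals import read_bed
from pcs.normalize import matrix_rpkm
from pcs.shape import count_shape_matching, synthetic_twist_table


def _one_class(n=30, width=(1000, 2000), density=8.0):
    return [sim.PeakClassSpec("narrow1", n, width, (15.0, 30.0),
                              "sharp-gaussian", gcg_density=density,
                              cpg_like=True)]


def test_peak_widths_respect_range():
    uni = sim.generate_universe(_one_class(width=(1200, 1800)),
                                {"chrS1": 1_000_000}, seed=3)
    widths = [p.width for p in uni.planted]
    assert all(1200 <= w <= 1800 for w in widths)
    assert len(widths) == 30


def test_peaks_disjoint_and_within_genome():
    uni = sim.generate_universe(_one_class(n=50), {"chrS1": 1_500_000}, seed=5)
    prev_end = -1
    for iv in uni.peaks:
        assert iv.start > prev_end
        prev_end = iv.end
        assert iv.end <= 1_500_000


def test_too_small_genome_raises():
    with pytest.raises(ValueError, match="genome too small"):
        sim.generate_universe(_one_class(n=500), {"chrS1": 100_000}, seed=0)


def test_generate_universe_deterministic():
    a = sim.generate_universe(_one_class(), {"chrS1": 1_000_000}, seed=11)
    b = sim.generate_universe(_one_class(), {"chrS1": 1_000_000}, seed=11)
    assert a.sequences == b.sequences
    assert [(p.interval.chrom, p.interval.start, p.interval.end, p.class_label)
            for p in a.planted] == \
           [(p.interval.chrom, p.interval.start, p.interval.end, p.class_label)
            for p in b.planted]
    c = sim.generate_universe(_one_class(), {"chrS1": 1_000_000}, seed=12)
    assert a.sequences != c.sequences


def test_planted_gcg_density_recovered_by_counter():
    """100 x 2 kb peaks at 10 shape-matching GCG per kb: the counter's mean
    density lands within 3 standard errors of the target."""
    classes = [sim.PeakClassSpec("narrow1", 100, (2000, 2000), (15.0, 30.0),
                                 "sharp-gaussian", gcg_density=10.0)]
    uni = sim.generate_universe(classes, {"chrS1": 2_000_000}, seed=21)
    table = synthetic_twist_table()
    densities = []
    for p in uni.planted:
        seq = uni.sequences[p.interval.chrom][p.interval.start:p.interval.end]
        densities.append(count_shape_matching(seq, table).density)
    mean = np.mean(densities)
    se = np.std(densities, ddof=1) / np.sqrt(len(densities))
    assert abs(mean - 10.0) <= 3 * max(se, 1e-9)


def test_class_labels_round_trip_through_bed(tmp_path, minimal_study):
    from pcs.intervals import write_bed
    path = tmp_path / "peaks.bed"
    write_bed(minimal_study.universe.peaks, path)
    back = read_bed(path)
    assert back.names() == minimal_study.universe.peaks.names()
    labels = {n.split("|")[0] for n in back.names()}
    assert labels == {"narrow1", "broad5"}


def _flat_condition(frac, bg=1.0, label="narrow1", **kw):
    return sim.ConditionSpec(("AB", "g", "t"), {label: frac},
                             background_rate=bg, **kw)


def test_zero_residual_gives_input_like_chip():
    uni = sim.generate_universe(_one_class(), {"chrS1": 1_000_000}, seed=2)
    chip, inp = sim.simulate_coverage(uni, _flat_condition(0.0), seed=2)
    # identical expected depth: means agree within Poisson error
    cm, im = chip.depth["chrS1"].mean(), inp.depth["chrS1"].mean()
    assert cm == pytest.approx(im, abs=0.02)


def test_plateau_mean_depth_matches_rate():
    """Plateau class, amplitude 20, fraction 0.5, background 1: interior
    in-peak bins average about 11 reads."""
    classes = [sim.PeakClassSpec("broad", 40, (6000, 6000), (20.0, 20.0),
                                 "flat-plateau")]
    uni = sim.generate_universe(classes, {"chrS1": 1_500_000}, seed=4)
    cond = sim.ConditionSpec(("AB", "g", "t"), {"broad": 0.5})
    chip, _ = sim.simulate_coverage(uni, cond, seed=4)
    interior = []
    for p in uni.planted:
        # skip the 10% taper at each end
        lo = (p.interval.start + 700) // 50
        hi = (p.interval.end - 700) // 50
        interior.append(chip.depth["chrS1"][lo:hi])
    interior = np.concatenate(interior)
    se = interior.std(ddof=1) / np.sqrt(interior.size)
    assert interior.mean() == pytest.approx(11.0, abs=3 * se)


def test_library_size_metadata_only_affects_rpkm():
    uni = sim.generate_universe(_one_class(), {"chrS1": 1_000_000}, seed=6)
    c1 = _flat_condition(1.0, library_size=1e7)
    c2 = _flat_condition(1.0, library_size=2e7)
    chip1, _ = sim.simulate_coverage(uni, c1, seed=6)
    chip2, _ = sim.simulate_coverage(uni, c2, seed=6)
    np.testing.assert_array_equal(chip1.depth["chrS1"], chip2.depth["chrS1"])
    m1 = matrix_rpkm(extract_signal_matrix(chip1, uni.peaks, 1000), c1.library_size)
    m2 = matrix_rpkm(extract_signal_matrix(chip2, uni.peaks, 1000), c2.library_size)
    np.testing.assert_allclose(m1.values, 2.0 * m2.values)


def test_spike_reads_inverse_to_efficiency():
    lo = _flat_condition(1.0, global_efficiency=0.5, spike_base=1e5)
    hi = _flat_condition(1.0, global_efficiency=2.0, spike_base=1e5)
    assert lo.spike_in_reads == 2e5
    assert hi.spike_in_reads == 5e4


def test_dispersion_knob_inflates_variance():
    uni = sim.generate_universe(_one_class(n=5), {"chrS1": 500_000}, seed=8)
    pois = _flat_condition(0.0, bg=5.0)
    nb = sim.ConditionSpec(("AB", "g", "t"), {"narrow1": 0.0},
                           background_rate=5.0, dispersion=0.5)
    _, inp_p = sim.simulate_coverage(uni, pois, seed=8)
    _, inp_nb = sim.simulate_coverage(uni, nb, seed=8)
    assert inp_nb.depth["chrS1"].var() > 1.5 * inp_p.depth["chrS1"].var()


def _dir_checksums(path):
    out = {}
    for p in sorted(path.iterdir()):
        out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


def test_write_study_reproducible_and_complete(tmp_path, minimal_study):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    m1 = sim.write_study(minimal_study, d1)
    m2 = sim.write_study(minimal_study, d2)
    assert _dir_checksums(d1) == _dir_checksums(d2)
    manifest = json.loads((d1 / "manifest.json").read_text())
    assert manifest["seed"] == minimal_study.seed
    sheet = (d1 / "samples.tsv").read_text().strip().split("\n")
    assert len(sheet) - 1 == len(minimal_study.conditions)
    for fname in ("peaks.bed", "genome.fa", "tss.bed", "terms.tsv", "twist.tsv"):
        assert (d1 / fname).exists()


def test_study_annotation_consistency(minimal_study):
    b = minimal_study
    peak_names = set(b.universe.peaks.names())
    assert set(b.peak_to_gene_truth) == peak_names
    gene_ids = {g for g, _, _, _ in b.tss}
    assert set(b.peak_to_gene_truth.values()) <= gene_ids
    assert set(b.terms["polycomb_target"]) == set(b.peak_to_gene_truth.values())


def test_wt_condition_has_unit_fractions():
    for cond in sim.default_conditions():
        if cond.sample_id[1] == "WT" and cond.sample_id[2] == "none":
            assert all(f == 1.0 for f in cond.residual_fraction_by_class.values())


def test_eed_inhibitor_interpretation_switch():
    default = {c.sample_id: c for c in sim.default_conditions()}
    flipped = {c.sample_id: c for c in sim.default_conditions(
        eed_inhibitor_as_reduction=True)}
    key = ("EZH2", "WT", "EED226")
    f0 = default[key].residual_fraction_by_class["narrow1"]
    f1 = flipped[key].residual_fraction_by_class["narrow1"]
    assert f0 == pytest.approx(0.77)
    assert f1 == pytest.approx(0.23)
    untreated = ("EZH2", "Mtf2GT", "none")
    assert default[untreated].residual_fraction_by_class == \
        flipped[untreated].residual_fraction_by_class
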