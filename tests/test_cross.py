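"""Introgression simulator: meiosis models, selection, segment bookkeeping."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import introgmap as im
from introgmap.cross import DONOR, RECIPIENT, _splice
from tests.conftest import demo_karyotype


def het_parent(length=15_000_000, chrom="I", marker_pos=1_875_000):
    marker = im.MarkerLocus(chrom, marker_pos)
    haps = {chrom: [im.Haplotype.uniform(chrom, length, DONOR),
                    im.Haplotype.uniform(chrom, length, RECIPIENT)]}
    return im.Individual(sex="female", haplotypes=haps, marker=marker, generation=1)


class TestF1:
    def test_f1_heterozygous_genome_wide(self):
        donor, recipient, gmap = demo_karyotype()
        marker = im.MarkerLocus("II", 1_875_000)
        f1 = im.make_f1(donor, recipient, marker, im.CrossScheme())
        assert f1.sex == "female" and f1.generation == 1
        total = donor.total_length()
        donor_bp = sum(h.donor_bp() for hs in f1.haplotypes.values() for h in hs)
        assert donor_bp / (2 * total) == pytest.approx(0.5)
        assert f1.is_marker_positive()

    def test_x_linked_marker_on_donor_x(self):
        donor, recipient, gmap = demo_karyotype()
        marker = im.MarkerLocus("X", 3_000_000)
        f1 = im.make_f1(donor, recipient, marker, im.CrossScheme(linkage="x_linked"))
        assert f1.haplotypes["X"][0].origin_at(3_000_000) == DONOR
        assert f1.is_marker_positive()


class TestMeiosis:
    def test_identical_parents_give_identical_gamete(self):
        gmap = im.GeneticMap.uniform({"I": 1_000_000}, 50)
        haps = {"I": [im.Haplotype.uniform("I", 1_000_000, DONOR),
                      im.Haplotype.uniform("I", 1_000_000, DONOR)]}
        ind = im.Individual("female", haps, im.MarkerLocus("I", 0), 1)
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = im.meiosis(ind, "I", gmap, "obligate_single", rng)
            assert g.segments == haps["I"][0].segments

    def test_obligate_single_recombinant_fraction_half(self):
        gmap = im.GeneticMap.uniform({"I": 1_000_000}, 50)
        parent = het_parent(1_000_000, marker_pos=0)
        rng = np.random.default_rng(1)
        n = 4000
        rec = sum(
            len(im.meiosis(parent, "I", gmap, "obligate_single", rng).segments) > 1
            for _ in range(n)
        )
        se = math.sqrt(0.25 / n)
        assert abs(rec / n - 0.5) < 3 * se

    def test_poisson_mean_crossovers_matches_map_length(self):
        # 50 cM map -> 0.5 crossovers per transmitted gamete
        gmap = im.GeneticMap.uniform({"I": 1_000_000}, 50)
        parent = het_parent(1_000_000, marker_pos=0)
        rng = np.random.default_rng(2)
        n = 6000
        xs = [len(im.meiosis(parent, "I", gmap, "poisson", rng).segments) - 1
              for _ in range(n)]
        se = math.sqrt(0.5 / n)  # Poisson variance = mean
        assert abs(np.mean(xs) - 0.5) < 3 * se

    def test_hemizygous_x_transmitted_unrecombined(self):
        gmap = im.GeneticMap.uniform({"X": 1_000_000}, 50)
        haps = {"X": [im.Haplotype("X", [
            im.AncestrySegment(0, 400_000, DONOR),
            im.AncestrySegment(400_000, 1_000_000, RECIPIENT)])]}
        ind = im.Individual("male", haps, im.MarkerLocus("X", 0), 2, x_chrom="X")
        g = im.meiosis(ind, "X", gmap, "obligate_single", np.random.default_rng(3))
        assert g.segments == haps["X"][0].segments

    def test_missing_chromosome_errors(self):
        parent = het_parent()
        with pytest.raises(im.GenomeError):
            im.meiosis(parent, "nope", im.GeneticMap.uniform({"I": 10}, 50),
                       "obligate_single", np.random.default_rng(0))

    @given(st.lists(st.integers(min_value=1, max_value=999_999), min_size=0,
                    max_size=6, unique=True))
    def test_tiling_invariant_after_any_splice(self, cuts):
        h0 = im.Haplotype.uniform("I", 1_000_000, DONOR)
        h1 = im.Haplotype.uniform("I", 1_000_000, RECIPIENT)
        g = _splice(h0, h1, sorted(cuts))
        assert g.segments[0].start == 0 and g.segments[-1].end == 1_000_000
        for a, b in zip(g.segments, g.segments[1:]):
            assert a.end == b.start and a.origin != b.origin


class TestBackcross:
    def test_marker_transmission_is_mendelian(self):
        donor, recipient, gmap = demo_karyotype(n_autosomes=1)
        marker = im.MarkerLocus("I", 1_875_000)
        scheme = im.CrossScheme(brood_size=1, seed=5)
        f1 = im.make_f1(donor, recipient, marker, scheme)
        streams = im.RngStreams(scheme.seed)
        successes = trials = 0
        for _ in range(800):
            trials += 1
            try:
                im.backcross_once(f1, scheme, gmap, streams)
                successes += 1
            except im.BroodExhaustedError:
                pass
        p = successes / trials
        assert abs(p - 0.5) < 3 * math.sqrt(0.25 / trials)

    def test_large_x_effect_selects_females_only(self):
        donor, recipient, gmap = demo_karyotype(n_autosomes=1)
        marker = im.MarkerLocus("X", 1_875_000)
        scheme = im.CrossScheme(linkage="x_linked", large_x_effect=True,
                                generations=4, seed=6)
        traj = im.run_introgression(donor, recipient, marker, scheme, gmap)
        assert all(ind.sex == "female" for ind in traj.individuals)

    def test_x_linked_without_large_x_alternates_sexes(self):
        donor, recipient, gmap = demo_karyotype(n_autosomes=1)
        marker = im.MarkerLocus("X", 1_875_000)
        scheme = im.CrossScheme(linkage="x_linked", large_x_effect=False,
                                generations=4, seed=7)
        traj = im.run_introgression(donor, recipient, marker, scheme, gmap)
        sexes = [ind.sex for ind in traj.individuals]
        assert sexes == ["female", "male", "female", "male", "female"]

    def test_marker_negative_carrier_rejected(self):
        donor, recipient, gmap = demo_karyotype(n_autosomes=1)
        marker = im.MarkerLocus("I", 1_875_000)
        ind = im.Individual("female", {
            "I": [im.Haplotype.uniform("I", 15_000_000, RECIPIENT),
                  im.Haplotype.uniform("I", 15_000_000, RECIPIENT)]},
            marker, 1)
        with pytest.raises(im.BroodExhaustedError):
            im.backcross_once(ind, im.CrossScheme(), gmap, im.RngStreams(0))


class TestRunIntrogression:
    def test_trajectory_length_and_selection_invariant(self):
        donor, recipient, gmap = demo_karyotype(n_autosomes=2)
        marker = im.MarkerLocus("I", 1_875_000)
        traj = im.run_introgression(donor, recipient, marker,
                                    im.CrossScheme(generations=1, seed=8), gmap)
        assert len(traj.individuals) == 2
        traj = im.run_introgression(donor, recipient, marker,
                                    im.CrossScheme(generations=10, seed=8), gmap)
        assert all(ind.is_marker_positive() for ind in traj.individuals)
        # marker-linked length never exceeds the previous generation's
        lengths = [st_.marker_linked_bp for st_ in traj.stats]
        assert all(b <= a for a, b in zip(lengths, lengths[1:]))

    def test_unlinked_donor_content_decays(self):
        donor, recipient, gmap = demo_karyotype(n_autosomes=2)
        marker = im.MarkerLocus("I", 1_875_000)
        unlinked = []
        for rep in range(30):
            traj = im.run_introgression(
                donor, recipient, marker,
                im.CrossScheme(generations=10, seed=100 + rep), gmap)
            fin = traj.final
            off = sum(h.donor_bp() for c, hs in fin.haplotypes.items()
                      for h in hs if c != "I")
            unlinked.append(off)
        # expected fraction (1/2)^10 of the off-marker genome: ~0 in most reps
        assert np.median(unlinked) == 0
        assert np.mean(unlinked) < 0.01 * 2 * 15_000_000

    def test_deterministic_under_seed(self):
        donor, recipient, gmap = demo_karyotype(n_autosomes=1)
        marker = im.MarkerLocus("I", 1_875_000)
        t1 = im.run_introgression(donor, recipient, marker,
                                  im.CrossScheme(generations=5, seed=9), gmap)
        t2 = im.run_introgression(donor, recipient, marker,
                                  im.CrossScheme(generations=5, seed=9), gmap)
        assert [s.marker_linked_bp for s in t1.stats] == [s.marker_linked_bp for s in t2.stats]
        t3 = im.run_introgression(donor, recipient, marker,
                                  im.CrossScheme(generations=5, seed=10), gmap)
        assert [s.marker_linked_bp for s in t3.stats] != [s.marker_linked_bp for s in t1.stats]


class TestSegmentStats:
    def test_f1_marker_linked_is_whole_chromosome(self):
        donor, recipient, gmap = demo_karyotype(n_autosomes=1)
        f1 = im.make_f1(donor, recipient, im.MarkerLocus("I", 1_875_000),
                        im.CrossScheme())
        st_ = im.segment_stats(f1)
        assert st_.marker_linked_bp == 15_000_000

    def test_hand_built_segment_arithmetic(self):
        hap = im.Haplotype("I", [
            im.AncestrySegment(0, 2_100_000, RECIPIENT),
            im.AncestrySegment(2_100_000, 3_000_000, DONOR),
            im.AncestrySegment(3_000_000, 15_000_000, RECIPIENT)])
        ind = im.Individual("female", {"I": [hap, im.Haplotype.uniform("I", 15_000_000, RECIPIENT)]},
                            im.MarkerLocus("I", 2_500_000), 8)
        st_ = im.segment_stats(ind)
        assert st_.marker_linked_bp == 900_000
        assert st_.total_donor_bp == 900_000
        assert st_.donor_segments_per_chrom == {"I": 1}

    def test_invariant_under_canonical_merge(self):
        hap = im.Haplotype("I", [
            im.AncestrySegment(0, 500, DONOR),
            im.AncestrySegment(500, 1000, DONOR),
            im.AncestrySegment(1000, 2000, RECIPIENT)])
        merged = hap.canonical()
        assert len(merged.segments) == 2
        ind_a = im.Individual("female", {"I": [hap, hap]}, im.MarkerLocus("I", 100), 1)
        ind_b = im.Individual("female", {"I": [merged, merged]}, im.MarkerLocus("I", 100), 1)
        assert im.segment_stats(ind_a).marker_linked_bp == im.segment_stats(ind_b).marker_linked_bp

    def test_marker_negative_reported_absent(self):
        hap = im.Haplotype.uniform("I", 1000, RECIPIENT)
        ind = im.Individual("female", {"I": [hap, hap]}, im.MarkerLocus("I", 100), 1)
        assert im.segment_stats(ind).marker_linked_bp is None


class TestExpectedFlankLength:
    def test_zero_flank(self):
        assert im.expected_flank_length(5, 0.0) == 0.0

    def test_one_generation_large_flank_approaches_one_morgan(self):
        assert im.expected_flank_length(1, 50.0) == pytest.approx(1.0, abs=1e-6)

    def test_closed_form_value(self):
        assert im.expected_flank_length(8, 0.25) == pytest.approx(
            (1 - math.exp(-2.0)) / 8, abs=1e-12)

    def test_poisson_simulation_matches_closed_form_spot(self):
        """One-flank retained length under the poisson model vs the closed
        form, at t=5, d=0.25 Morgans (the full grid runs in the acceptance
        suite)."""
        mean, se, expect = _flank_sim(t=5, d=0.25, reps=2000, seed=13)
        assert abs(mean - expect) < 3 * se


def _flank_sim(t, d, reps, seed):
    """Marker at the left end; measure donor length retained on the right
    flank of length d Morgans after t marker-selected poisson meioses."""
    L = 1_000_000
    gmap = im.GeneticMap.uniform({"I": L}, d * 100)
    marker = im.MarkerLocus("I", 0)
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(reps):
        hap = im.Haplotype.uniform("I", L, DONOR)
        for _gen in range(t):
            parent = im.Individual("female", {
                "I": [hap, im.Haplotype.uniform("I", L, RECIPIENT)]}, marker, 1)
            while True:
                g = im.meiosis(parent, "I", gmap, "poisson", rng)
                if g.donor_segment_containing(0) is not None:
                    hap = g
                    break
        seg = hap.donor_segment_containing(0)
        vals.append((seg.end - seg.start) / L * d)
    vals = np.asarray(vals)
    expect = im.expected_flank_length(t, d)
    return float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(reps)), expect
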