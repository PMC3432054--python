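"""Panel design: candidate regions, primer picking, the full selection loop."""

import numpy as np
import pytest

import introgmap as im
from introgmap.panel import RegionExhaustedError, _arm_label, layout_targets
from tests._oracles import suffix_scan, sw_score


def _flat_annotation(chrom, length, features):
    ann = im.AnnotationSet()
    for s, e, kind in features:
        ann.add(im.Feature(chrom, s, e, kind))
    return ann


class TestSelectCandidateRegion:
    SPEC = im.PanelSpec(candidate_region_length_bp=400, reselection_step_bp=200)

    def test_unobstructed_target_centered(self):
        ann = _flat_annotation("I", 10_000, [(0, 10_000, "intergenic")])
        s, e = im.select_candidate_region(ann, "I", 5000, self.SPEC, 10_000)
        assert (s, e) == (4800, 5200)

    def test_target_in_exon_displaced_to_flank(self):
        ann = _flat_annotation(
            "I", 10_000, [(4000, 6000, "exon"), (0, 4000, "intergenic"), (6000, 10_000, "intergenic")]
        )
        s, e = im.select_candidate_region(ann, "I", 5000, self.SPEC, 10_000)
        assert e <= 4000 or s >= 6000
        assert min(abs(5000 - (s + e) // 2), 0) == 0  # nearest flanking placement

    def test_repeat_overlap_excluded(self):
        ann = _flat_annotation(
            "I", 10_000, [(0, 10_000, "intergenic"), (4500, 5500, "repeat")]
        )
        s, e = im.select_candidate_region(ann, "I", 5000, self.SPEC, 10_000)
        assert e <= 4500 or s >= 5500

    def test_fully_exonic_chromosome_exhausted(self):
        ann = _flat_annotation("I", 10_000, [(0, 10_000, "exon")])
        with pytest.raises(RegionExhaustedError):
            im.select_candidate_region(ann, "I", 5000, self.SPEC, 10_000)

    def test_exclusion_walks_to_next_placement(self):
        ann = _flat_annotation("I", 10_000, [(0, 10_000, "intergenic")])
        first = im.select_candidate_region(ann, "I", 5000, self.SPEC, 10_000)
        second = im.select_candidate_region(ann, "I", 5000, self.SPEC, 10_000, exclude={first})
        assert second != first


class TestPickPrimerPair:
    SPEC = im.PanelSpec(product_size_range=(120, 400), candidate_region_length_bp=420)

    def test_homopolymer_region_yields_none(self):
        assert im.pick_primer_pair("A" * 400, self.SPEC) is None

    def test_benign_region_yields_valid_pair(self, rng):
        region = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 420)])
        pair = im.pick_primer_pair(region, self.SPEC, region_start=100, chrom="I")
        assert pair is not None
        assert 120 <= pair.product_size_bp <= 400
        assert 18 <= len(pair.left_seq) <= 27 and 18 <= len(pair.right_seq) <= 27
        # coordinates reference the chromosome, sequences the region
        assert region[pair.left_start - 100 : pair.left_start - 100 + len(pair.left_seq)] == pair.left_seq
        assert pair.product_size_bp == pair.right_end - pair.left_start

    def test_deterministic(self, rng):
        region = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 420)])
        a = im.pick_primer_pair(region, self.SPEC)
        b = im.pick_primer_pair(region, self.SPEC)
        assert (a.left_seq, a.right_seq, a.left_start, a.right_end) == (
            b.left_seq, b.right_seq, b.left_start, b.right_end)


class TestLayout:
    def test_arm_weights_deplete_middle(self):
        spec = im.PanelSpec(primers_per_chromosome=15, arm_density_weights=(0.4, 0.2, 0.4))
        targets = layout_targets(15_000_000, spec)
        third = 15_000_000 / 3
        counts = [sum(1 for t in targets if i * third <= t < (i + 1) * third) for i in range(3)]
        assert counts[1] == min(counts) and counts[1] < counts[0]
        assert len(targets) == 15

    def test_arm_labels(self):
        assert _arm_label(100, 15_000) == "left"
        assert _arm_label(7_500, 15_000) == "middle"
        assert _arm_label(14_000, 15_000) == "right"


class TestDesignPanel:
    def test_zero_divergence_is_infeasible(self):
        cfg = im.DivergenceConfig(
            seed=2, n_autosomes=1, chrom_length_bp=8000,
            substitution_rate_exonic=0, substitution_rate_nonexonic=0,
            indel_rate_nonexonic=0,
        )
        pair = im.generate_sister_pair(cfg)
        with pytest.raises(im.PanelInfeasibleError):
            im.design_panel(pair.donor, pair.recipient, pair.annotation,
                            spec=im.PanelSpec(primers_per_chromosome=4,
                                              product_size_range=(120, 400),
                                              candidate_region_length_bp=420))

    def test_full_panel_retained_and_audited(self, sister, designed, small_spec):
        """Every retained pair passes a post-hoc audit with the independent
        oracles: recipient alignment score of its source region <= 50 and
        3'-suffix match <= 8 for both primers."""
        retained = designed.retained()
        per_chrom = {c.name: 0 for c in sister.donor}
        recip_seqs = [c.sequence for c in sister.recipient.chromosomes]
        for p in retained:
            per_chrom[p.chrom] += 1
            assert p.max_offtarget_score <= small_spec.offtarget_score_cutoff
            assert p.max_three_prime_match <= small_spec.three_prime_cutoff_bp
            for primer in (p.left_seq, p.right_seq):
                assert suffix_scan(primer, recip_seqs) <= 8
        assert all(n >= 3 for n in per_chrom.values())

    def test_primer_score_agrees_with_dp_oracle_on_sample(self, sister, designed):
        # spot-check the production aligner against the DP oracle on a primer
        p = designed.retained()[0]
        recip = sister.recipient[p.chrom].sequence
        assert im.max_local_alignment_score(p.left_seq, recip) == sw_score(p.left_seq, recip)

    def test_donor_only_amplification(self, sister, designed):
        for p in designed.retained():
            ok_d, size = im.insilico_pcr_sequence(sister.donor, p)
            ok_r, _ = im.insilico_pcr_sequence(sister.recipient, p)
            assert ok_d and size == p.product_size_bp
            assert not ok_r

    def test_design_deterministic_and_order_invariant(self, sister, small_spec, designed):
        reordered = im.Genome(
            "donor", list(reversed(sister.donor.chromosomes)), list(sister.donor.markers)
        )
        again = im.design_panel(reordered, sister.recipient,
                                sister.annotation, spec=small_spec)
        key = lambda d: sorted((p.id, p.left_start, p.left_seq) for p in d.panel)
        assert key(again) == key(designed)

    def test_rejections_are_logged_with_causes(self, designed):
        assert all({"chrom", "target", "cause"} <= set(e) for e in designed.log)


class TestValidatePanel:
    def test_identical_genomes_discard_everything(self, sister, designed):
        panel = [im.PrimerPair(**{
            "id": p.id, "chrom": p.chrom, "left_seq": p.left_seq,
            "right_seq": p.right_seq, "left_start": p.left_start,
            "right_end": p.right_end, "product_size_bp": p.product_size_bp,
        }) for p in designed.retained()]
        v = im.validate_panel(panel, sister.donor, sister.donor)
        assert v.n_retained == 0
        assert v.n_cross_amplifying == v.n_candidates

    def test_validation_idempotent(self, sister, designed):
        v1 = im.validate_panel(designed.panel, sister.donor, sister.recipient)
        statuses = [p.status for p in designed.panel]
        v2 = im.validate_panel(designed.panel, sister.donor, sister.recipient)
        assert statuses == [p.status for p in designed.panel]
        assert (v1.n_candidates, v1.n_cross_amplifying) == (v2.n_candidates, v2.n_cross_amplifying)


class TestSpacingStats:
    def test_even_spacing_arithmetic(self, sister):
        panel = []
        for mb in (1, 2, 3):
            panel.append(im.PrimerPair(
                id=f"I-{mb}", chrom="I", left_seq="A" * 22, right_seq="C" * 22,
                left_start=mb * 1_000_000 - 150, right_end=mb * 1_000_000 + 150,
                product_size_bp=300, status="retained"))
        g = im.Genome("d", [im.Chromosome("I", 15_000_000)])
        df = im.panel_spacing_stats(panel, g)
        assert df[df.chrom == "I"].mean_gap_bp.iloc[0] == pytest.approx(1_000_000)

    def test_fixture_spacing_near_layout_density(self, sister, designed, small_spec):
        df = im.panel_spacing_stats(designed.retained(), sister.donor)
        expected = sister.config.chrom_length_bp / small_spec.primers_per_chromosome
        got = df[df.chrom == "*"].mean_gap_bp.iloc[0]
        assert abs(got - expected) / expected < 0.20

    def test_single_pair_chromosome_warns_and_omitted(self):
        panel = [im.PrimerPair(id="I-1", chrom="I", left_seq="A" * 22,
                               right_seq="C" * 22, left_start=100, right_end=400,
                               product_size_bp=300, status="retained")]
        g = im.Genome("d", [im.Chromosome("I", 15_000_000)])
        with pytest.warns(UserWarning):
            df = im.panel_spacing_stats(panel, g)
        assert df.empty


def test_panel_tsv_round_trip(designed, tmp_path):
    path = tmp_path / "panel.tsv"
    im.write_panel(designed.panel, path)
    back = im.read_panel(path)
    assert [(p.id, p.left_seq, p.status) for p in back] == [
        (p.id, p.left_seq, p.status) for p in designed.panel
    ]
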