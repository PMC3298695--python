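import numpy as np
import pytest

import synmotif as sm
from synmotif.engine import CodingSequence, segment_regions
from synmotif.errors import FrameError
from synmotif.motif import feasible_starts
from _utils import assert_dists_close, random_motif, random_nt_for, \
    random_protein_capped


class TestCodingSequence:
    def test_terminal_stop_detached(self):
        s = CodingSequence.from_cds("g", "ATGAAATAA")
        assert (s.nt, s.aa, s.has_terminal_stop, s.boundary_base) == (
            "ATGAAA",
            "MK",
            True,
            "T",
        )

    def test_fragment_keeps_no_boundary(self):
        s = CodingSequence.from_cds("f", "ATGAAA")
        assert s.boundary_base is None and not s.has_terminal_stop

    def test_internal_stop_rejected(self):
        with pytest.raises(FrameError):
            CodingSequence.from_cds("bad", "ATGTAAATG")


class TestSegmentation:
    def test_contiguous_possible_run_is_one_region(self):
        seq = CodingSequence(id="x", nt="AAAAAAAAA")  # KKK
        regions = segment_regions(seq, sm.parse_motif_spec("AAA"))
        assert [(r.start, r.end) for r in regions] == [(0, 3)]

    def test_isolated_forced_codons_split(self):
        seq = CodingSequence(id="x", nt="ATGTTTATG")  # M F M
        regions = segment_regions(seq, sm.parse_motif_spec("ATG"))
        assert [(r.start, r.end) for r in regions] == [(0, 1), (2, 3)]

    def test_impossible_motif_gives_no_regions(self):
        seq = CodingSequence(id="x", nt="ATGAAAATG")  # M K M
        assert segment_regions(seq, sm.parse_motif_spec("TTT")) == []

    def test_every_feasible_start_in_exactly_one_region(self, rng):
        for _ in range(30):
            aa = random_protein_capped(rng, max_codons=30, deg_cap=10**9)
            motif = random_motif(rng, aa)
            seq = CodingSequence(id="x", nt=random_nt_for(rng, aa))
            regions = segment_regions(seq, motif)
            for s in feasible_starts(aa, motif):
                c0, c1 = s // 3, (s + motif.length - 1) // 3
                hits = [r for r in regions if r.start <= c0 and c1 < r.end]
                assert len(hits) == 1
            assert sum(r.n_feasible for r in regions) == len(
                feasible_starts(aa, motif)
            )


class TestRegionDistribution:
    def test_two_lysines_uniform(self, uniform_icm):
        seq = CodingSequence(id="x", nt="AAAAAA")
        d = sm.sequence_distribution(seq, sm.parse_motif_spec("AAA"), uniform_icm)
        assert_dists_close(
            d, sm.CountDistribution.from_dict({0: 0.25, 1: 0.25, 3: 0.25, 4: 0.25})
        )

    def test_forced_codon_contains_motif(self, dcm, icm):
        seq = CodingSequence(id="x", nt="ATG")
        for model in (icm, dcm):
            d = sm.sequence_distribution(seq, sm.parse_motif_spec("ATG"), model)
            assert_dists_close(d, sm.CountDistribution.point_mass(1))

    def test_four_lysines_long_motif_vs_enumeration(self, uniform_icm):
        motif = sm.parse_motif_spec("AAAAAA")
        bf = sm.brute_force_distribution("KKKK", motif, uniform_icm)
        dp = sm.sequence_distribution(
            CodingSequence(id="x", nt="AAA" * 4), motif, uniform_icm
        )
        assert_dists_close(dp, bf)


class TestSequenceAndDataset:
    def test_no_region_returns_point_mass_at_zero(self, icm):
        seq = CodingSequence(id="x", nt="ATGAAAATG")
        d = sm.sequence_distribution(seq, sm.parse_motif_spec("TTT"), icm)
        assert_dists_close(d, sm.CountDistribution.point_mass(0))

    def test_split_at_unique_first_base_matches_unsplit(self, uniform_icm):
        # D (GAT/GAC) interrupts the lysine run; split and no-split agree
        motif = sm.parse_motif_spec("AAA")
        aa = "KKDKK"
        bf = sm.brute_force_distribution(aa, motif, uniform_icm)
        seq = CodingSequence(id="x", nt="AAAAAAGATAAAAAA")
        for segm in (True, False):
            dp = sm.sequence_distribution(seq, motif, uniform_icm, segmentation=segm)
            assert_dists_close(dp, bf)

    def test_two_sequences_convolve(self, uniform_icm):
        motif = sm.parse_motif_spec("AAA")
        one = CodingSequence(id="a", nt="AAAAAA")
        d1 = sm.sequence_distribution(one, motif, uniform_icm)
        d2 = sm.dataset_distribution([one, one], motif, uniform_icm)
        assert_dists_close(d2, sm.convolve(d1, d1))

    def test_empty_dataset_rejected(self, icm):
        with pytest.raises(ValueError):
            sm.dataset_distribution([], sm.parse_motif_spec("AAA"), icm)

    def test_dataset_normalization_on_random_sequences(self, dcm, rng):
        seqs = [
            CodingSequence(
                id=f"s{i}",
                nt=sm.sample_coding_sequence(
                    dcm, sm.random_protein(30, rng), "T", rng
                ),
                boundary_base="T",
            )
            for i in range(50)
        ]
        d = sm.dataset_distribution(seqs, sm.parse_motif_spec("GAAGAA"), dcm)
        assert d.total_mass == pytest.approx(1.0, abs=1e-9)


class TestStopConvention:
    def test_occurrence_overlapping_stop_never_counted(self, dcm):
        # gene K-stop: AAATAA contains AAT and ATA across the stop boundary,
        # but the modeled sequence is only the K codon
        seq = CodingSequence.from_cds("g", "AAATAA")
        for spec in ("AAT", "ATA", "TAA"):
            d = sm.sequence_distribution(seq, sm.parse_motif_spec(spec), dcm)
            assert_dists_close(d, sm.CountDistribution.point_mass(0))

    def test_codon_before_stop_conditions_on_t(self):
        # reference in which K before 'T' is always AAA, otherwise uniform-ish
        dcm = sm.build_dcm(sm.count_reference(["AAAAAGAAATAA"]))
        seq = CodingSequence.from_cds("g", "AAATAA")  # one K, boundary 'T'
        d = sm.sequence_distribution(seq, sm.parse_motif_spec("AAA"), dcm)
        # p(AAA|K,T) = 1, so the motif is certain
        assert_dists_close(d, sm.CountDistribution.point_mass(1))


class TestOracleEquivalence:
    @pytest.mark.parametrize("which", ["icm", "dcm"])
    def test_dp_equals_enumeration(self, which, icm, dcm, rng):
        model = icm if which == "icm" else dcm
        for _ in range(30):
            aa = random_protein_capped(rng)
            motif = random_motif(rng, aa)
            bb = [None, "T", "A", "C", "G"][int(rng.integers(0, 5))]
            bf = sm.brute_force_distribution(aa, motif, model, boundary_base=bb)
            seq = CodingSequence(
                id="t", nt=random_nt_for(rng, aa), boundary_base=bb
            )
            dp = sm.sequence_distribution(seq, motif, model)
            assert_dists_close(dp, bf)

    def test_mean_matches_positionwise_expectation_icm(self, icm, rng):
        """Under the ICM the expected count is the sum over feasible
        placements of the product of per-codon match probabilities —
        computed here without the DP."""
        for _ in range(10):
            aa = random_protein_capped(rng, max_codons=12, deg_cap=10**9)
            motif = random_motif(rng, aa)
            expected = 0.0
            for s in range(3 * len(aa) - motif.length + 1):
                for mem in motif.members:
                    p = 1.0
                    for c in range(s // 3, (s + motif.length - 1) // 3 + 1):
                        lo, hi = max(s, 3 * c), min(s + motif.length, 3 * c + 3)
                        frag = mem[lo - s : hi - s]
                        p *= sum(
                            icm.p_icm(cod)
                            for cod in sm.codons_for(aa[c])
                            if cod[lo - 3 * c : lo - 3 * c + len(frag)] == frag
                        )
                        if p == 0.0:
                            break
                    expected += p
            seq = CodingSequence(id="x", nt=random_nt_for(rng, aa))
            d = sm.sequence_distribution(seq, motif, icm)
            assert d.mean() == pytest.approx(expected, abs=1e-9)
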