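import pytest

import synmotif as sm
from synmotif.errors import MotifSpecError
from synmotif.motif import feasible_starts


class TestParsing:
    def test_bracket_expansion(self):
        assert set(sm.parse_motif_spec("AGACT[AG]").members) == {
            "AGACTA",
            "AGACTG",
        }
        assert set(sm.parse_motif_spec("AGACT[A/G]").members) == {
            "AGACTA",
            "AGACTG",
        }

    def test_revcomp_set(self):
        m = sm.parse_motif_spec("AACCTG", include_revcomp=True)
        assert set(m.members) == {"AACCTG", "CAGGTT"}

    def test_slash_separated_members(self):
        m = sm.parse_motif_spec("CCGGAA/CGGAAG")
        assert set(m.members) == {"CCGGAA", "CGGAAG"}

    @pytest.mark.parametrize(
        "bad", ["AAA/CCCC", "", "ACGU", "AC[", "AC]G", "A[]G"]
    )
    def test_malformed_specs_rejected(self, bad):
        with pytest.raises(MotifSpecError):
            sm.parse_motif_spec(bad)

    def test_motif_file(self, tmp_path):
        p = tmp_path / "motifs.txt"
        p.write_text(
            "# comment line\n"
            "CCGGAA/CGGAAG\tgabp_core\n"
            "AGACT[AG]\n"
            "\n"
            "TTTTTT  # trailing comment\n"
        )
        motifs = sm.parse_motif_file(str(p))
        assert [m.label for m in motifs] == [
            "gabp_core",
            "AGACTA/AGACTG",
            "TTTTTT",
        ]
        assert set(motifs[0].members) == {"CCGGAA", "CGGAAG"}


class TestSpan:
    @pytest.mark.parametrize(
        "l,span", [(1, 1), (2, 2), (3, 2), (4, 2), (6, 3), (7, 3), (10, 4)]
    )
    def test_span_values(self, l, span):
        assert sm.motif_span(l) == span

    def test_span_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            sm.motif_span(0)

    def test_span_is_true_maximum_overlap(self):
        # enumerate frame offsets: an l-mer starting at codon offset o
        # touches ceil((o + l) / 3) codons
        for l in range(1, 31):
            expected = max(-(-(o + l) // 3) for o in range(3))
            assert sm.motif_span(l) == expected


class TestCounting:
    @pytest.mark.parametrize(
        "seq,spec,n",
        [
            ("AAAAAA", "AAA", 4),
            ("AAAAAG", "AAA", 3),
            ("CCGGAAG", "CCGGAA/CGGAAG", 2),
            ("GGGG", "TTT", 0),
        ],
    )
    def test_overlapping_counts(self, seq, spec, n):
        assert sm.count_occurrences(seq, sm.parse_motif_spec(spec)) == n

    @pytest.mark.parametrize(
        "window,spec,n",
        [
            ("AAAAAAAAA", "AAAAAA", 3),
            ("ATGATG", "ATG", 1),
            ("GCAGCA", "ATG", 0),
        ],
    )
    def test_theta_counts_ends_in_last_codon(self, window, spec, n):
        assert sm.theta(window, sm.parse_motif_spec(spec)) == n

    def test_theta_rejects_wrong_window_length(self):
        with pytest.raises(ValueError):
            sm.theta("ATGATG", sm.parse_motif_spec("AAAAAA"))

    def test_theta_windows_tile_the_plain_count(self, rng):
        """Summing θ over sliding Δ-codon windows (5'-padded with a
        non-matching sentinel) reproduces the overlapping count."""
        from _utils import random_nt_for, random_protein_capped

        for _ in range(25):
            aa = random_protein_capped(rng, max_codons=12, deg_cap=10**9)
            nt = random_nt_for(rng, aa)
            from _utils import random_motif

            motif = random_motif(rng, aa)
            delta = motif.span
            padded = "X" * 3 * (delta - 1) + nt
            total = sum(
                sm.theta(padded[3 * k : 3 * (k + delta)], motif)
                for k in range(len(aa))
            )
            assert total == sm.count_occurrences(nt, motif)


class TestWindowCompatibility:
    @pytest.mark.parametrize(
        "aa,spec,possible",
        [
            ("M", "ATG", True),
            ("M", "AAA", False),
            ("KK", "TTT", False),
            ("KK", "AAA", True),
            ("W", "TGG", True),
        ],
    )
    def test_motif_possible_in_window(self, aa, spec, possible):
        assert sm.motif_possible_in_window(aa, sm.parse_motif_spec(spec)) is possible

    def test_stop_in_window_rejected(self):
        with pytest.raises(ValueError):
            sm.motif_possible_in_window("K*", sm.parse_motif_spec("AAA"))

    def test_feasible_starts_are_realizable(self, rng):
        """Every feasible start is witnessed by an explicit codon choice."""
        from _utils import random_motif, random_protein_capped

        for _ in range(20):
            aa = random_protein_capped(rng, max_codons=6, deg_cap=2000)
            motif = random_motif(rng, aa)
            starts = set(feasible_starts(aa, motif))
            from itertools import product

            witnessed = set()
            for combo in product(*(sm.codons_for(a) for a in aa)):
                nt = "".join(combo)
                for mem in motif.members:
                    s = nt.find(mem)
                    while s != -1:
                        witnessed.add(s)
                        s = nt.find(mem, s + 1)
            assert starts == witnessed


def test_codon_triple_sparsity_bound(rng):
    """Over random amino-acid triples, at most 864 distinct 6-mers are
    realizable (216 codon choices x 4 offsets) and at least 79% of the
    4096 6-mers are forbidden."""
    from synmotif.genetic_code import AMINO_ACIDS

    triples = [
        "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 3))
        for _ in range(200)
    ] + ["LLL", "SSS", "RRR"]  # worst-degeneracy corners
    stats = sm.hexamer_sparsity(triples)
    assert stats["max_realizable_6mers"] <= 864
    assert stats["min_forbidden_fraction"] >= 0.79
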