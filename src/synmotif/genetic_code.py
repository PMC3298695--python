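"""The standard genetic code: translation, synonymous sets, first-base structure.

The null models in this package condition on the amino-acid sequence, so the
degeneracy structure of the code is load-bearing: the set of codons compatible
with each residue bounds the dynamic-programming state space, and the fact that
17 of the 20 amino acids admit a single codon first base is what lets the
dinucleotide-corrected model cut its Markov chain into independent regions.
Only the standard nuclear code is supported.
"""

from __future__ import annotations

from functools import lru_cache

from .errors import FrameError

BASES = "ACGT"

STOP_SYMBOL = "*"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# Standard genetic code (NCBI table 1), codon -> one-letter amino acid.
CODON_TO_AA: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TO_AA.items():
    if _aa != STOP_SYMBOL:
        AA_TO_CODONS.setdefault(_aa, ())
        AA_TO_CODONS[_aa] = AA_TO_CODONS[_aa] + (_codon,)

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(AA_TO_CODONS))


class GeneticCode:
    """Codon/amino-acid tables of the standard genetic code.

    Instances are stateless views over module-level tables; the default
    instance :data:`STANDARD_CODE` is what every other module uses.
    """

    codon_to_aa = CODON_TO_AA
    aa_to_codons = AA_TO_CODONS
    stop_codons = STOP_CODONS
    amino_acids = AMINO_ACIDS

    def translate_cds(self, nt_sequence: str) -> str:
        """Translate an in-frame CDS to a one-letter amino-acid string.

        Stop codons (terminal or internal) translate to ``*``; the policy for
        rejecting internal stops belongs to input admission, not here.

        Raises
        ------
        FrameError
            If the length is not a multiple of 3 or a non-ACGT character occurs.
        """
        if len(nt_sequence) % 3 != 0:
            raise FrameError(
                f"sequence length {len(nt_sequence)} is not a multiple of 3: "
                f"{nt_sequence[:30]!r}"
            )
        out = []
        for i in range(0, len(nt_sequence), 3):
            codon = nt_sequence[i : i + 3]
            try:
                out.append(CODON_TO_AA[codon])
            except KeyError:
                raise FrameError(
                    f"invalid codon {codon!r} at nucleotide offset {i}"
                ) from None
        return "".join(out)

    def codons_for(self, aa: str) -> tuple[str, ...]:
        """Synonymous codon set of one amino acid (size 1..6)."""
        try:
            return AA_TO_CODONS[aa]
        except KeyError:
            raise KeyError(f"unknown amino-acid symbol {aa!r}") from None

    def first_bases(self, aa: str) -> frozenset[str]:
        """Distinct first bases over the synonymous codons of ``aa``.

        Singleton for 17 amino acids; two bases for Ser, Arg and Leu.
        """
        return _first_bases_cached(aa)

    def has_unique_first_base(self, aa: str) -> bool:
        return len(_first_bases_cached(aa)) == 1


@lru_cache(maxsize=None)
def _first_bases_cached(aa: str) -> frozenset[str]:
    try:
        codons = AA_TO_CODONS[aa]
    except KeyError:
        raise KeyError(f"unknown amino-acid symbol {aa!r}") from None
    return frozenset(c[0] for c in codons)


STANDARD_CODE = GeneticCode()


def translate_cds(nt_sequence: str) -> str:
    return STANDARD_CODE.translate_cds(nt_sequence)


def codons_for(aa: str) -> tuple[str, ...]:
    return STANDARD_CODE.codons_for(aa)


def first_bases(aa: str) -> frozenset[str]:
    return STANDARD_CODE.first_bases(aa)
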