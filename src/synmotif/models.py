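"""Null models of synonymous codon choice estimated from a reference CDS set.

Two nulls are supported.  The independent codon model (ICM) draws each codon
from the reference codon-usage table conditioned only on its amino acid,
``p(α|A) = F(α) / Σ_{α'∈A} F(α')``.  The dinucleotide-corrected codon model
(DCM) additionally conditions on the first base ``b`` of the 3'-neighboring
codon, ``p(α|A,b) = F(α,b) / F(A,b)``, where ``F(α,b)`` counts reference
occurrences of codon α immediately 5' of a codon starting with ``b``.  The
extra conditioning reproduces the reference dinucleotide usage across codon
boundaries — in particular the depletion of hypermutable CpG — which the ICM
cannot.  Sequences are generated (conceptually) 3'→5', so each codon's
conditioning base is already fixed when the codon is drawn.

Boundary conventions: a terminal stop codon is not a modeled codon but
supplies conditioning base 'T' (the first letter of all three stops) to its
5' neighbor; a fragment with no known 3' context uses the ICM marginal for
its 3'-most codon.  Cells never observed in the reference fall back to the
ICM conditional (or uniform for entirely unobserved amino acids) unless a
pseudocount is supplied, so every synonymous sequence keeps positive support
and exact p-values stay well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import EstimationError, FrameError
from .genetic_code import (
    AA_TO_CODONS,
    AMINO_ACIDS,
    BASES,
    CODON_TO_AA,
    STANDARD_CODE,
    STOP_SYMBOL,
)


@dataclass
class ReferenceCounts:
    """Observed codon and codon→next-base counts from a reference CDS set."""

    f_codon: dict[str, int] = field(default_factory=dict)
    f_codon_base: dict[tuple[str, str], int] = field(default_factory=dict)
    f_aa_base: dict[tuple[str, str], int] = field(default_factory=dict)
    n_sequences: int = 0

    def f(self, codon: str) -> int:
        return self.f_codon.get(codon, 0)

    def f_cb(self, codon: str, base: str) -> int:
        return self.f_codon_base.get((codon, base), 0)

    def f_ab(self, aa: str, base: str) -> int:
        return self.f_aa_base.get((aa, base), 0)


def count_reference(coding_sequences: list[str]) -> ReferenceCounts:
    """Tally F(α), F(α,b) and F(A,b) over in-frame reference sequences.

    Adjacent-codon pairs never span sequence boundaries.  A terminal stop
    contributes its first base 'T' as conditioning context for the preceding
    codon but is not itself counted; the 3'-terminal codon of a stop-less
    sequence contributes to F(α) only.
    """
    if not coding_sequences:
        raise EstimationError("cannot estimate a null model from zero sequences")
    counts = ReferenceCounts()
    for seq in coding_sequences:
        aa = STANDARD_CODE.translate_cds(seq)
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        has_stop = bool(aa) and aa[-1] == STOP_SYMBOL
        core = len(codons) - 1 if has_stop else len(codons)
        if STOP_SYMBOL in aa[:core]:
            raise FrameError(
                f"internal stop codon in reference sequence {seq[:30]!r}..."
            )
        for i in range(core):
            counts.f_codon[codons[i]] = counts.f_codon.get(codons[i], 0) + 1
            if i + 1 < len(codons):  # stop, if present, still supplies its 'T'
                b = codons[i + 1][0]
                key = (codons[i], b)
                counts.f_codon_base[key] = counts.f_codon_base.get(key, 0) + 1
                akey = (aa[i], b)
                counts.f_aa_base[akey] = counts.f_aa_base.get(akey, 0) + 1
        counts.n_sequences += 1
    return counts


@dataclass(frozen=True)
class IcmModel:
    """Independent codon model: p(α|A) from the reference usage table."""

    p_codon_given_aa: dict[str, dict[str, float]]

    is_dcm = False

    def p_icm(self, codon: str) -> float:
        aa = CODON_TO_AA[codon]
        return self.p_codon_given_aa[aa][codon]

    def p_cond(self, codon: str, base: str | None) -> float:
        # the ICM ignores 3' context
        return self.p_icm(codon)


@dataclass(frozen=True)
class DcmModel:
    """Dinucleotide-corrected codon model: p(α|A,b) with ICM fallback."""

    p_codon_given_aa_base: dict[tuple[str, str], dict[str, float]]
    fallback_icm: IcmModel

    is_dcm = True

    def p_icm(self, codon: str) -> float:
        return self.fallback_icm.p_icm(codon)

    def p_cond(self, codon: str, base: str | None) -> float:
        """p(α|A,b); ICM marginal when ``base`` is None (no 3' context) or the
        (A,b) cell was never observed."""
        if base is None:
            return self.p_icm(codon)
        aa = CODON_TO_AA[codon]
        cell = self.p_codon_given_aa_base.get((aa, base))
        if cell is None:
            return self.p_icm(codon)
        return cell.get(codon, 0.0)


def build_icm(counts: ReferenceCounts) -> IcmModel:
    """Normalize F(α) within each synonymous group; unobserved amino acids
    get the uniform distribution over their codons."""
    table: dict[str, dict[str, float]] = {}
    for aa in AMINO_ACIDS:
        codons = AA_TO_CODONS[aa]
        total = sum(counts.f(c) for c in codons)
        if total == 0:
            table[aa] = {c: 1.0 / len(codons) for c in codons}
        else:
            table[aa] = {c: counts.f(c) / total for c in codons}
    return IcmModel(table)


def build_dcm(counts: ReferenceCounts, pseudocount: float = 0.0) -> DcmModel:
    """Build p(α|A,b) tables; optional additive pseudocount regularizes
    sparse cells, otherwise unseen (A,b) cells defer to the ICM fallback."""
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be non-negative, got {pseudocount}")
    icm = build_icm(counts)
    table: dict[tuple[str, str], dict[str, float]] = {}
    for aa in AMINO_ACIDS:
        codons = AA_TO_CODONS[aa]
        for b in BASES:
            denom = counts.f_ab(aa, b) + pseudocount * len(codons)
            if denom <= 0:
                continue  # p_cond falls back to the ICM for this cell
            table[(aa, b)] = {
                c: (counts.f_cb(c, b) + pseudocount) / denom for c in codons
            }
    return DcmModel(table, icm)


def sequence_probability(
    model: IcmModel | DcmModel, nt_sequence: str, boundary_base: str | None = None
) -> float:
    """Probability of one synonymous re-encoding under the model.

    ``boundary_base`` is the first base of the codon 3'-adjacent to the
    sequence ('T' for a whole gene, by the stop-codon convention); if absent
    the 3'-most codon uses the ICM marginal.  Stop codons must not appear in
    the sequence itself.
    """
    aa = STANDARD_CODE.translate_cds(nt_sequence)
    if STOP_SYMBOL in aa:
        raise FrameError("stop codon inside sequence passed to sequence_probability")
    codons = [nt_sequence[i : i + 3] for i in range(0, len(nt_sequence), 3)]
    if not codons:
        return 1.0
    if not model.is_dcm:
        p = 1.0
        for c in codons:
            p *= model.p_icm(c)
        return p
    p = model.p_cond(codons[-1], boundary_base)
    for i in range(len(codons) - 1):
        p *= model.p_cond(codons[i], codons[i + 1][0])
    return p


def write_model_tsv(model: IcmModel | DcmModel, path: str) -> None:
    """Dump a fitted model as TSV (amino acid, base, codon, probability);
    '-' marks the unconditioned ICM rows."""
    with open(path, "w") as fh:
        fh.write("aa\tbase\tcodon\tprobability\n")
        if model.is_dcm:
            for (aa, b), cell in sorted(model.p_codon_given_aa_base.items()):
                for codon, p in sorted(cell.items()):
                    fh.write(f"{aa}\t{b}\t{codon}\t{p:.12g}\n")
            icm = model.fallback_icm
        else:
            icm = model
        for aa, cell in sorted(icm.p_codon_given_aa.items()):
            for codon, p in sorted(cell.items()):
                fh.write(f"{aa}\t-\t{codon}\t{p:.12g}\n")
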