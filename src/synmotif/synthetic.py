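"""Brute-force oracle, null-model samplers and synthetic benchmarks.

Everything the test bed needs without external data lives here: the
definitional enumeration of the count distribution (the independent check of
the dynamic program), samplers that draw synonymous sequences from a fitted
null, a synthetic reference generator with tunable CpG depletion (so the
dinucleotide contrast between the two nulls is exercised), the
motif-insertion power experiment, and dinucleotide composition diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .distribution import CountDistribution
from .engine import CodingSequence
from .errors import EnumerationGuardError
from .genetic_code import (
    AMINO_ACIDS,
    BASES,
    STANDARD_CODE,
    STOP_CODONS,
    STOP_SYMBOL,
)
from .models import DcmModel, IcmModel, sequence_probability
from .motif import Motif, count_occurrences

DEFAULT_ENUMERATION_GUARD = 10 ** 6


def brute_force_distribution(
    aa: str,
    motif: Motif,
    model: IcmModel | DcmModel,
    boundary_base: str | None = None,
    guard: int = DEFAULT_ENUMERATION_GUARD,
) -> CountDistribution:
    """The definitional count distribution by exhaustive enumeration.

    Every synonymous nucleotide sequence of ``aa`` is generated, weighted by
    its model probability, and its occurrence count tallied.  Exponential in
    sequence length; guarded, and entirely independent of the DP code path.
    """
    codon_sets = [STANDARD_CODE.codons_for(a) for a in aa]
    size = 1
    for s in codon_sets:
        size *= len(s)
        if size > guard:
            raise EnumerationGuardError(
                f"enumeration of {aa!r} needs > {guard} sequences"
            )
    tallies: dict[int, float] = {}
    for combo in product(*codon_sets):
        nt = "".join(combo)
        p = sequence_probability(model, nt, boundary_base)
        k = count_occurrences(nt, motif)
        tallies[k] = tallies.get(k, 0.0) + p
    if not tallies:
        return CountDistribution.point_mass(0)
    return CountDistribution.from_dict(tallies)


# per-model cache of cumulative codon-choice tables keyed (aa, 3' base);
# keyed by object identity, with the model kept in the entry to detect reuse
_SAMPLER_TABLES: dict[int, tuple[object, dict]] = {}


def _choice_table(
    model: IcmModel | DcmModel, aa: str, next_base: str | None
) -> tuple[tuple[str, ...], np.ndarray]:
    ent = _SAMPLER_TABLES.get(id(model))
    if ent is None or ent[0] is not model:
        ent = (model, {})
        _SAMPLER_TABLES[id(model)] = ent
    tables = ent[1]
    key = (aa, next_base if model.is_dcm else None)
    tab = tables.get(key)
    if tab is None:
        choices = STANDARD_CODE.codons_for(aa)
        if model.is_dcm:
            weights = [model.p_cond(c, next_base) for c in choices]
        else:
            weights = [model.p_icm(c) for c in choices]
        total = sum(weights)
        if total <= 0:
            raise ValueError(f"no codon of {aa!r} has positive probability")
        tab = (choices, np.cumsum(weights) / total)
        tables[key] = tab
    return tab


def sample_coding_sequence(
    model: IcmModel | DcmModel,
    aa: str,
    boundary_base: str | None = None,
    rng: np.random.Generator | int | None = None,
) -> str:
    """Draw one synonymous re-encoding of ``aa`` from the null.

    The DCM draws codons 3'→5', each conditioned on the first base of the
    previously drawn (3'-neighbor) codon; the ICM draws independently.
    """
    rng = np.random.default_rng(rng)
    codons: list[str] = [""] * len(aa)
    next_base = boundary_base
    u = rng.random(len(aa))
    for i in range(len(aa) - 1, -1, -1):
        choices, cum = _choice_table(model, aa[i], next_base)
        codons[i] = choices[int(np.searchsorted(cum, u[i] * cum[-1]))]
        next_base = codons[i][0]
    return "".join(codons)


def random_protein(
    n_codons: int, rng: np.random.Generator | int | None = None
) -> str:
    """i.i.d. uniform amino-acid string (no stops) — the default synthetic
    protein composition."""
    rng = np.random.default_rng(rng)
    idx = rng.integers(0, len(AMINO_ACIDS), size=n_codons)
    return "".join(AMINO_ACIDS[i] for i in idx)


def synthetic_reference(
    n_seqs: int = 200,
    len_codons: int = 200,
    cpg_depletion: float = 0.25,
    rng: np.random.Generator | int | None = None,
) -> list[str]:
    """Sample a reference CDS corpus from a first-order nucleotide chain
    with the CG dinucleotide down-weighted by ``cpg_depletion``.

    CpG hypermutability is the dominant neutral dinucleotide bias in
    vertebrate coding sequence; depleting CG in the generator gives the
    corpus boundary-dinucleotide structure that an independent-codon null
    cannot reproduce but the dinucleotide-corrected null can.  Sequences are
    in frame, free of internal stops, and end with a stop codon.
    """
    rng = np.random.default_rng(rng)
    trans = np.ones((4, 4))
    trans[BASES.index("C"), BASES.index("G")] = cpg_depletion
    trans /= trans.sum(axis=1, keepdims=True)
    cum = trans.cumsum(axis=1)
    out = []
    for _ in range(n_seqs):
        codons: list[str] = []
        prev = int(rng.integers(0, 4))
        first = True
        while len(codons) < len_codons:
            # draw one codon from the chain; redraw in place if it is a stop
            b = prev
            picks = []
            for k in range(3):
                if first and k == 0:
                    picks.append(b)
                else:
                    b = int(np.searchsorted(cum[b], rng.random()))
                    picks.append(b)
            codon = "".join(BASES[i] for i in picks)
            if codon in STOP_CODONS:
                continue
            codons.append(codon)
            prev = b
            first = False
        stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
        out.append("".join(codons) + stop)
    return out


def generate_insertion_dataset(
    model: IcmModel | DcmModel,
    n_seqs: int,
    len_codons: int,
    motif: Motif,
    n_inserted: int,
    rng: np.random.Generator | int | None = None,
    aa_strings: list[str] | None = None,
) -> list[CodingSequence]:
    """Null-sampled sequences with the motif overwritten into ``n_inserted``
    of them at uniformly random positions.

    The benchmark for detection power: sample ``n_seqs`` sequences from the
    null (3'-most codon treated as preceding a stop, boundary base 'T'),
    choose ``n_inserted`` distinct sequences, and overwrite one member of
    the motif at a random offset in each; an overwrite that would create a
    premature stop codon is redrawn at another location.
    """
    if n_inserted > n_seqs:
        raise ValueError("cannot insert into more sequences than exist")
    rng = np.random.default_rng(rng)
    if motif.length > 3 * len_codons:
        raise ValueError("motif longer than the sequences")
    null = []
    for i in range(n_seqs):
        aa = aa_strings[i] if aa_strings is not None else random_protein(
            len_codons, rng
        )
        nt = sample_coding_sequence(model, aa, boundary_base="T", rng=rng)
        null.append(
            CodingSequence(id=f"syn{i}", nt=nt, has_terminal_stop=True,
                           boundary_base="T")
        )
    return insert_motif_copies(null, motif, n_inserted, rng)


def insert_motif_copies(
    seqs: list[CodingSequence],
    motif: Motif,
    n_inserted: int,
    rng: np.random.Generator | int | None = None,
) -> list[CodingSequence]:
    """Overwrite one motif member into ``n_inserted`` distinct sequences at
    uniformly random positions, redrawing any location that would create a
    premature stop codon.  The input list is not modified, so one null
    sample can serve many motifs and insertion levels."""
    if n_inserted > len(seqs):
        raise ValueError("cannot insert into more sequences than exist")
    rng = np.random.default_rng(rng)
    l = motif.length
    out = list(seqs)
    targets = rng.choice(len(seqs), size=n_inserted, replace=False)
    for t in targets:
        seq = out[int(t)]
        if l > len(seq.nt):
            raise ValueError("motif longer than the sequences")
        member = motif.members[int(rng.integers(0, len(motif.members)))]
        for _attempt in range(10_000):
            pos = int(rng.integers(0, len(seq.nt) - l + 1))
            cand = seq.nt[:pos] + member + seq.nt[pos + l :]
            if STOP_SYMBOL not in STANDARD_CODE.translate_cds(cand):
                out[int(t)] = CodingSequence(
                    id=seq.id, nt=cand,
                    has_terminal_stop=seq.has_terminal_stop,
                    boundary_base=seq.boundary_base,
                )
                break
        else:
            raise RuntimeError(
                f"could not place motif {motif.label!r} without a stop codon"
            )
    return out


@dataclass(frozen=True)
class DinucleotideTable:
    """Counts and frequencies of the 16 dinucleotides, within-sequence only."""

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[str, float]:
        t = self.total
        return {d: c / t for d, c in self.counts.items()}

    def as_vector(self) -> np.ndarray:
        """Frequencies in lexicographic dinucleotide order."""
        t = self.total
        return np.array(
            [self.counts[a + b] / t for a in BASES for b in BASES]
        )


def dinucleotide_frequencies(seqs: list[str]) -> DinucleotideTable:
    """All overlapping dinucleotides within each sequence (codon boundaries
    included), never across sequences."""
    if not seqs:
        raise ValueError("need at least one sequence")
    counts = {a + b: 0 for a in BASES for b in BASES}
    for s in seqs:
        for i in range(len(s) - 1):
            counts[s[i : i + 2]] += 1
    return DinucleotideTable(counts)


def strip_terminal_stop(seq: str) -> str:
    return seq[:-3] if len(seq) >= 3 and seq[-3:] in STOP_CODONS else seq


def realizable_kmers_in_window(aa_window: str, k: int = 6) -> set[str]:
    """All distinct k-mers realizable over every codon choice and offset of
    an amino-acid window."""
    codon_sets = [STANDARD_CODE.codons_for(a) for a in aa_window]
    found: set[str] = set()
    n_bases = 3 * len(aa_window)
    for combo in product(*codon_sets):
        s = "".join(combo)
        for off in range(n_bases - k + 1):
            found.add(s[off : off + k])
    return found


def hexamer_sparsity(
    triples: list[str] | None = None,
) -> dict[str, float]:
    """Sparsity of 6-mers over codon triples: how many of the 4096 6-mers
    can occur in a 3-codon window, over the given (default: all 20^3)
    amino-acid triples.

    A triple has at most 6^3 = 216 codon choices and 4 offsets for a 6-mer
    in its 9 bases, so at most 864 realizable 6-mers — at least 79% of all
    6-mers are forbidden in any triple.  This sparsity is what makes the
    independent-region decomposition effective.
    """
    if triples is None:
        triples = ["".join(t) for t in product(AMINO_ACIDS, repeat=3)]
    max_realizable = 0
    for tri in triples:
        n = len(realizable_kmers_in_window(tri, 6))
        if n > max_realizable:
            max_realizable = n
    return {
        "n_triples": len(triples),
        "max_realizable_6mers": max_realizable,
        "min_forbidden_fraction": 1.0 - max_realizable / 4096.0,
    }
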