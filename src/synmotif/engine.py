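"""Exact motif-count distributions by dynamic programming over synonymous
re-encodings.

Given an amino-acid sequence and a null model of codon choice, the copy
number X of a motif over all synonymous nucleotide sequences is a random
variable whose exact distribution D(X) this module computes.  Direct
enumeration is exponential in sequence length; instead the induction walks
the sequence one codon at a time keeping, for every codon context of the
last Δ−1 codons (Δ = motif span), the sub-distribution of counts accumulated
so far.  Appending a codon adds the number of occurrences that begin in it
(each occurrence is attributed to its 5'-most codon, so none is counted
twice) and multiplies by the model probability of the codon.

The walk runs 3'→5': under the dinucleotide-corrected model each codon is
conditioned on the first base of its 3' neighbor, which in this direction is
already part of the DP context, so every probability factor is applied
exactly once and no separate finalization weighting is needed.

Most motifs are impossible over long stretches of protein sequence (at most
864 of the 4096 6-mers are realizable over any codon triple), so sequences
split into short independent regions outside which the motif cannot occur;
per-region distributions are convolved.  Under the DCM, a split is exact
only where the Markov chain is cut by an amino acid whose first base is
forced (17 of 20 residues); regions whose gap lacks such a cut are merged
before the DP, and a region's 3' boundary base is resolved by chaining the
conditional tables from the nearest forced base (or the sequence boundary)
back to the region edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .distribution import CountDistribution, combine_all
from .errors import FrameError
from .genetic_code import STANDARD_CODE, STOP_SYMBOL
from .models import DcmModel, IcmModel
from .motif import Motif, feasible_starts

_MASS_TOL = 1e-6


@dataclass(frozen=True)
class CodingSequence:
    """An in-frame coding nucleotide sequence and its translation.

    A terminal stop codon is stored as a flag, not as sequence content, and
    fixes ``boundary_base='T'`` (all three stops start with T); motifs are
    never sought overlapping the stop.  ``boundary_base=None`` marks a
    fragment with unknown 3' context.
    """

    id: str
    nt: str
    aa: str = ""
    has_terminal_stop: bool = False
    boundary_base: str | None = None

    def __post_init__(self) -> None:
        if not self.aa:
            object.__setattr__(self, "aa", STANDARD_CODE.translate_cds(self.nt))
        if STOP_SYMBOL in self.aa:
            raise FrameError(f"stop codon inside coding sequence {self.id!r}")
        if len(self.nt) != 3 * len(self.aa):
            raise FrameError(f"nt/aa length mismatch in {self.id!r}")

    @classmethod
    def from_cds(
        cls, id: str, nt: str, boundary_base: str | None = None
    ) -> "CodingSequence":
        """Build from a CDS that may end in a stop codon; the stop is
        detached and implies boundary base 'T'."""
        aa = STANDARD_CODE.translate_cds(nt)
        if aa.endswith(STOP_SYMBOL):
            return cls(id, nt[:-3], aa[:-1], has_terminal_stop=True,
                       boundary_base="T")
        return cls(id, nt, aa, has_terminal_stop=False,
                   boundary_base=boundary_base)

    @property
    def n_codons(self) -> int:
        return len(self.aa)


@dataclass(frozen=True)
class Region:
    """A maximal codon stretch of one sequence inside which a motif can
    occur; no occurrence can extend across its edges."""

    parent_id: str
    parent_aa: str
    parent_boundary_base: str | None
    start: int  # codon index, 0-based
    end: int    # exclusive
    n_feasible: int  # feasible occurrence start positions inside the region

    @property
    def aa_string(self) -> str:
        return self.parent_aa[self.start : self.end]

    def __len__(self) -> int:
        return self.end - self.start


def segment_regions(seq: CodingSequence, motif: Motif) -> list[Region]:
    """Split a sequence into independent regions for one motif.

    Feasible occurrence placements (some codon assignment realizes a member
    there) are projected to codon intervals and overlapping intervals merged;
    codons no occurrence can touch are excluded.  Splits whose gap contains
    no amino acid with a forced first base are additionally merged, keeping
    per-region convolution exact under the DCM.
    """
    starts = feasible_starts(seq.aa, motif)
    if not starts:
        return []
    l = motif.length
    intervals: list[list[int]] = []
    counts: list[int] = []
    for s in starts:
        c0, c1 = s // 3, (s + l - 1) // 3
        if intervals and c0 <= intervals[-1][1]:
            intervals[-1][1] = max(intervals[-1][1], c1)
            counts[-1] += 1
        else:
            intervals.append([c0, c1])
            counts.append(1)
    # merge splits the DCM chain cannot cut
    merged: list[list[int]] = [intervals[0]]
    mcounts = [counts[0]]
    for (c0, c1), k in zip(intervals[1:], counts[1:]):
        gap = seq.aa[merged[-1][1] + 1 : c0]
        if any(STANDARD_CODE.has_unique_first_base(a) for a in gap):
            merged.append([c0, c1])
            mcounts.append(k)
        else:
            merged[-1][1] = c1
            mcounts[-1] += k
    return [
        Region(seq.id, seq.aa, seq.boundary_base, c0, c1 + 1, k)
        for (c0, c1), k in zip(merged, mcounts)
    ]


def _boundary_base_distribution(
    region: Region, model: DcmModel
) -> dict[str, float] | None:
    """Marginal distribution of the first base of the codon 3'-adjacent to
    the region, under the DCM applied to the codons outside the region.

    Scans 3' to the nearest amino acid with a forced first base (the chain
    is deterministic there) or to the sequence boundary, then chains the
    conditional tables back 5' to the region edge.  Returns None when the
    region reaches the 3' end of a fragment with no known context (the
    region's 3'-most codon then uses the ICM marginal).
    """
    aa = region.parent_aa
    n = len(aa)
    e = region.end
    if e == n:
        bb = region.parent_boundary_base
        return {bb: 1.0} if bb is not None else None
    j = e
    while j < n and not STANDARD_CODE.has_unique_first_base(aa[j]):
        j += 1
    if j < n:
        base = next(iter(STANDARD_CODE.first_bases(aa[j])))
        cur: dict[str, float] | None = {base: 1.0}
    else:
        bb = region.parent_boundary_base
        cur = {bb: 1.0} if bb is not None else None
    # chain back over the (rare) run of first-base-degenerate residues
    for i in range(j - 1, e - 1, -1):
        nxt: dict[str, float] = {}
        for codon in STANDARD_CODE.codons_for(aa[i]):
            if cur is None:
                p = model.p_icm(codon)
            else:
                p = sum(w * model.p_cond(codon, b) for b, w in cur.items())
            if p > 0:
                nxt[codon[0]] = nxt.get(codon[0], 0.0) + p
        total = sum(nxt.values())
        cur = {b: p / total for b, p in nxt.items()}
    return cur


@lru_cache(maxsize=None)
def _starts_in_first_codon(window: str, motif: Motif) -> int:
    """Occurrences of any member that begin in the first codon of a window
    of at most Δ codons (the 3'→5' mirror of the per-step count θ)."""
    members = motif.member_set
    l = motif.length
    n = 0
    for s in range(min(3, len(window))):
        if s + l <= len(window) and window[s : s + l] in members:
            n += 1
    return n


def region_distribution(
    region: Region,
    motif: Motif,
    model: IcmModel | DcmModel,
    method: str = "direct",
) -> CountDistribution:
    """Exact count distribution over all codon assignments of one region."""
    aa_r = region.aa_string
    n_r = len(aa_r)
    delta = motif.span
    kmax = region.n_feasible
    is_dcm = model.is_dcm
    bdist = _boundary_base_distribution(region, model) if is_dcm else None

    init = np.zeros(kmax + 1)
    init[0] = 1.0
    states: dict[tuple[str, ...], np.ndarray] = {(): init}
    for i in range(n_r - 1, -1, -1):
        new_states: dict[tuple[str, ...], np.ndarray] = {}
        last = i == n_r - 1
        for ctx, arr in states.items():
            ctx_str = "".join(ctx)
            for codon in STANDARD_CODE.codons_for(aa_r[i]):
                if last:
                    if not is_dcm:
                        w = model.p_icm(codon)
                    elif bdist is None:
                        w = model.p_icm(codon)
                    else:
                        w = sum(
                            p * model.p_cond(codon, b) for b, p in bdist.items()
                        )
                elif is_dcm:
                    w = model.p_cond(codon, ctx[0][0])
                else:
                    w = model.p_icm(codon)
                if w == 0.0:
                    continue
                add = _starts_in_first_codon(codon + ctx_str, motif)
                new_ctx = ((codon,) + ctx)[: delta - 1]
                acc = new_states.get(new_ctx)
                if acc is None:
                    acc = np.zeros(kmax + 1)
                    new_states[new_ctx] = acc
                if add:
                    acc[add:] += w * arr[: kmax + 1 - add]
                else:
                    acc += w * arr
        states = new_states

    probs = np.zeros(kmax + 1)
    for arr in states.values():
        probs += arr
    mass = probs.sum()
    if abs(mass - 1.0) > _MASS_TOL:
        raise RuntimeError(
            f"region distribution mass {mass} drifted beyond tolerance "
            f"(region {region.parent_id}[{region.start}:{region.end}])"
        )
    return CountDistribution(probs).trimmed()


def sequence_distribution(
    seq: CodingSequence,
    motif: Motif,
    model: IcmModel | DcmModel,
    segmentation: bool = True,
    method: str = "direct",
) -> CountDistribution:
    """Count distribution for one sequence; convolution of its regions.

    ``segmentation=False`` runs one DP over the whole sequence (identical
    result, no sparsity speedup) — kept as a correctness cross-check.
    """
    if segmentation:
        regions = segment_regions(seq, motif)
    else:
        k = len(feasible_starts(seq.aa, motif))
        regions = (
            [Region(seq.id, seq.aa, seq.boundary_base, 0, seq.n_codons, k)]
            if seq.n_codons
            else []
        )
    if not regions:
        return CountDistribution.point_mass(0)
    parts = [region_distribution(r, motif, model, method=method) for r in regions]
    return combine_all(parts, method=method)


def dataset_distribution(
    seqs: list[CodingSequence],
    motif: Motif,
    model: IcmModel | DcmModel,
    segmentation: bool = True,
    method: str = "direct",
) -> CountDistribution:
    """Count distribution over an independent sequence set; occurrences
    never span sequence boundaries."""
    if not seqs:
        raise ValueError("dataset_distribution requires at least one sequence")
    parts = [
        sequence_distribution(s, motif, model, segmentation=segmentation,
                              method=method)
        for s in seqs
    ]
    return combine_all(parts, method=method)
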