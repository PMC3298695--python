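"""Motifs as equal-length k-mer sets, occurrence counting, and codon-window
compatibility.

A motif is a non-empty set of equal-length DNA words; an occurrence of any
member counts as an occurrence of the motif.  Degenerate positions are written
with brackets (``AGACT[AG]`` expands to ``AGACTA`` and ``AGACTG``), explicit
alternatives with ``/`` (``AACCTG/CAGGTT``); this set representation captures
base correlations that IUPAC symbols cannot.  The *span* Δ of an l-mer is the
maximum number of codons a single occurrence can overlap, ``ceil((l+2)/3)``:
a 6-mer starting at the third base of a codon reaches into a third codon, so
Δ(6) = 3.  Δ fixes the context width of the dynamic program.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from typing import Iterable, Iterator

from .errors import MotifSpecError
from .genetic_code import BASES, STANDARD_CODE, STOP_SYMBOL

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(kmer: str) -> str:
    return kmer.translate(_COMPLEMENT)[::-1]


def motif_span(length: int) -> int:
    """Maximum number of codons an ``length``-mer occurrence can overlap.

    Equals ``ceil((length + 2) / 3)``: the worst frame offset places the first
    base at the third position of a codon.
    """
    if length < 1:
        raise ValueError(f"motif length must be >= 1, got {length}")
    return (length + 2 + 2) // 3  # ceil((l + 2) / 3)


@dataclass(frozen=True)
class Motif:
    """An equal-length k-mer set with its codon span and display label."""

    members: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise MotifSpecError("motif has no members")
        lengths = {len(m) for m in self.members}
        if len(lengths) != 1:
            raise MotifSpecError(
                f"motif members have mixed lengths {sorted(lengths)}; "
                "evaluate each length as a separate motif"
            )
        for m in self.members:
            if not m or any(b not in BASES for b in m):
                raise MotifSpecError(f"motif member {m!r} is not an ACGT string")
        if len(set(self.members)) != len(self.members):
            object.__setattr__(self, "members", tuple(dict.fromkeys(self.members)))
        if not self.label:
            object.__setattr__(self, "label", "/".join(self.members))

    @property
    def length(self) -> int:
        return len(self.members[0])

    @property
    def span(self) -> int:
        return motif_span(self.length)

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)


def _split_members(token: str) -> list[str]:
    """Split on '/' outside brackets, so ``AGACT[A/G]`` stays one token."""
    parts, depth, cur = [], 0, []
    for ch in token:
        if ch == "[":
            depth += 1
            cur.append(ch)
        elif ch == "]":
            depth -= 1
            if depth < 0:
                raise MotifSpecError(f"unbalanced ']' in motif spec {token!r}")
            cur.append(ch)
        elif ch == "/" and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    if depth != 0:
        raise MotifSpecError(f"unbalanced '[' in motif spec {token!r}")
    parts.append("".join(cur))
    return [p for p in parts if p]


def _expand_brackets(token: str) -> list[str]:
    """Expand positional degeneracy: ``AGACT[AG]`` -> AGACTA, AGACTG."""
    groups: list[str] = []
    i = 0
    while i < len(token):
        if token[i] == "[":
            j = token.index("]", i)
            alts = token[i + 1 : j].replace("/", "")
            if not alts:
                raise MotifSpecError(f"empty bracket group in {token!r}")
            groups.append(alts)
            i = j + 1
        else:
            groups.append(token[i])
            i += 1
    return ["".join(p) for p in product(*groups)]


def parse_motif_spec(
    spec: str | Iterable[str], include_revcomp: bool = False, label: str = ""
) -> Motif:
    """Parse motif text token(s) into a :class:`Motif`.

    ``spec`` is a single token (members joined by '/', brackets for
    positional degeneracy) or an iterable of tokens.  With
    ``include_revcomp`` the reverse complement of every member is added.
    """
    if isinstance(spec, str):
        tokens = _split_members(spec.strip().upper())
    else:
        tokens = [t for s in spec for t in _split_members(str(s).strip().upper())]
    if not tokens:
        raise MotifSpecError("empty motif specification")
    members: list[str] = []
    for tok in tokens:
        members.extend(_expand_brackets(tok))
    if include_revcomp:
        members.extend(reverse_complement(m) for m in list(members))
    return Motif(tuple(dict.fromkeys(members)), label=label)


def parse_motif_file(path: str, include_revcomp: bool = False) -> list[Motif]:
    """Read a motif file: one motif per line, members separated by '/',
    '#' comments, optional label after a tab."""
    motifs = []
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].rstrip("\n").strip()
            if not line:
                continue
            fields = line.split("\t")
            spec = fields[0].strip()
            lab = fields[1].strip() if len(fields) > 1 else ""
            motifs.append(parse_motif_spec(spec, include_revcomp, label=lab))
    if not motifs:
        raise MotifSpecError(f"no motifs found in {path}")
    return motifs


def count_occurrences(nt_sequence: str, motif: Motif) -> int:
    """Overlapping occurrences of any member, all reading frames.

    Members are equal-length, so at most one can match a given start; summing
    per-member overlapping counts never double counts.
    """
    total = 0
    for m in motif.members:
        start = nt_sequence.find(m)
        while start != -1:
            total += 1
            start = nt_sequence.find(m, start + 1)
    return total


def theta(window: str, motif: Motif) -> int:
    """Occurrences (any member) whose final base lies in the last codon of a
    Δ-codon window; the per-step count increment of the induction."""
    span = motif.span
    if len(window) != 3 * span:
        raise ValueError(
            f"window must be exactly {3 * span} bases for this motif, "
            f"got {len(window)}"
        )
    l = motif.length
    members = motif.member_set
    n = 0
    # ends (0-based, inclusive) inside the last codon: 3*span-3 .. 3*span-1
    for end in range(3 * span - 3, 3 * span):
        start = end - l + 1
        if start >= 0 and window[start : end + 1] in members:
            n += 1
    return n


@lru_cache(maxsize=None)
def _codon_compatible(aa: str, rel: int, fragment: str) -> bool:
    """Can some synonymous codon of ``aa`` show ``fragment`` at codon
    positions rel..rel+len(fragment)-1?"""
    for codon in STANDARD_CODE.codons_for(aa):
        if codon[rel : rel + len(fragment)] == fragment:
            return True
    return False


def _member_feasible_at(aa_string: str, member: str, start: int) -> bool:
    """Is there a codon assignment of ``aa_string`` realizing ``member`` at
    base offset ``start``?  Codons are constrained independently."""
    l = len(member)
    first_codon = start // 3
    last_codon = (start + l - 1) // 3
    for c in range(first_codon, last_codon + 1):
        lo = max(start, 3 * c)
        hi = min(start + l, 3 * c + 3)
        if not _codon_compatible(aa_string[c], lo - 3 * c, member[lo - start : hi - start]):
            return False
    return True


def feasible_starts(aa_string: str, motif: Motif) -> list[int]:
    """Base offsets (0-based) where some member can occur for some codon
    choice; drives the sparse-region segmentation and the per-region count
    bound."""
    l = motif.length
    n_bases = 3 * len(aa_string)
    out = []
    for s in range(n_bases - l + 1):
        if any(_member_feasible_at(aa_string, m, s) for m in motif.members):
            out.append(s)
    return out


def motif_possible_in_window(aa_window: str, motif: Motif) -> bool:
    """True iff some synonymous codon assignment of ``aa_window`` contains at
    least one member occurrence at any offset."""
    if STOP_SYMBOL in aa_window:
        raise ValueError("stop symbol inside amino-acid window")
    l = motif.length
    n_bases = 3 * len(aa_window)
    for s in range(n_bases - l + 1):
        if any(_member_feasible_at(aa_window, m, s) for m in motif.members):
            return True
    return False


def iter_all_kmers(k: int) -> Iterator[str]:
    """All 4^k DNA k-mers in lexicographic order (exhaustive scans)."""
    for tup in product(BASES, repeat=k):
        yield "".join(tup)
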