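"""Shared helpers for the test suite."""

from __future__ import annotations

import numpy as np

import synmotif as sm
from synmotif.genetic_code import AMINO_ACIDS


def assert_dists_close(d1, d2, tol: float = 1e-9) -> None:
    """Elementwise comparison of two count distributions, padding the
    shorter support with zeros."""
    m = max(len(d1), len(d2))
    a = np.zeros(m)
    a[: len(d1)] = d1.probs
    b = np.zeros(m)
    b[: len(d2)] = d2.probs
    err = float(np.abs(a - b).max())
    assert err <= tol, f"distributions differ by {err:.3g} (> {tol:g})"


def random_protein_capped(
    rng: np.random.Generator, max_codons: int = 10, deg_cap: int = 3000
) -> str:
    """Random amino-acid string whose synonymous-space size stays below
    ``deg_cap`` so the brute-force oracle remains cheap."""
    while True:
        n = int(rng.integers(1, max_codons + 1))
        aa = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, n))
        deg = 1
        for a in aa:
            deg *= len(sm.codons_for(a))
        if deg <= deg_cap:
            return aa


def random_motif(
    rng: np.random.Generator,
    aa: str,
    lmin: int = 3,
    lmax: int = 7,
    p_realizable: float = 0.5,
    p_degenerate: float = 0.3,
) -> sm.Motif:
    """Random k-mer (set); with probability ``p_realizable`` the first member
    is cut from a realizable re-encoding of ``aa`` so counts are often > 0."""
    l = int(rng.integers(lmin, lmax + 1))
    members: list[str] = []
    if rng.random() < p_realizable and 3 * len(aa) >= l:
        nt = "".join(
            sm.codons_for(a)[rng.integers(0, len(sm.codons_for(a)))] for a in aa
        )
        s = int(rng.integers(0, 3 * len(aa) - l + 1))
        members.append(nt[s : s + l])
    else:
        members.append("".join("ACGT"[i] for i in rng.integers(0, 4, l)))
    if rng.random() < p_degenerate:
        members.append("".join("ACGT"[i] for i in rng.integers(0, 4, l)))
    return sm.Motif(tuple(dict.fromkeys(members)))


def random_nt_for(rng: np.random.Generator, aa: str) -> str:
    """A uniformly random synonymous re-encoding of ``aa``."""
    return "".join(
        sm.codons_for(a)[rng.integers(0, len(sm.codons_for(a)))] for a in aa
    )
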