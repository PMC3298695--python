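"""Count distributions and their algebra.

A :class:`CountDistribution` is the dense array ``probs[k] = P(X = k)`` of a
motif's copy number under a null model.  Counts over disjoint independent
regions add, so distributions convolve; the convolution of many small
distributions is scheduled smallest-first, which keeps intermediate products
short for the common case of many length-O(1) regions.

Direct polynomial multiplication is the default convolution.  An FFT variant
is available; it can produce slightly negative coefficients from round-off,
which are clamped to zero and the mass rescaled.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import fftconvolve

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class CountDistribution:
    """Probability distribution over motif copy numbers 0..max_count."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.probs, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("distribution must be a non-empty 1-d array")
        if np.any(arr < 0):
            raise ValueError("distribution has negative entries")
        object.__setattr__(self, "probs", arr)

    @classmethod
    def point_mass(cls, count: int = 0) -> "CountDistribution":
        arr = np.zeros(count + 1)
        arr[count] = 1.0
        return cls(arr)

    @classmethod
    def from_dict(cls, d: dict[int, float]) -> "CountDistribution":
        arr = np.zeros(max(d) + 1)
        for k, p in d.items():
            arr[k] = p
        return cls(arr)

    @property
    def max_count(self) -> int:
        return len(self.probs) - 1

    @property
    def total_mass(self) -> float:
        return float(self.probs.sum())

    def is_normalized(self, tol: float = _NORM_TOL) -> bool:
        return abs(self.total_mass - 1.0) <= tol

    def mean(self) -> float:
        return float(np.dot(np.arange(len(self.probs)), self.probs))

    def variance(self) -> float:
        k = np.arange(len(self.probs))
        m = self.mean()
        return float(np.dot((k - m) ** 2, self.probs))

    def tail_ge(self, observed: int) -> float:
        """P(X >= observed); 0 beyond the support, 1 at observed <= 0."""
        if observed <= 0:
            return self.total_mass
        if observed > self.max_count:
            return 0.0
        return float(self.probs[observed:].sum())

    def trimmed(self) -> "CountDistribution":
        """Drop trailing structural zeros (keep at least P(0))."""
        nz = np.nonzero(self.probs)[0]
        hi = int(nz[-1]) if nz.size else 0
        return CountDistribution(self.probs[: hi + 1].copy())

    def __len__(self) -> int:
        return len(self.probs)


def convolve(
    d1: CountDistribution, d2: CountDistribution, method: str = "direct"
) -> CountDistribution:
    """Distribution of the sum of two independent counts.

    ``method='direct'`` multiplies the generating functions term by term;
    ``method='fft'`` uses a fast transform, clamping round-off negatives to
    zero and rescaling so the output mass equals the product of input masses
    (sub-normalized inputs occur inside the induction).
    """
    if method == "direct":
        out = np.convolve(d1.probs, d2.probs)
    elif method == "fft":
        out = fftconvolve(d1.probs, d2.probs)
        neg = out < 0
        if np.any(neg):
            out[neg] = 0.0
        target = d1.probs.sum() * d2.probs.sum()
        s = out.sum()
        if s > 0 and target > 0:
            out *= target / s
    else:
        raise ValueError(f"unknown convolution method {method!r}")
    return CountDistribution(out)


def combine_all(
    ds: Sequence[CountDistribution] | Iterable[CountDistribution],
    method: str = "direct",
) -> CountDistribution:
    """Convolve a collection of distributions, always combining the two
    currently smallest; order-invariant up to floating round-off."""
    ds = list(ds)
    if not ds:
        raise ValueError("combine_all requires at least one distribution")
    heap = [(len(d), i, d) for i, d in enumerate(ds)]
    heapq.heapify(heap)
    tie = len(heap)
    while len(heap) > 1:
        _, _, a = heapq.heappop(heap)
        _, _, b = heapq.heappop(heap)
        c = convolve(a, b, method=method)
        heapq.heappush(heap, (len(c), tie, c))
        tie += 1
    return heap[0][2]
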