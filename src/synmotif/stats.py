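"""Exact over/under-representation statistics from a count distribution.

The overrepresentation p-value is the inclusive tail P(X >= observed) under
the exact null distribution; underrepresentation is its complement
1 - p_over, so the two tails overlap at the observed count by definition.
The z-score and count ratio (observed/mean) are comparison statistics
computed from the same exact distribution — the idealized versions of what
sampling-based methods estimate — and are reported alongside, not instead
of, the exact p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .distribution import CountDistribution
from .engine import CodingSequence, dataset_distribution
from .models import DcmModel, IcmModel
from .motif import Motif, count_occurrences


@dataclass(frozen=True)
class MotifResult:
    """Observed count and exact statistics for one motif on one dataset."""

    motif_label: str
    observed: int
    p_over: float
    p_under: float
    mean: float
    z: float | None            # None when the null variance is zero
    count_ratio: float | None  # None when the null mean is below threshold
    distribution: CountDistribution | None = None


def p_value_over(d: CountDistribution, observed: int) -> float:
    """P(X >= observed) under the null; 1 at observed=0, 0 beyond support."""
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    return min(1.0, d.tail_ge(observed))


def p_value_under(d: CountDistribution, observed: int) -> float:
    """1 minus the overrepresentation p-value."""
    return 1.0 - p_value_over(d, observed)


def z_score(d: CountDistribution, observed: int) -> float | None:
    """(observed - mean) / sd from the exact moments; None at zero variance."""
    var = d.variance()
    if var <= 0:
        return None
    return (observed - d.mean()) / math.sqrt(var)


def evaluate_motif(
    seqs: list[CodingSequence],
    motif: Motif,
    model: IcmModel | DcmModel,
    keep_distribution: bool = False,
    min_mean_for_ratio: float = 0.0,
    method: str = "direct",
) -> MotifResult:
    """Observed count plus the full exact-null statistics for one motif."""
    observed = sum(count_occurrences(s.nt, motif) for s in seqs)
    d = dataset_distribution(seqs, motif, model, method=method)
    mean = d.mean()
    ratio = observed / mean if mean > 0.0 and mean >= min_mean_for_ratio else None
    return MotifResult(
        motif_label=motif.label,
        observed=observed,
        p_over=p_value_over(d, observed),
        p_under=p_value_under(d, observed),
        mean=mean,
        z=z_score(d, observed),
        count_ratio=ratio,
        distribution=d if keep_distribution else None,
    )


def bonferroni_threshold(k: int, alpha: float = 1.0) -> float:
    """Significance threshold for an exhaustive k-mer scan: alpha / 4^k
    (e.g. 4^-6 ≈ 0.0002 for all 6-mers)."""
    return alpha / (4 ** k)
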