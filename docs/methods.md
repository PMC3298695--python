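# Methods

## Model and null space

Fix an amino-acid sequence A = A₁…A_N. The null sample space C_A is the
set of all nucleotide sequences α₁…α_N whose translation is A — every
synonymous re-encoding. A motif μ is a non-empty set of equal-length DNA
words over {A,C,G,T}; an occurrence of any member at any position, in any
reading frame and overlapping freely, is an occurrence of μ. The object of
interest is the exact distribution D(X) of the copy number X(α) over C_A,
weighted by a probabilistic model of codon choice, and the tail
probability P(X ≥ observed).

Two codon-choice nulls are estimated from a reference CDS set:

- **ICM.** p(α|A) = F(α)/Σ_{α'∈syn(A)} F(α'), with F(α) the reference
  count of codon α. Codons are independent given the protein.
- **DCM.** p(α|A,b) = F(α,b)/F(A,b), where F(α,b) counts reference
  occurrences of α immediately 5' of a codon starting with base b, and
  F(A,b) aggregates over the synonymous set. Sequences are generated
  3'→5', so the conditioning base is always already drawn. Because 17 of
  the 20 amino acids admit a single codon first base, conditioning on the
  3' neighbor's first base transfers the reference's codon-boundary
  dinucleotide structure into the null: on an idealized code in which
  *every* amino acid had a forced first base, the expected codon and
  dinucleotide counts of the generation process equal the reference
  counts exactly (the identity E[α] = Σ_b p(α|A,b)·F(A,b) = Σ_b F(α,b)
  = F(α), and its dinucleotide analogue; both are verified as tests on
  the code restricted away from Ser/Arg/Leu). On the real code the
  preservation is near-exact; the residual comes only from the first-base
  degeneracy of Ser, Arg and Leu.

Boundary conventions. A whole gene's 3'-most codon is conditioned on
b = T, the shared first base of all three stop codons; motifs are never
counted overlapping the stop (it is detached at ingestion). A fragment
with no known 3' context uses the ICM marginal for its 3'-most codon —
the whole-gene rule has no analogue for fragments, and marginalization
adds no assumption. Cells (A,b) never observed in the
reference fall back to the ICM conditional, and entirely unobserved amino
acids to the uniform distribution over their codons, so every synonymous
sequence keeps positive support and exact p-values remain well defined;
an additive pseudocount is available as an alternative regularization
(default 0).

## The dynamic program

Δ = ⌈(l+2)/3⌉ is the maximum number of codons an l-mer occurrence can
overlap (an occurrence starting at the third base of a codon reaches
furthest). Note ⌊(l−1)/3⌋+1 — the span formula one might write first —
agrees for l not divisible by 3 but undercounts for l divisible by 3: a
6-mer can overlap three codons. The DP state must cover the true maximum,
so Δ = ⌈(l+2)/3⌉ is used throughout.

The induction walks the sequence one codon at a time keeping, for every
codon assignment of the last Δ−1 codons processed, the sub-normalized
distribution of counts accumulated so far (at most 6^(Δ−1) contexts, and
only those compatible with the amino acids). Appending a codon forms a
window of up to Δ codons; the number of occurrences *beginning* in the
appended codon and lying inside the window is added to the count (each
occurrence begins in exactly one codon, so none is counted twice — the
mirror of counting occurrences that *end* in the newest codon when
walking 5'→3'), and the state weight is multiplied by the model
probability of the appended codon. The walk runs 3'→5'; under the DCM the
conditioning base of the appended codon is the first base of the
previously appended codon, already in the context, so every probability
factor is applied exactly once and finalization is a plain sum over
contexts. The final mass must be 1; a drift beyond 1e-6 raises, and the
test suite asserts 1e-9.

Distributions are dense double-precision arrays indexed 0..max_count,
with max_count the number of *feasible occurrence start positions* of the
region — a much tighter bound than the region length. All probability
arithmetic is linear-space; at desk scale (≤ a few hundred kb of query)
neither underflow nor cancellation is a concern. p-values smaller than
~1e-300 would underflow; that is a documented limitation, not a target
regime.

## Sparse regions

For most motifs, most of a protein admits no occurrence under any codon
choice: at most 216 codon combinations × 4 offsets = 864 six-mers are
realizable over any amino-acid triple (the census over all 20³ triples
gives an even smaller 192), so ≥ 79% of 6-mers are forbidden in any given
triple. Feasible placements are found per start position (each touched
codon is independently checked against its synonymous set), projected to
codon intervals, and overlapping intervals merged into regions; codons no
occurrence can touch are skipped entirely. Counts in disjoint regions add,
so the sequence distribution is the convolution of region distributions;
multi-sequence datasets convolve per-sequence distributions (occurrences
never span sequence boundaries).

Under the DCM, regions are independent only if the Markov chain is cut
between them: a gap containing at least one amino acid with a forced
first base makes the 5' region's codons conditionally deterministic with
respect to the 3' region. Splits whose gap lacks such a residue
(gaps consisting solely of Ser/Arg/Leu, including empty gaps) are merged
before the DP, so the per-region convolution is exact rather than
approximate. A region's own 3' boundary base is resolved by scanning 3'
to the nearest forced-first-base residue (or the sequence boundary) and
chaining the conditional tables back to the region edge, yielding an
exact marginal base distribution that is mixed into the first DP step.
The identity of split and no-split results to 1e-9 is asserted over random
instances, as is elementwise equality of the whole DP with brute-force
enumeration — the definitional oracle and the suite's central property.

Convolution is direct polynomial multiplication by default; with many
short regions the products are tiny and an FFT buys nothing while
occasionally producing slightly negative coefficients from round-off. The
FFT path is available as an opt-in (`method="fft"`), with negatives
clamped to zero and mass rescaled. `combine_all` always merges the two
currently smallest distributions, the schedule that keeps intermediate
supports short; the result is order-invariant to 1e-9 by property test.

## Statistics

p_over(k) = P(X ≥ k) is the inclusive exact tail; p_under = 1 − p_over by
definition, so the two tails overlap at the observed count (no mid-p
correction by default). The z-score uses the exact mean and variance of
D(X) — the ideal of what a sampling method estimates — and is flagged
undefined (None) at zero variance rather than raised. The count ratio
observed/mean is suppressed when the mean is 0 or below a user threshold
(`min_mean_for_ratio`, default 0), since tiny means make the ratio an
outlier-driven statistic. Raw p-values are reported; for exhaustive k-mer
scans the CLI notes the Bonferroni threshold 4⁻ᵏ but never adjusts
silently.

## Synthetic data and what the tests show

No external data ship with the package; the test bed is generated:

- **Reference corpora** are drawn from a first-order nucleotide Markov
  chain with the CG transition down-weighted (default factor 0.25, a
  strength chosen to give a clearly CpG-depleted corpus of the kind
  vertebrate CDS presents), emitted codon-wise with stop codons redrawn in
  place, stop-terminated. This gives the fitted DCM a real dinucleotide
  signal to preserve; it does not emulate amino-acid composition, codon
  autocorrelation beyond first order, or selection.
- **Synthetic proteins** for oracle tests and the power study are i.i.d.
  uniform over the 20 amino acids. Real proteomes are far from uniform;
  the choice is a neutral stand-in that exercises every synonymous set,
  and all correctness properties asserted are composition-free.
- **The insertion power study** follows the published design at its
  published scale — 20 sequences × 350 codons, a 6-mer overwritten into
  0..15 of the sequences, redrawn if it would create a premature stop —
  but with the null trained on the synthetic corpus rather than human
  CDS, and a 64-motif subsample of the 4096 6-mers (16 in the test
  suite). The monotone fall of the median exact p-value and its crossing
  of the 4⁻⁶ threshold are therefore qualitative reproductions; the
  absolute crossing point (≈10 insertions here) depends on the null's
  training corpus and is expected to differ from runs on real data.

Passing tests show the algorithm computes exactly the distribution it
defines, on any model of this family; they cannot show that ICM/DCM nulls
are adequate for a particular genome — that is a modeling judgment the
original analyses argue from real data.

## Numerical and design choices

- Brute-force enumeration guards at 10⁶ sequences; oracle tests cap the
  synonymous-space size (≤ 3000) to stay fast rather than shrinking
  tolerances.
- Normalization tolerances: 1e-12 for probability tables, 1e-9 for
  finalized distributions (accumulated float error over long inductions),
  asserted rather than silently renormalized.
- Sampling uses `numpy.random.Generator` exclusively, seeded explicitly
  everywhere; no global RNG state.
- Regions are processed in sequence order and combined smallest-first;
  results are order-invariant within tolerance.
- Mixed-length k-mer sets are rejected at the `Motif` level (Δ and the
  per-window end-count are length-derived); the CLI evaluates each length
  as its own motif row.
- Only the standard genetic code is supported; alternative codes would
  change the first-base structure on which the DCM's region cutting and
  preservation argument rest.

## Known limitations

Exact p-values are conditional on the amino-acid sequence and the fitted
null; they inherit any misfit of that null. Linear-space probabilities
bound usable dataset sizes well below genome scale in a single
distribution (supports of ~10⁵ counts are fine; 10⁸ are not). Motifs
spanning exon–exon junctions, PWM/IUPAC motifs, and higher-order (≥ 2
codon) Markov nulls are out of scope by design.
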