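"""Exact count distribution for a toy case, against full enumeration.

The two-lysine protein "KK" has four synonymous re-encodings.  Under the
uniform codon model, counting occurrences of AAA in each shows the exact
distribution the dynamic program must reproduce: AAAAAA holds 4 overlapping
copies, AAAAAG holds 3, AAGAAA holds 1, AAGAAG none — so the counts 0,1,3,4
each carry probability 1/4 and a count of 2 is structurally impossible.
"""

import synmotif as sm

uniform = sm.build_icm(sm.count_reference(["ATGTAA"]))  # only Met observed
motif = sm.parse_motif_spec("AAA")

dp = sm.sequence_distribution(
    sm.CodingSequence(id="toy", nt="AAAAAA"), motif, uniform
)
bf = sm.brute_force_distribution("KK", motif, uniform)

print("count  P(dynamic program)  P(enumeration)")
for k in range(len(dp)):
    print(f"{k:5d}  {dp.probs[k]:18.4f}  {bf.probs[k]:14.4f}")
print()
print("The observed sequence AAAAAA carries 4 copies; its exact")
print("overrepresentation p-value is P(X >= 4) =",
      sm.p_value_over(dp, 4))
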