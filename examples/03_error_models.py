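"""The three analytic models: error multiplicity, direction skew, culling counts.

All three are exact binomial computations; nothing here needs sequencing data.
"""

from cdr3err import binom_boundaries, cull_threshold, expected_multi_error_rate

# 1. Independence expectation for multi-substitution sequences: with a
#    per-position single error rate SER over an N-nt CDR3, the chance of a
#    sequence carrying M independent errors is C(N,M) * SER^M. Observed
#    frequencies above this indicate correlated ("complementing") errors.
ser, n = 1e-3, 36
print("M  expected frequency (SER=1e-3, N=36)")
for m in (2, 3, 4):
    print(f"{m}  {expected_multi_error_rate(ser, m, n):.3e}")
print("e.g. M=2: C(36,2)=630 combinations x (1e-3)^2 = 6.30e-04\n")

# 2. Exact binomial boundaries on the forward-read count. A clonotype read n
#    times with forward probability p should have its forward count inside
#    [lower, upper] except with <1% probability per tail; clonotypes far
#    outside are direction-skewed, a hallmark of erroneous sequences.
for reads in (20, 100, 1000):
    lower, upper = binom_boundaries(reads, p_fwd=0.5, tail=0.01)
    print(f"n={reads:>4}, p_fwd=0.5 -> 98% boundaries on forward count: [{lower}, {upper}]")
print()

# 3. Culling-count thresholds. The naive rule culls a 1-mismatch neighbor if
#    its count is at most cutoff x index count; at low counts this under-culls.
naive = cull_threshold(200, 0.005, mode="naive")
adjusted = cull_threshold(200, 0.005, confidence=0.95, mode="binomial")
print(f"index 200 reads, cutoff 0.5%: naive threshold = {naive:.0f} read")
print(f"binomially adjusted threshold (95% confidence) = {adjusted} reads")
print("-> an error sequence truly at 0.5% of the index can appear 2-3 times by"
      " chance;\n   culling counts <= 3 is needed to purge it with 95% confidence")
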