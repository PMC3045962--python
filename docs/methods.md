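# Methods

`cdr3err` analyses sequencing errors in single-end amplicon reads of the
T-cell receptor β-chain CDR3. The core idea is the monoclonal audit: in a
sample that expresses exactly one known receptor, every accepted read whose
CDR3 deviates from the true sequence is, by construction, a processing or
sequencing error, so error frequency, type, position, lane dependence and
read-direction dependence can all be measured directly. The package couples
that audit to a synthetic read generator so every stage is exercisable and
testable without sequencing data.

## Read validation and CDR3 extraction

An accepted read must satisfy, in this order (the first failing criterion is
the recorded rejection reason, so rejection counts are reproducible):

1. **Flank identity.** The V-side and J-side mapping segments (defaults: the
   27 nt of flank adjacent to the CDR3 on each side; V segments of 25–30 nt
   are typical) must occur exactly — 100% identity — in the read, V before J.
   The forward strand is searched first, then the reverse complement; the
   leftmost V match and the leftmost J match after it are used. An `N`
   anywhere in a flank can never exact-match, so the identity criterion
   subsumes the no-N rule there.
2. **Frame.** The spanned CDR3 must have length divisible by 3.
3. **No `N`** inside the span.
4. **No stop codon** in the translated span.
5. **Conserved residues.** The codon immediately 5′ of the span must encode
   C, and the four codons from the J match onward must encode FGXG, FAXG or
   HGXG. With flank segments that end in the C codon / start at the F codon
   (the default construction) this is guaranteed by the exact flank match;
   it is still re-checked on the oriented read so arbitrary flank choices
   honour the criterion.

The returned CDR3 excludes the C and F codons. Reverse-orientation reads are
reverse-complemented (qualities reversed) before extraction, so all
downstream coordinates are in reference orientation. Phred filtering is a
minimum over the CDR3 window only: a record passes cutoff q iff every CDR3
base quality is ≥ q; q = 0 passes everything, and pass sets are nested in q.
Qualities are decoded as Phred+33 by default with a `phred_offset` switch
for Phred+64 data.

## The synthetic amplicon generator

`simulate_reads` draws, per read: a template (by clone abundance), a lane
and sample path (uniformly, or balanced over the 27 reactions of the 3×3×3
trifurcating study design), an orientation (forward with probability
`p_forward`, default 0.5), and then errors.

**Substitutions.** The error process is a per-read probability matrix over
(position, alternative nucleotide). Each position errs independently with
its total cell probability; the destination base is chosen in proportion to
the cell rates. Effective rates are the base matrix times an optional
per-lane multiplier and, on reverse reads, a direction-bias multiplier —
all three may be scalars or full (L, 4) matrices. An optional *burst* regime
multiplies all rates by `burst_boost` on a `burst_fraction` of reads; this
induces correlated (complementing) multi-errors while the default process
keeps errors independent across positions, so both regimes of the
multiplicity analysis are exercisable.

**Default rates.** The default model draws cell rates log-uniformly on
[1e-5, 1.2e-3] (a ~100–200-fold spread between the least and most
error-prone cells, matching the tens-to-hundreds-fold spread seen in real
monoclonal audits) and boosts the transition cell at every position
(C→T, G→A, A→G, T→C) 8-fold, capped at 1.5e-3. Over a 36-nt CDR3 this
yields a raw (q = 0) error rate of ~6% of accepted sequences, the scale
reported for real Illumina CDR3 data, falling to below 1% at q = 30.
Per-cell lane multipliers are log-uniform on [0.5, 2] and per-cell
direction-bias multipliers log-uniform on [0.2, 5], giving lane effects
detectable by ANOVA and the strong orientation skew of erroneous clonotypes.

**Qualities.** Correct bases draw Phred scores with 99% mass on 30–40 and
1% on 20–29; error bases draw 90% on 2–25 and 10% on 30–40. The 0.99
per-base high-quality mass makes a q = 30 filter retain ≈ 0.99³⁶ ≈ 70% of
correct reads, and the 10% high-quality error mass leaves a small residual
error rate after filtering — quality filtering diminishes but does not
eliminate errors, which is the behaviour real data shows. (A stricter
per-base split — e.g. 94% high mass for correct bases and none for error
bases — would reject ~89% of correct reads and 100% of errors at q = 30,
which is not a useful emulation.)

**Indels.** Deletions/elongations are single whole-codon (3-nt) events
inside the CDR3, at per-read rates 2e-5 / 5e-6. In-frame events are the
only length errors that can survive the frame criterion, so these are what
the truncated/elongated length classes downstream consist of; a 1-nt indel
is always rejected as out-of-frame. Defaults keep non-correct-length errors
well under 1% of the error population.

**Templates.** Built-in synthetic templates carry a 30-nt V flank ending in
a cysteine codon, a 30- or 36-nt CDR3, a 27-nt J flank starting with an
FGAG motif, and pads to a 125-bp read. CDR3s (including the random
clonotypes of the polyclonal generator) are assembled from *stop-robust*
codons — codons no single substitution of which creates a stop — so every
injected substitution remains observable after validation rather than being
silently rejected. Polyclonal repertoires default to 300 distinct clones
with Zipf (rank⁻¹) abundances sharing one V/J context.

**Determinism.** All randomness flows from one integer seed through one
`numpy` generator, and strata are processed in sorted order, so a given
(config, seed) reproduces FASTQ output and truth tables byte for byte.

**What the generator does not emulate:** cluster-formation chemistry,
PCR-cycle error genealogy, barcode demultiplexing or adapter chimeras,
quality-score autocorrelation along the read, and any coupling between
errors and local sequence context beyond the per-cell rates. Passing tests
therefore demonstrate that the analysis recovers the statistical structure
it is pointed at — not that real instrument data has exactly this structure.

## Error profiling

Each accepted CDR3 is classified against the reference: equal length with
zero mismatches (*correct*), equal length with M ≥ 1 mismatches
(*substitution*, with the exact (position, from, to) list), shorter
(*truncated*) or longer (*elongated*). Summaries per Phred cutoff report
the error percentage, unique erroneous sequences (pooled and per sample),
length-class composition, and the multiplicity spectrum.

The substitution matrix counts, per stratum (lane, direction and/or
sample), reads carrying each (position, to-base) substitution; the
denominator is the total accepted reads in the stratum, so a cell rate is
"fraction of sequences with this particular substitution" and multi-error
reads contribute to several cells. Positions are 0-based in the CDR3 window
throughout (figure-style labels such as "17A→C" in the repertoire
literature are 1-based). Per-origin-base rates average cells over positions
sharing a reference base, separately per read direction; origin bases
absent from the reference are flagged undefined. The four dominant
substitutions under the default model — C→T, G→A, A→G, T→C — are
*transitions* under standard nomenclature (parts of the repertoire
literature have mislabelled them purine–pyrimidine transversions); outputs
use the standard labels.

Lane effects are quantified two ways. The composite CV is the mean ± sd of
per-cell coefficients of variation (sample sd / mean) of per-sample rates
computed within each lane, contrasted with the same computed ignoring lanes;
cells with zero mean rate have undefined CV and are excluded (their number
is reported). Per-cell one-way fixed-effects ANOVA groups per-sample rates
by lane on raw rates (no transform — cell rates are small and roughly
homoscedastic at these scales, and a transform would change the reported
quantity); cells with no variance anywhere get p = 1 by convention, and the
headline number is the raw fraction of cells with p < 0.05 (deliberately no
multiplicity correction: under the null ≈ 5% of cells are significant, so
the fraction is read against that baseline).

## Analytic models

**Error multiplicity.** Under independent errors at per-position single
error rate SER, the expected fraction of sequences with exactly M
substitutions over an N-nt CDR3 is p = C(N, M)·SERᴹ with
C = N!/(M!(N−M)!), computed in log space. SER is estimated from data as
(fraction of sequences with exactly one substitution)/N — the per-position
reading, which is what makes C·SERᴹ dimensionally consistent with
per-sequence frequencies. The survival-factor variant
C·SERᴹ·(1−SER)^(N−M) is also implemented (`include_survival=True`); the
plain form is the default and the two agree to <1% for SER ≲ 1e-4 at
CDR3-scale N. Observed/expected ratios ≈ 1 indicate independent error
formation; ratios > 1 indicate complementation. p > 1 is flagged as model
breakdown.

**Direction boundaries.** For a clonotype read n times with forward-read
probability p, the screen computes the exact binomial interval
[lower, upper]: upper is the smallest k with P(X > k) < 0.01 and lower the
largest k with P(X < k) < 0.01 — per-tail mass strictly below 1%, ties
broken toward wider intervals, no normal approximation (the implementation
uses the exact regularized-incomplete-beta CDF and is tested against
rational-arithmetic pmf summation). Direction-neutral clonotypes fall
inside ≥ 98% of the time; erroneous clonotypes under a direction-biased
error process mostly fall outside. Only clonotypes with ≥ 20 reads are
assessed, and p defaults to the forward fraction of the most abundant
(presumed correct) clonotype.

**Culling thresholds.** The naive rule culls a distance-1 neighbor when its
count is at most cutoff × index count. At small indexes this under-culls:
an error sequence whose true frequency is exactly the cutoff can easily be
observed 2–3 times. The adjusted threshold is the smallest integer k whose
Binomial(index count, cutoff) CDF reaches the target confidence (default
0.95) — e.g. index 200, cutoff 0.5%: naive 1, adjusted 3.

## Mismatch culling

Clone tables group accepted CDR3s by exact sequence with forward/reverse
and per-lane counts. Hamming-1 neighbors are found with position-wildcard
indexing (identical results to the all-pairs scan, which is the test
oracle); only equal-length sequences can be neighbors, and "lower
frequency" is strict, so equal-count pairs are mutually non-neighbors and
the relation stays antisymmetric.

Monoclonal culling removes distance-1 neighbors of the true sequence with
count **at or below** cutoff × index count (inclusive ≤ — forced by the
cutoff-1 convention "removes everything at or below the index frequency";
cutoff 0 removes nothing since counts are ≥ 1). Polyclonal tallies use
strict **<** against the cutoff ("present at less than the indicated
frequency"). The asymmetry is deliberate and follows the two rules'
standard statements. Polyclonal indexes are the top-20 clonotypes (ties
broken lexicographically — a repo convention, since no standard tie-break
exists); indexes are processed in descending count order and a sequence
attributed to one index is not re-counted for another. The global tally
(no cutoff) counts, summed over all clonotypes, their lower-count
distance-1 neighbors.

## Diversity

ACE follows the classic bias-corrected Chao & Lee form with rare/abundant
cutoff 10 (the EstimateS "n = 10" convention; configurable):

    C_ace  = 1 − F1/N_rare
    γ²     = max[(S_rare/C_ace) · Σ i(i−1)F_i / (N_rare(N_rare−1)) − 1, 0]
    ACE    = S_abund + S_rare/C_ace + (F1/C_ace)·γ²

With no rare clonotypes ACE = S_obs; when all rare clonotypes are
singletons C_ace = 0 and the estimator falls back to bias-corrected Chao1
with F2 = 0 (S_obs + F1(F1−1)/2), flagged in the result. The
implementation is cross-checked against `vegan::estimateR` in the test
suite. Point estimates only — no variance or rarefaction.

## Problem sizes and numerical choices

The test and example runs use 10⁴–2×10⁵ simulated reads per scenario and
polyclonal mixes of 300 clones — sizes at which every injected effect
(per-cell rates ≥ 1e-3, 5× lane multipliers, burst complementation,
transition dominance) is detectable within 3 binomial standard errors while
a full run of the suite stays in the minutes range. Parameter-recovery
checks compare estimated cell rates to injected ones at 3 binomial SE per
cell for cells with rate ≥ 1e-3 at 10⁵ reads. Binomial computations use
the exact CDF (no continuity corrections); boundary and threshold searches
scan integer k with strict-inequality tie handling as defined above.

## Known limitations

* Exact-substring flank matching cannot distinguish "V segment present with
  one mismatch" from "V segment absent"; both reject (`no_flank_match`),
  and the `v_mismatch` rejection label is reserved but never emitted.
* Free-offset flank search: the mapping segment may start at any read
  offset. Primer-anchored designs could exploit fixed offsets to reject
  chimeras earlier.
* No mismatch-tolerant or paired-end matching; no Hamming-2/3 clustering of
  clonotypes (single-mismatch culling only).
* Truncated/elongated sequences are length-classified only; no attempt is
  made to localize the indel.
* The simulator's parameter distributions are stand-ins chosen for
  qualitative fidelity, not values fitted to any instrument.
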