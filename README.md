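# cdr3err

Sequencing-error profiling and filtering for T-cell receptor CDR3β amplicon
repertoire data.

High-throughput repertoire sequencing reads the hypervariable CDR3 junction
of millions of T-cell receptors, but 1–6% of accepted reads can carry
errors — and because the CDR3 is generated by somatic recombination, an
erroneous read is not distinguishable from a genuine rare clonotype by
sequence alone. In a **monoclonal** sample (a transgenic, recombination-
deficient background expressing a single known receptor) every deviant read
*is* an error, which turns such samples into calibration standards: error
frequency, substitution spectrum, positional and lane dependence, and
read-direction skew can all be measured exactly.

`cdr3err` implements that audit as a reusable library for immunologists and
bioinformaticians working with bulk TCR amplicon data:

* a **synthetic amplicon simulator** with ground truth — position- and
  substitution-specific error rates, transition enrichment, lane effects,
  read-orientation bias, quality-correlated errors, rare in-frame indels,
  and the 3×3×3 trifurcating study design (27 reactions);
* **read validation / CDR3 extraction** — exact V/J flank identity in either
  orientation, frame, no-N, no-stop and conserved C…FGXG checks, with
  min-Phred filtering over the CDR3 window;
* **error profiling** — per-cutoff error summaries, position × substitution
  rate matrices stratified by lane/direction/sample, per-origin-base rates,
  composite CVs and per-cell lane ANOVA;
* **exact analytic models** — the independence expectation
  `p = C(N,M)·SER^M` for multi-substitution reads, exact-binomial
  direction-skew boundaries (per-tail < 1%), and binomially adjusted
  culling-count thresholds for low-count index sequences;
* **single-nt-mismatch culling** of clonotype tables (monoclonal residual
  error; polyclonal top-20-index neighbor tallies) and **ACE** clonotype
  richness with rare-abundance cutoff 10.

## Worked example

Simulate a monoclonal control under the default error process, extract and
profile it (this is `examples/02_extract_and_profile.py`):

```python
from cdr3err import FlankSpec, extract_all, simulate_reads, summarize
from cdr3err.simulate import default_error_model, example_template, preset_study_design

template = example_template(36)                      # 125-bp amplicon, 36-nt CDR3
model = default_error_model(template, seed=0)
reads, truth = simulate_reads(template, model, 27_000, seed=0,
                              design=preset_study_design(0))
records, rejections = extract_all(reads, FlankSpec.from_template(template))
summaries = summarize(records, template.cdr3, q_cutoffs=(0, 10, 20, 30))
print("q_cutoff  n_seqs  error%  unique_errors  %errors_excluded_vs_q0")
for q, s in summaries.items():
    excl = f"{s.pct_error_excluded:.1f}" if s.pct_error_excluded is not None else "-"
    print(f"{q:>8}  {s.n_total:>6}  {s.error_percent:>6.2f}  {s.n_unique_error:>13}  {excl:>10}")
```

prints

```
q_cutoff  n_seqs  error%  unique_errors  %errors_excluded_vs_q0
       0   24431    6.63            147         0.0
      10   23940    4.72            114        30.3
      20   23362    2.36             81        66.0
      30   15944    0.78             59        92.3
```

Reading: of 27,000 simulated reads, 24,431 pass the validity criteria; 6.6%
of them carry an erroneous CDR3. Because error bases are enriched at low
Phred scores, raising the minimum-quality cutoff removes errors much faster
than it removes correct reads — at q = 30 the error rate drops to 0.78% and
92% of erroneous reads (and most of the unique erroneous sequences) are
gone, at the cost of ~35% of total reads. The `examples/` directory has one
short script per capability: simulation with ground truth, extraction and
profiling, the analytic models, mismatch culling with direction-skew
screening, and polyclonal diversity (where quality filtering shrinks the
error-inflated ACE richness estimate toward the true clone count).

The culling-threshold model in one line:

```python
>>> from cdr3err import cull_threshold
>>> cull_threshold(200, 0.005, mode="naive")
1.0
>>> cull_threshold(200, 0.005, confidence=0.95, mode="binomial")
3
```

i.e. with a 200-read index clonotype and a 0.5% relative cutoff, the naive
rule culls only single-mismatch clonotypes seen once, but an error sequence
whose true frequency is 0.5% of the index can appear 2–3 times by chance —
culling counts up to 3 is required to purge it with 95% confidence.

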