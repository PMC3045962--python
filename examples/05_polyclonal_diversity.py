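"""Polyclonal repertoire: neighbor tallies and ACE diversity before/after filtering.

Simulates a 300-clone power-law repertoire with the default error process,
then shows how quality filtering shrinks the population of presumed-erroneous
low-frequency single-mismatch clonotypes and the ACE richness estimate
(error inflation masquerades as diversity).
"""

from cdr3err import (
    FlankSpec,
    build_clone_table,
    cull_polyclonal,
    extract_all,
    phred_filter,
    richness_report,
    simulate_reads,
)
from cdr3err.simulate import default_error_model, random_polyclonal_templates, zipf_abundances

templates = random_polyclonal_templates(300, seed=2)
model = default_error_model(templates[0], seed=2, n_lanes=1)
reads, _ = simulate_reads(
    templates, model, 60_000, n_lanes=1, seed=2, abundances=zipf_abundances(300)
)
records, _ = extract_all(reads, FlankSpec.from_template(templates[0]))
table_q0 = build_clone_table(records)
table_q30 = build_clone_table(phred_filter(records, 30)[0])

print("single-mismatch neighbor tallies for the 20 most frequent clonotypes:")
print("cutoff   q=0   q=30")
rep0 = cull_polyclonal(table_q0)
rep30 = cull_polyclonal(table_q30)
for cutoff in rep0.per_cutoff_totals:
    print(f"{cutoff:>6}  {rep0.per_cutoff_totals[cutoff]:>4}  {rep30.per_cutoff_totals[cutoff]:>5}")
print(f"global lower-frequency neighbor tally: q=0 {rep0.global_tally}, "
      f"q=30 {rep30.global_tally}\n")

report = richness_report(table_q0, table_q30)
print(f"q=0 : {report['q0']['total_reads']} reads, "
      f"{report['q0']['unique_clonotypes']} unique clonotypes, ACE = {report['q0']['ace']:.0f}")
print(f"q=30: {report['q30']['total_reads']} reads, "
      f"{report['q30']['unique_clonotypes']} unique clonotypes, ACE = {report['q30']['ace']:.0f}")
print(f"ACE reduction from filtering: {report['reduction_percent']['ace']:.1f}% "
      "(300 clones were actually present)")
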