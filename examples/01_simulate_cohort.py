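"""Simulate a synthetic patient cohort with ground truth.

Generates serial whole-blood and cfDNA variant tables for 20 patients with CH
clones, tumor-shed variants and germline variants, and prints the cohort
composition.  Every emitted variant row carries a matching ground-truth
record, which is what makes the downstream recovery checks possible.
"""

from chdyn.synthetic import SimulationConfig, simulate_cohort

cohort = simulate_cohort(SimulationConfig(n_patients=20, seed=42))

print(f"patients:            {len(cohort.patients)}")
print(f"called variant rows: {len(cohort.variants)}  (WB + cfDNA x 3 timepoints)")
print("truth categories:   ", cohort.truth["true_category"].value_counts().to_dict())
print("origin labels:      ", cohort.truth["true_origin"].value_counts().to_dict())
# Each count above is a distinct variant; 'somatic' splits into hematopoietic
# CH clones (seen in WB and cfDNA) and non-hematopoietic tumor-shed variants
# (cfDNA only, true WB VAF = 0).
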