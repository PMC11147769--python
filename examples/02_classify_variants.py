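"""Run the variant retention + classification cascade.

Classifies every call of a simulated cohort into filtered / somatic /
germline / SNP-excluded, then calls patient-level CH status (somatic CH-gene
mutation with VAF >= 1%) and compares it with the simulated truth.
"""

from chdyn.filtering import call_ch_status, classify_calls
from chdyn.genes import default_ch_genes
from chdyn.synthetic import SimulationConfig, simulate_cohort

cohort = simulate_cohort(SimulationConfig(n_patients=20, seed=42))
classified = classify_calls(cohort.variants)

print("categories:", classified["category"].value_counts().to_dict())

ch_genes = default_ch_genes()
baseline = classified[
    (classified["source"] == "WB") & (classified["timepoint_years"] == 0.0)
]
n_pos = 0
for pid, grp in baseline.groupby("patient_id"):
    if call_ch_status(grp, ch_genes).positive:
        n_pos += 1
truth_pos = int(cohort.patients["ch_truth"].sum())
print(f"CH-positive patients: called {n_pos}, simulated {truth_pos}")
# Category counts are per observation (variant x source x timepoint); a
# germline variant therefore appears 6 times.  CH status uses the baseline
# WB sample only, mirroring how prevalence is reported.
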