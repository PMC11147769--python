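"""Cohort statistics: baseline tests and mutation co-occurrence.

Reproduces Fisher tests on published baseline contingency tables (counts of
CH-negative vs CH-positive patients per level) and runs the gene
co-occurrence analysis with BH-FDR on a simulated cohort.
"""

from chdyn.filtering import classify_calls
from chdyn.stats import cooccurrence_matrix, fisher_exact
from chdyn.synthetic import SimulationConfig, simulate_cohort

tables = {
    "number of previous lines (1 vs >1)": [[38, 24], [12, 29]],
    "prior PARPi treatment": [[46, 29], [4, 24]],
    "history of cancer": [[48, 45], [2, 8]],
    "ECOG performance status": [[44, 39], [6, 14]],
    "treatment arm (A/B/C)": [[16, 18], [17, 18], [17, 17]],
}
for name, tab in tables.items():
    res = fisher_exact(tab)
    orr = f", OR = {res.odds_ratio:.1f}" if res.odds_ratio is not None else ""
    print(f"{name:38s} p = {res.p_value:.3g}{orr}")
# Heavier pretreatment (more lines, prior PARPi) associates with CH; the
# randomized arm assignment does not (p = 1), as it must.

cohort = simulate_cohort(SimulationConfig(n_patients=80, seed=42))
classified = classify_calls(cohort.variants)
somatic = classified[
    (classified["category"] == "somatic")
    & (classified["source"] == "WB")
    & (classified["timepoint_years"] == 0.0)
]
cooc = cooccurrence_matrix(somatic)
top = cooc[cooc["gene_1"] < cooc["gene_2"]].nsmallest(3, "p_fdr")
print(top[["gene_1", "gene_2", "n_cooccur", "odds_ratio", "p_raw", "p_fdr"]]
      .to_string(index=False))
# Each row tests whether two genes are mutated in the same patients more
# often than chance, across patients with >= 2 mutations.
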