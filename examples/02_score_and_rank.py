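"""Score genes with the integrative cumulative score and rank them.

Merges CSQ-embedded SIFT/PolyPhen scores with the external FATHMM-XF and
CADD tables, normalizes each against its deleterious cutoff, and aggregates
per gene: each deleterious SNV contributes its (averaged) normalized score
weighted by how many more tumor than normal patients carry it, summed per
transcript with a 1/ln(length) penalty and averaged over the gene's
transcripts.
"""

from pathlib import Path

from iqgene import SimulationConfig, load_cohort, score_cohort, simulate_cohort
from iqgene.scoring import top_percent

out = Path("scratch_example_cohort")
cohort = simulate_cohort(SimulationConfig(n_patients=20, n_genes=80,
                                          n_driver_genes=2, seed=7), out)
data = load_cohort(cohort.manifest_path)
scored = score_cohort(data, cohort.variant_scores_path,
                      cohort.transcript_scores_path,
                      modes=("integrative", "cadd"))

ranking = scored.rankings["integrative"]
print(f"{ranking.p} pathogenic genes (>= 1 deleterious SNV); top 5 by iQ(G):")
print(ranking.to_frame().head(5).to_string(index=False))
print("planted drivers:", ", ".join(cohort.truth.driver_genes))
print("top 1% gene list:", top_percent(ranking, 0.01))
# The planted high-burden driver genes should head the table: their many
# high-scoring, multi-patient, tumor-only variants dominate the cumulative sum.
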