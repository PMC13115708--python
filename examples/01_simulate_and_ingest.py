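"""Generate a synthetic tumor/normal cohort and ingest it.

Writes per-patient somatic VCFs with VEP-style CSQ annotation plus external
analyzer score tables, then parses them back into the unique-SNV frequency
table and the cohort summary.
"""

from pathlib import Path

from iqgene import SimulationConfig, load_cohort, simulate_cohort

out = Path("scratch_example_cohort")
cohort = simulate_cohort(SimulationConfig(n_patients=20, n_genes=80,
                                          n_driver_genes=2, seed=7), out)
print(f"wrote cohort under {out}/ with planted drivers: "
      f"{', '.join(cohort.truth.driver_genes)}")

data = load_cohort(cohort.manifest_path)
summary = data.summary()
print(f"{summary.n_vcf_files} VCF files, {summary.n_patients} patients")
print(f"{summary.n_unique_snvs_all} unique SNVs "
      f"({summary.n_unique_snvs_filtered} nonsynonymous on protein-coding transcripts)")
print("category counts:", summary.category_counts_all)
print("tumor-sample nucleotide-change matrix (rows = ref base, cols = alt base):")
print(summary.change_type_tumor)
# Most variants are tumor-only: in somatic call sets the tumor sample carries
# the overwhelming majority of SNVs, with a small shared ("common") fraction.
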