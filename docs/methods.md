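# Methods

## Model and procedure

The pipeline treats a somatic cohort as a set of patients, each with a
paired tumor/normal VCF (or several). Analysis proceeds in four stages.

**1. Ingestion.** Each VCF's per-transcript consequence annotation is read
from its own `##INFO=<ID=CSQ,...>` metadata, so differently configured VEP
exports parse without code changes. A sample carries an SNV iff its
genotype includes the alternate allele; unknown genotypes (`./.`) count as
not carrying. Multi-allelic lines split into one SNV per alternate allele;
indels and multi-base alleles are skipped (and counted). Per unique SNV the
pipeline counts distinct carrying patients per sample class: the same SNV
in two files of one patient counts once, in two patients twice. Records are
then filtered to protein-coding transcripts whose consequence includes a
configurable nonsynonymous whitelist (default: `missense_variant`,
`stop_gained`, `stop_lost`, `start_lost`; nonsense is included because
premature stops are the one loss-of-function class present in SNV-only
somatic call sets).

**2. Score integration.** SIFT and PolyPhen come from the CSQ cells
(qualified forms like `tolerated(0.32)` are parsed); FATHMM-XF joins per
variant, CADD per (variant, transcript), both chr-prefix-agnostically.
Directionality is harmonized (SIFT complemented), the published cutoffs
classify deleteriousness in each analyzer's native direction, and scores
are min–max normalized between the harmonized cutoff and range maximum.
AveScore(v) is the mean of the available normalized scores; the variant is
deleterious in the integrative mode iff any analyzer flags it.

**3. Gene scoring.** Per transcript, deleterious variants contribute
normalized score × (tumor − normal patient counts), damped by 1/ln(length);
the gene score averages transcripts (transcripts without deleterious
variants contribute 0 but count in N_G). Pathogenic genes are ranked
1..p descending, competition style.

**4. Evaluation.** SAR = (mean rank − 1)/p for a gene list, with rank
p + 1 for unranked genes; calibrated against random same-size gene sets
sampled without replacement from a protein-coding background, with a
one-sided z-test.

## Parameters that matter

| parameter | default | rationale |
|---|---|---|
| analyzer ranges/cutoffs | FATHMM-XF 0–1/≥0.5; CADD 0–99/≥10; SIFT 0–1/≤0.05; PolyPhen 0–1/≥0.447 | the analyzers' published operating points; overridable per analyzer in config |
| length penalty | 1/ln l(t_j) | damps the head start long transcripts get in variant counts while retaining weak length sensitivity; 1/sqrt and 1/l selectable for sensitivity checks |
| nonsynonymous set | missense, stop-gained/lost, start-lost | coding consequence terms that alter the protein |
| top fraction | 0.01 | the conventional "top 1 %" export for downstream enrichment; boundary ties included |
| null resamples | 1000 | makes the null SE ~3 % of its SD; larger values change nothing material |
| z denominator | null SD | the observed list is a single draw from the null, not a mean of draws; the SE of the null mean is reported separately |

## Design choices where the design was open

- **Benign-score normalization.** Anchoring x_min at the cutoff makes
  sub-cutoff scores negative under raw min–max; normalized scores are
  clamped to [0, 1] so a benign call contributes exactly 0 to AveScore(v)
  while the variant can still enter through another analyzer's deleterious
  flag. This keeps AveScore in [0, 1] and makes "benign" mean "no
  evidence", not "negative evidence".
- **Eq. for SAR.** SAR is computed as (Σ r_i)/(k·p) − 1/p, the unique
  reading that is 0 when all listed genes are at rank 1, 1 when all are
  absent (rank p + 1), and always within [0, 1].
- **Transcript length source.** Taken from the denominator of the VEP
  `cDNA_position` field (`"123/2034"` → 2034), falling back to a
  config-named explicit length column. Transcripts without a resolvable
  length are excluded from gene models (they cannot enter the ln penalty).
- **N_G scope.** Counts the transcripts of the gene observed in the
  cohort's CSQ annotations, not an external transcript catalog — the
  pipeline's universe is what the annotation shows it.
- **Missing scores.** A variant unscored by analyzer A simply does not
  contribute to A's Q(G) (it is not zero-filled); a variant unscored by
  every analyzer is excluded entirely.
- **Signed frequency difference.** (tumor_v − normal_v) is kept signed;
  normal-enriched variants subtract. Such variants are rare in somatic call
  sets and typically score benign, so their influence is minimal.
- **Sample-class detection.** Tumor/normal genotype columns are found by
  name (`TUMOR`/`NORMAL`, the GDC somatic convention), falling back to
  (second, first) column order; both overridable in config.

## The synthetic-data generator

`iqgene.simulate` emulates the full input contract: per-patient VCFs with
CSQ annotation and paired NORMAL/TUMOR genotype columns, FATHMM-style and
CADD-style external score tables, known-gene and background lists, plus a
ground-truth manifest. Default composition (fixed as the package's study
conditions): 50 patients, 300 genes, 3 planted driver genes; 95 % of
variants tumor-only, 1 % normal-only, the rest common, mirroring the
composition of real somatic cohorts; 7 % of scores missing per analyzer
(within the 5–10 % range seen in practice). Drivers draw ~15 expected
variants per gene with latent deleteriousness Beta(8, 2) and multi-patient
tumor-only carriage (1 + Poisson(3) carriers); passengers draw ~1.5
variants with Beta(2, 5) latent scores and mostly single-patient carriage.
Each analyzer observes the latent value through its native scale and
direction plus truncated Gaussian noise (sd 0.05 on the latent scale). A
tenth of patients receive a duplicate VCF repeating half their variants to
exercise the count-once rule; a twentieth of genes are non-coding and some
passenger variants synonymous, to exercise the filter.

What the generator does **not** emulate: mutational signatures and
context-dependent substitution spectra (substitutions are uniform),
linkage/clonal structure, transcript-specific consequences (a variant's
CSQ entry is repeated for every transcript of its gene), per-transcript
analyzer disagreement, and population-stratification noise. Passing tests
therefore demonstrate the pipeline's arithmetic, contracts and
discrimination under clean planted signal — not calling accuracy on real
tumors.

## Numerical choices

- Gene-score agreement with a literal triple-loop evaluation is verified to
  1e-12 (pure float summation, no stochastic terms).
- Rank ties share the minimal rank of their block; output order breaks ties
  by gene symbol so runs are byte-reproducible.
- Top-percent export takes ceil(fraction × p) genes, extending through any
  score tie at the boundary.
- A degenerate null (all resampled SARs identical, e.g. exhaustive
  sampling) reports SD = 0 and resolves the z-test by the sign of the
  difference, with a warning.
- All randomness (generator, resampling) flows from explicit integer seeds
  through `numpy.random.default_rng`; identical seed ⇒ identical output
  files, bit for bit.

## Problem sizes

The test suite and the acceptance script run on synthetic cohorts of 20–50
patients and 80–300 genes (the default scale being 50/300/3 drivers), and
the multi-seed comparative check uses 20 cohorts of 30 patients × 120
genes. These sizes give stable driver recovery and SAR separation while
keeping a full run in seconds; the pipeline itself is linear in the number
of (variant, transcript) records and has no scale-specific constants.

## Known limitations

- SNVs only: indels, structural variants and splice-region effects outside
  the consequence whitelist are not scored.
- Unweighted transcript averaging: all transcripts of a gene count equally
  in N_G; expression-weighted averaging would need matched transcriptomics.
- The z-test assumes approximate normality of the null SAR; for very small
  k or p the empirical tail proportion (also reported) is the safer number.
- Scores from different analyzers are averaged after cutoff-anchored
  rescaling; this aligns their operating points but does not calibrate
  their probability scales.
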