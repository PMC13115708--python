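"""Synthetic somatic-SNV cohort generator.

Emits everything the pipeline consumes — per-patient VCFs with VEP-style
CSQ annotation and paired NORMAL/TUMOR genotype columns, a per-variant
score CSV (FATHMM-XF dialect), a per-(variant, transcript) score TSV (CADD
dialect), a known-gene list and a protein-coding background list — plus a
ground-truth manifest, so every stage is testable end-to-end without any
external download.

The generative model is deliberately simple test scaffolding, not a claim
about tumor biology.  Each gene gets a Poisson number of SNVs; a small set
of planted "driver" genes receives a much higher variant rate, high latent
deleteriousness, and multi-patient tumor-only carriage, while passenger
genes get sparse, mostly benign, mostly single-patient variants.  Each
analyzer observes the latent deleteriousness of a variant through its own
native scale and direction, perturbed by independent truncated Gaussian
noise, and drops scores at a configurable missingness rate.  Defaults
mirror the tumor/normal composition observed in real somatic cohorts
(~95% tumor-only variants, ~4% common, a sliver normal-only; 5–10% of
scores missing per analyzer).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .analyzers import DEFAULT_ANALYZERS, AnalyzerSpec
from .ingest import change_type_matrix
from .variants import BASES, VariantKey

_ANALYZER_ORDER = ("fathmm", "cadd", "sift", "polyphen")


@dataclass
class SimulationConfig:
    """Knobs of the generator.  Rates are expected SNVs per gene per cohort;
    fractions are probabilities per variant."""

    n_patients: int = 50
    n_genes: int = 300
    n_driver_genes: int = 3
    transcripts_per_gene: Tuple[int, int] = (1, 5)
    transcript_length: Tuple[int, int] = (500, 5000)
    driver_variant_rate: float = 15.0
    passenger_variant_rate: float = 1.5
    tumor_only_fraction: float = 0.95
    normal_only_fraction: float = 0.01
    driver_latent_beta: Tuple[float, float] = (8.0, 2.0)
    passenger_latent_beta: Tuple[float, float] = (2.0, 5.0)
    synonymous_latent_beta: Tuple[float, float] = (1.0, 10.0)
    driver_carrier_mean: float = 3.0     # tumor carriers = 1 + Poisson(mean)
    passenger_carrier_mean: float = 0.5
    normal_carrier_mean: float = 0.2
    synonymous_fraction: float = 0.10    # passenger variants annotated synonymous
    stop_gained_fraction: float = 0.10   # driver variants annotated nonsense
    noncoding_gene_fraction: float = 0.05
    analyzer_noise_sd: float = 0.05
    missing_score_rate: float = 0.07
    duplicate_file_fraction: float = 0.10
    n_background_extra: int = 300
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_patients", "n_genes", "n_driver_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_driver_genes > self.n_genes:
            raise ValueError("n_driver_genes exceeds n_genes")
        for name in ("tumor_only_fraction", "normal_only_fraction",
                     "synonymous_fraction", "stop_gained_fraction",
                     "noncoding_gene_fraction", "missing_score_rate",
                     "duplicate_file_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.tumor_only_fraction + self.normal_only_fraction > 1.0:
            raise ValueError("tumor_only_fraction + normal_only_fraction exceeds 1")
        if self.transcript_length[0] < 2:
            raise ValueError("transcript lengths must be >= 2")


@dataclass
class SimVariant:
    """One generated SNV with its full ground truth."""

    variant: VariantKey
    gene_symbol: str
    consequence: str
    latent: float
    category: str
    tumor_patients: List[str]
    normal_patients: List[str]
    raw_scores: Dict[str, Optional[float]]  # analyzer mode -> raw score or None


@dataclass
class SimGene:
    gene_symbol: str
    chrom: str
    biotype: str
    is_driver: bool
    transcripts: Dict[str, int]  # transcript_id -> length


@dataclass
class TruthManifest:
    """Everything needed to verify the pipeline against the generator."""

    config: SimulationConfig
    genes: List[SimGene]
    variants: List[SimVariant]
    driver_genes: List[str]
    background_genes: List[str]

    def expected_frequency_frame(self) -> pd.DataFrame:
        rows = []
        for sv in self.variants:
            t, n = len(sv.tumor_patients), len(sv.normal_patients)
            cat = "common" if t and n else ("tumor_only" if t else "normal_only")
            rows.append({
                "chrom": sv.variant.chrom, "pos": sv.variant.pos,
                "ref": sv.variant.ref, "alt": sv.variant.alt,
                "tumor_count": t, "normal_count": n, "category": cat,
            })
        df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                         "tumor_count", "normal_count", "category"])
        return df.sort_values(["chrom", "pos", "ref", "alt"], kind="mergesort").reset_index(drop=True)

    def expected_change_matrix(self, sample_class: str) -> pd.DataFrame:
        if sample_class == "tumor":
            keys = [sv.variant for sv in self.variants if sv.tumor_patients]
        elif sample_class == "normal":
            keys = [sv.variant for sv in self.variants if sv.normal_patients]
        else:
            raise ValueError(f"sample_class must be 'tumor' or 'normal', got {sample_class!r}")
        return change_type_matrix(keys)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "config": asdict(self.config),
            "driver_genes": self.driver_genes,
            "background_genes": self.background_genes,
            "genes": [asdict(g) for g in self.genes],
            "variants": [
                {
                    "chrom": sv.variant.chrom, "pos": sv.variant.pos,
                    "ref": sv.variant.ref, "alt": sv.variant.alt,
                    "gene": sv.gene_symbol, "consequence": sv.consequence,
                    "latent": sv.latent, "category": sv.category,
                    "tumor_patients": sv.tumor_patients,
                    "normal_patients": sv.normal_patients,
                    "raw_scores": sv.raw_scores,
                }
                for sv in self.variants
            ],
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass
class SimulatedCohort:
    """File layout of a written synthetic cohort."""

    out_dir: Path
    manifest_path: Path        # cohort manifest CSV (patient_id, vcf_path)
    variant_scores_path: Path  # per-variant score CSV (FATHMM-XF dialect)
    transcript_scores_path: Path  # per-(variant, transcript) TSV (CADD dialect)
    known_genes_path: Path
    background_path: Path
    truth_path: Path
    truth: TruthManifest


def latent_to_analyzer(
    latent: float,
    spec: AnalyzerSpec,
    noise_sd: float,
    rng: np.random.Generator,
) -> float:
    """Map a latent deleteriousness in [0, 1] onto an analyzer's native scale.

    Noise is added on the latent scale, truncated to [0, 1], then stretched
    to the analyzer's range, inverting direction for lower-is-deleterious
    scales (SIFT).
    """
    if not 0.0 <= latent <= 1.0:
        raise ValueError(f"latent deleteriousness must lie in [0, 1], got {latent}")
    noisy = latent + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
    noisy = min(1.0, max(0.0, noisy))
    span = spec.score_max - spec.score_min
    if spec.higher_is_deleterious:
        return spec.score_min + noisy * span
    return spec.score_max - noisy * span


def _sift_cell(raw: Optional[float]) -> str:
    if raw is None:
        return ""
    label = "deleterious" if raw <= 0.05 else "tolerated"
    return f"{label}({raw:.4f})"


def _polyphen_cell(raw: Optional[float]) -> str:
    if raw is None:
        return ""
    label = "probably_damaging" if raw >= 0.447 else "benign"
    return f"{label}({raw:.4f})"


CSQ_FORMAT = "Allele|Consequence|SYMBOL|Feature|BIOTYPE|cDNA_position|SIFT|PolyPhen"


def _generate(config: SimulationConfig) -> TruthManifest:
    config.validate()
    rng = np.random.default_rng(config.seed)
    patients = [f"PAT{i + 1:03d}" for i in range(config.n_patients)]

    # genes, biotypes, transcripts
    genes: List[SimGene] = []
    tid_counter = 0
    coding_idx = []
    for i in range(config.n_genes):
        symbol = f"GENE{i + 1:04d}"
        chrom = f"chr{(i % 22) + 1}"
        biotype = ("lincRNA" if rng.random() < config.noncoding_gene_fraction
                   else "protein_coding")
        lo, hi = config.transcripts_per_gene
        n_tr = int(rng.integers(lo, hi + 1))
        transcripts = {}
        for _ in range(n_tr):
            tid_counter += 1
            length = int(rng.integers(config.transcript_length[0],
                                      config.transcript_length[1] + 1))
            transcripts[f"TRS{tid_counter:06d}"] = length
        genes.append(SimGene(symbol, chrom, biotype, False, transcripts))
        if biotype == "protein_coding":
            coding_idx.append(i)

    driver_idx = sorted(rng.choice(coding_idx, size=config.n_driver_genes, replace=False))
    for i in driver_idx:
        genes[i].is_driver = True
    driver_genes = [genes[i].gene_symbol for i in driver_idx]

    # variants
    pos_counter: Dict[str, int] = {}
    variants: List[SimVariant] = []
    p_common = 1.0 - config.tumor_only_fraction - config.normal_only_fraction
    for gene in genes:
        rate = config.driver_variant_rate if gene.is_driver else config.passenger_variant_rate
        n_var = int(rng.poisson(rate))
        if gene.is_driver:
            n_var = max(n_var, 1)  # a planted driver always carries signal
        for _ in range(n_var):
            pos_counter[gene.chrom] = pos_counter.get(gene.chrom, 10_000) + int(rng.integers(200, 900))
            pos = pos_counter[gene.chrom]
            ref = BASES[rng.integers(0, 4)]
            alt = rng.choice([b for b in BASES if b != ref])
            key = VariantKey(gene.chrom, pos, ref, str(alt))

            if gene.is_driver:
                consequence = ("stop_gained" if rng.random() < config.stop_gained_fraction
                               else "missense_variant")
                a, b = config.driver_latent_beta
            elif rng.random() < config.synonymous_fraction:
                consequence = "synonymous_variant"
                a, b = config.synonymous_latent_beta
            else:
                consequence = "missense_variant"
                a, b = config.passenger_latent_beta
            latent = float(rng.beta(a, b))

            u = rng.random()
            if u < config.tumor_only_fraction:
                category = "tumor_only"
            elif u < config.tumor_only_fraction + config.normal_only_fraction:
                category = "normal_only"
            else:
                category = "common"
            carrier_mean = (config.driver_carrier_mean if gene.is_driver
                            else config.passenger_carrier_mean)
            n_tum = min(config.n_patients, 1 + int(rng.poisson(carrier_mean)))
            n_norm = min(config.n_patients, 1 + int(rng.poisson(config.normal_carrier_mean)))
            tumor_patients: List[str] = []
            normal_patients: List[str] = []
            if category in ("tumor_only", "common"):
                tumor_patients = sorted(rng.choice(patients, size=n_tum, replace=False))
            if category in ("normal_only", "common"):
                normal_patients = sorted(rng.choice(patients, size=n_norm, replace=False))

            raw_scores: Dict[str, Optional[float]] = {}
            for mode in _ANALYZER_ORDER:
                if rng.random() < config.missing_score_rate:
                    raw_scores[mode] = None
                else:
                    raw = latent_to_analyzer(latent, DEFAULT_ANALYZERS[mode],
                                             config.analyzer_noise_sd, rng)
                    raw_scores[mode] = round(float(raw), 4)
            variants.append(SimVariant(key, gene.gene_symbol, consequence, latent,
                                       category, tumor_patients, normal_patients,
                                       raw_scores))

    background = [g.gene_symbol for g in genes if g.biotype == "protein_coding"]
    background += [f"BGONLY{i + 1:04d}" for i in range(config.n_background_extra)]
    return TruthManifest(config=config, genes=genes, variants=variants,
                         driver_genes=driver_genes, background_genes=background)


def _chrom_sort_key(chrom: str) -> Tuple[int, str]:
    core = chrom[3:] if chrom.startswith("chr") else chrom
    return (int(core), "") if core.isdigit() else (99, core)


def _write_vcf(path: Path, variants: Sequence[SimVariant], patient: str,
               gene_by_symbol: Dict[str, SimGene], contigs: Sequence[str]) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=iqgene-simulate",
    ]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += [
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations '
        f'from Ensembl VEP. Format: {CSQ_FORMAT}">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNORMAL\tTUMOR",
    ]
    for sv in variants:
        gene = gene_by_symbol[sv.gene_symbol]
        entries = []
        for tid, length in gene.transcripts.items():
            cdna = f"{max(1, length // 2)}/{length}"
            entries.append("|".join([
                sv.variant.alt, sv.consequence, sv.gene_symbol, tid, gene.biotype,
                cdna, _sift_cell(sv.raw_scores.get("sift")),
                _polyphen_cell(sv.raw_scores.get("polyphen")),
            ]))
        gt_t = "0/1" if patient in sv.tumor_patients else "0/0"
        gt_n = "0/1" if patient in sv.normal_patients else "0/0"
        lines.append("\t".join([
            sv.variant.chrom, str(sv.variant.pos), ".", sv.variant.ref,
            sv.variant.alt, ".", "PASS", "CSQ=" + ",".join(entries),
            "GT", gt_n, gt_t,
        ]))
    path.write_text("\n".join(lines) + "\n")


def simulate_cohort(config: SimulationConfig, out_dir: str | Path) -> SimulatedCohort:
    """Generate a synthetic cohort and write every pipeline input under
    ``out_dir``.  Byte-identical for identical (config, seed)."""
    truth = _generate(config)
    out_dir = Path(out_dir)
    vcf_dir = out_dir / "vcfs"
    vcf_dir.mkdir(parents=True, exist_ok=True)
    gene_by_symbol = {g.gene_symbol: g for g in truth.genes}
    contigs = sorted({g.chrom for g in truth.genes}, key=_chrom_sort_key)
    patients = [f"PAT{i + 1:03d}" for i in range(config.n_patients)]

    # deterministic duplicate-file selection, independent of generation RNG
    dup_rng = np.random.default_rng(config.seed + 1)
    dup_flags = dup_rng.random(config.n_patients) < config.duplicate_file_fraction

    manifest_rows = []
    for pi, patient in enumerate(patients):
        carried = [sv for sv in truth.variants
                   if patient in sv.tumor_patients or patient in sv.normal_patients]
        carried.sort(key=lambda sv: (_chrom_sort_key(sv.variant.chrom), sv.variant.pos))
        vcf_path = vcf_dir / f"{patient}.vcf"
        _write_vcf(vcf_path, carried, patient, gene_by_symbol, contigs)
        manifest_rows.append({"patient_id": patient, "vcf_path": f"vcfs/{patient}.vcf"})
        if dup_flags[pi] and carried:
            # a second file for the same patient repeating half their variants:
            # exercises the count-once deduplication rule
            dup_path = vcf_dir / f"{patient}_rerun.vcf"
            _write_vcf(dup_path, carried[: max(1, len(carried) // 2)], patient,
                       gene_by_symbol, contigs)
            manifest_rows.append({"patient_id": patient,
                                  "vcf_path": f"vcfs/{patient}_rerun.vcf"})

    manifest_path = out_dir / "cohort_manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)

    fathmm_rows, cadd_rows = [], []
    for sv in truth.variants:
        v = sv.variant
        if sv.raw_scores.get("fathmm") is not None:
            fathmm_rows.append({"chrom": v.chrom, "pos": v.pos, "ref": v.ref,
                                "alt": v.alt, "score": sv.raw_scores["fathmm"]})
        if sv.raw_scores.get("cadd") is not None:
            for tid in gene_by_symbol[sv.gene_symbol].transcripts:
                cadd_rows.append({"chrom": v.chrom, "pos": v.pos, "ref": v.ref,
                                  "alt": v.alt, "transcript_id": tid,
                                  "phred": sv.raw_scores["cadd"]})
    variant_scores_path = out_dir / "scores_fathmm.csv"
    transcript_scores_path = out_dir / "scores_cadd.tsv"
    pd.DataFrame(fathmm_rows, columns=["chrom", "pos", "ref", "alt", "score"]).to_csv(
        variant_scores_path, index=False)
    pd.DataFrame(cadd_rows, columns=["chrom", "pos", "ref", "alt", "transcript_id",
                                     "phred"]).to_csv(transcript_scores_path, sep="\t",
                                                      index=False)

    known_genes_path = out_dir / "known_genes.csv"
    known_genes_path.write_text("gene\n" + "\n".join(truth.driver_genes) + "\n")
    background_path = out_dir / "background_genes.txt"
    background_path.write_text("\n".join(truth.background_genes) + "\n")
    truth_path = out_dir / "truth_manifest.json"
    truth.to_json(truth_path)

    return SimulatedCohort(
        out_dir=out_dir, manifest_path=manifest_path,
        variant_scores_path=variant_scores_path,
        transcript_scores_path=transcript_scores_path,
        known_genes_path=known_genes_path, background_path=background_path,
        truth_path=truth_path, truth=truth,
    )
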