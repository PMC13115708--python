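"""Cohort ingestion: parse CSQ-annotated somatic VCFs, build the unique-variant
frequency table, filter to nonsynonymous protein-coding records, and summarize.

VCF files are read with pysam (plain or bgzipped).  The CSQ field layout is
taken from the file's own ``##INFO=<ID=CSQ,...Format: ...>`` metadata line,
so cohorts annotated with different VEP configurations parse without code
changes; which CSQ columns map onto which record fields is configurable
through :class:`CsqFieldMap`.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd
import pysam

from .variants import (
    BASES,
    CATEGORIES,
    COMMON,
    NORMAL_ONLY,
    TUMOR_ONLY,
    ConsequenceRecord,
    VariantFrequency,
    VariantKey,
)

logger = logging.getLogger(__name__)

#: default nonsynonymous consequence whitelist.  Nonsense (stop_gained) is
#: included because premature-stop SNVs are the one loss-of-function class
#: present in somatic SNV-only call sets; terms are Sequence Ontology.
DEFAULT_NONSYNONYMOUS = frozenset(
    {"missense_variant", "stop_gained", "stop_lost", "start_lost"}
)

_SCORE_RE = re.compile(r"\(([-+]?\d*\.?\d+(?:[eE][-+]?\d+)?)\)")


@dataclass(frozen=True)
class CsqFieldMap:
    """Mapping from CSQ column names (as declared in the VCF header) to the
    first-class fields of :class:`ConsequenceRecord`.  Defaults follow VEP's
    standard naming."""

    allele: str = "Allele"
    symbol: str = "SYMBOL"
    feature: str = "Feature"
    consequence: str = "Consequence"
    biotype: str = "BIOTYPE"
    sift: str = "SIFT"
    polyphen: str = "PolyPhen"
    cdna_position: str = "cDNA_position"
    transcript_length: str = "TRANSCRIPT_LENGTH"  # fallback when cDNA_position lacks "/len"


@dataclass
class ParseResult:
    """Outcome of parsing one VCF file for one patient."""

    patient_id: str
    path: str
    records: List[ConsequenceRecord] = field(default_factory=list)
    #: VariantKey -> (carried in tumor sample, carried in normal sample)
    carriage: Dict[VariantKey, Tuple[bool, bool]] = field(default_factory=dict)
    n_skipped_non_snv: int = 0
    n_skipped_bad_csq: int = 0
    warnings: List[str] = field(default_factory=list)


def parse_score_cell(cell: str) -> Optional[float]:
    """Extract the numeric score from a CSQ SIFT/PolyPhen cell.

    Accepts both the qualified form ``"tolerated(0.32)"`` and a bare numeric.
    Returns None for empty or unparseable cells.
    """
    cell = cell.strip()
    if not cell:
        return None
    m = _SCORE_RE.search(cell)
    if m:
        return float(m.group(1))
    try:
        return float(cell)
    except ValueError:
        return None


def _csq_format_fields(vcf: pysam.VariantFile, path: str) -> List[str]:
    try:
        desc = vcf.header.info["CSQ"].description
    except KeyError:
        raise ValueError(f"VCF {path!r} has no ##INFO=<ID=CSQ,...> definition") from None
    marker = "Format:"
    idx = desc.find(marker)
    if idx < 0:
        raise ValueError(f"CSQ INFO description in {path!r} declares no Format: field list")
    return [f.strip() for f in desc[idx + len(marker):].strip().strip('"').split("|")]


def _transcript_length(fields: Mapping[str, str], fmap: CsqFieldMap) -> Optional[int]:
    cdna = fields.get(fmap.cdna_position, "")
    if "/" in cdna:
        tail = cdna.split("/")[-1].strip()
        # VEP may print ranges like "101-102/2034"; the denominator is the length
        if tail.isdigit():
            return int(tail)
    raw = fields.get(fmap.transcript_length, "").strip()
    if raw.isdigit():
        return int(raw)
    return None


def _sample_carries(sample, alt_index: int) -> bool:
    """A sample carries the SNV iff its genotype includes the alt allele.
    Unknown genotypes (./.) are treated as not carrying."""
    gt = sample.get("GT")
    if gt is None:
        return False
    return any(allele == alt_index for allele in gt if allele is not None)


def parse_vcf(
    path: str | Path,
    patient_id: str,
    field_map: CsqFieldMap = CsqFieldMap(),
    tumor_sample: str = "TUMOR",
    normal_sample: str = "NORMAL",
) -> ParseResult:
    """Parse one somatic VCF into per-(SNV, transcript) consequence records
    plus per-SNV tumor/normal carriage flags.

    Tumor and normal genotype columns are located by name (defaults
    ``TUMOR``/``NORMAL``, the GDC somatic convention); when those names are
    absent the second genotype column is taken as tumor and the first as
    normal.  Multi-allelic lines are split into one SNV per alternate
    allele; non-SNV alleles (indels, multi-base substitutions) are skipped
    and counted.
    """
    path = str(path)
    result = ParseResult(patient_id=patient_id, path=path)
    with pysam.VariantFile(path) as vcf:
        csq_fields = _csq_format_fields(vcf, path)
        samples = list(vcf.header.samples)
        if tumor_sample in samples and normal_sample in samples:
            t_name, n_name = tumor_sample, normal_sample
        elif len(samples) >= 2:
            n_name, t_name = samples[0], samples[1]
        elif len(samples) == 1:
            t_name, n_name = samples[0], None
        else:
            t_name = n_name = None

        for line_no, rec in enumerate(vcf, start=1):
            ref = rec.ref or ""
            alts = rec.alts or ()
            csq_entries = rec.info.get("CSQ", ()) if "CSQ" in rec.info else ()
            for alt_index, alt in enumerate(alts, start=1):
                if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
                    result.n_skipped_non_snv += 1
                    continue
                key = VariantKey(rec.chrom, rec.pos, ref, alt)
                in_tumor = in_normal = False
                if t_name is not None:
                    in_tumor = _sample_carries(rec.samples[t_name], alt_index)
                if n_name is not None:
                    in_normal = _sample_carries(rec.samples[n_name], alt_index)
                if in_tumor or in_normal:
                    prev = result.carriage.get(key, (False, False))
                    result.carriage[key] = (prev[0] or in_tumor, prev[1] or in_normal)

                for entry in csq_entries:
                    parts = entry.split("|")
                    if len(parts) != len(csq_fields):
                        result.n_skipped_bad_csq += 1
                        result.warnings.append(
                            f"{path}: record {line_no}: CSQ entry has {len(parts)} fields, "
                            f"expected {len(csq_fields)}; skipped"
                        )
                        continue
                    fields = dict(zip(csq_fields, parts))
                    # attach entry to the matching alt when an Allele column exists
                    csq_allele = fields.get(field_map.allele)
                    if csq_allele and csq_allele in alts and csq_allele != alt:
                        continue
                    extra = {
                        k: v
                        for k, v in fields.items()
                        if k
                        not in {
                            field_map.allele,
                            field_map.symbol,
                            field_map.feature,
                            field_map.consequence,
                            field_map.biotype,
                            field_map.sift,
                            field_map.polyphen,
                            field_map.cdna_position,
                            field_map.transcript_length,
                        }
                    }
                    result.records.append(
                        ConsequenceRecord(
                            variant=key,
                            gene_symbol=fields.get(field_map.symbol, ""),
                            transcript_id=fields.get(field_map.feature, ""),
                            consequence=fields.get(field_map.consequence, ""),
                            biotype=fields.get(field_map.biotype, ""),
                            transcript_length=_transcript_length(fields, field_map),
                            sift_raw=parse_score_cell(fields.get(field_map.sift, "")),
                            polyphen_raw=parse_score_cell(fields.get(field_map.polyphen, "")),
                            extra=extra,
                        )
                    )
    if result.n_skipped_non_snv:
        logger.info("%s: skipped %d non-SNV allele(s)", path, result.n_skipped_non_snv)
    return result


def build_frequency_table(results: Iterable[ParseResult]) -> Dict[VariantKey, VariantFrequency]:
    """Count, per unique SNV, the number of distinct patients carrying it in
    tumor and in normal tissue.  A patient contributing several VCF files in
    which the same SNV recurs is counted once; distinct patients sharing an
    SNV each count."""
    per_patient: Dict[str, Tuple[Set[VariantKey], Set[VariantKey]]] = {}
    for res in results:
        tum, norm = per_patient.setdefault(res.patient_id, (set(), set()))
        for key, (in_t, in_n) in res.carriage.items():
            if in_t:
                tum.add(key)
            if in_n:
                norm.add(key)
    table: Dict[VariantKey, VariantFrequency] = {}
    counts: Dict[VariantKey, List[int]] = {}
    for tum, norm in per_patient.values():
        for key in tum:
            counts.setdefault(key, [0, 0])[0] += 1
        for key in norm:
            counts.setdefault(key, [0, 0])[1] += 1
    for key, (t, n) in counts.items():
        table[key] = VariantFrequency(variant=key, tumor_count=t, normal_count=n)
    return table


def frequencies_to_frame(table: Mapping[VariantKey, VariantFrequency]) -> pd.DataFrame:
    rows = [
        {
            "chrom": f.variant.chrom,
            "pos": f.variant.pos,
            "ref": f.variant.ref,
            "alt": f.variant.alt,
            "tumor_count": f.tumor_count,
            "normal_count": f.normal_count,
            "category": f.category,
        }
        for f in table.values()
    ]
    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "tumor_count", "normal_count", "category"],
    )
    if not df.empty:
        df = df.sort_values(["chrom", "pos", "ref", "alt"], kind="mergesort").reset_index(drop=True)
    return df


def filter_nonsynonymous_protein_coding(
    records: Iterable[ConsequenceRecord],
    nonsynonymous: frozenset[str] | Set[str] = DEFAULT_NONSYNONYMOUS,
    biotype: str = "protein_coding",
) -> List[ConsequenceRecord]:
    """Retain records on protein-coding transcripts whose consequence includes
    at least one term of the nonsynonymous whitelist.  VEP packs multiple
    terms with ``&``; any matching term retains the record.  Records with an
    empty consequence are dropped (and counted by :func:`summarize_cohort`)."""
    kept = []
    for rec in records:
        if rec.biotype != biotype or not rec.consequence:
            continue
        terms = set(rec.consequence.split("&"))
        if terms & set(nonsynonymous):
            kept.append(rec)
    return kept


def change_type_matrix(variants: Iterable[VariantKey]) -> pd.DataFrame:
    """Tally the 12 single-base substitution types as a 4x4 ref-by-alt table
    (the diagonal is structurally zero)."""
    mat = pd.DataFrame(0, index=list(BASES), columns=list(BASES), dtype=int)
    for v in variants:
        mat.loc[v.ref, v.alt] += 1
    return mat


@dataclass
class CohortSummary:
    """Headline counts for one ingested cohort, before and after the
    nonsynonymous/protein-coding filter, plus 12-way nucleotide-change
    matrices per sample class."""

    n_vcf_files: int
    n_patients: int
    n_unique_snvs_all: int
    n_unique_snvs_filtered: int
    category_counts_all: Dict[str, int]
    category_counts_filtered: Dict[str, int]
    n_transcripts_all: int
    n_transcripts_filtered: int
    n_genes_all: int
    n_genes_filtered: int
    change_type_tumor: pd.DataFrame
    change_type_normal: pd.DataFrame

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_vcf_files": self.n_vcf_files,
            "n_patients": self.n_patients,
            "n_unique_snvs_all": self.n_unique_snvs_all,
            "n_unique_snvs_filtered": self.n_unique_snvs_filtered,
            "category_counts_all": self.category_counts_all,
            "category_counts_filtered": self.category_counts_filtered,
            "n_transcripts_all": self.n_transcripts_all,
            "n_transcripts_filtered": self.n_transcripts_filtered,
            "n_genes_all": self.n_genes_all,
            "n_genes_filtered": self.n_genes_filtered,
            "change_type_tumor": self.change_type_tumor.to_dict(),
            "change_type_normal": self.change_type_normal.to_dict(),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def summarize_cohort(
    results: Sequence[ParseResult],
    frequencies: Mapping[VariantKey, VariantFrequency],
    filtered_records: Sequence[ConsequenceRecord],
) -> CohortSummary:
    all_records = [r for res in results for r in res.records]
    filtered_variants = {r.variant for r in filtered_records}

    def _cat_counts(keys: Iterable[VariantKey]) -> Dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for k in keys:
            if k in frequencies:
                out[frequencies[k].category] += 1
        return out

    tumor_vars = [f.variant for f in frequencies.values() if f.tumor_count > 0]
    normal_vars = [f.variant for f in frequencies.values() if f.normal_count > 0]
    return CohortSummary(
        n_vcf_files=len(results),
        n_patients=len({res.patient_id for res in results}),
        n_unique_snvs_all=len(frequencies),
        n_unique_snvs_filtered=len(filtered_variants & set(frequencies)),
        category_counts_all=_cat_counts(frequencies.keys()),
        category_counts_filtered=_cat_counts(filtered_variants),
        n_transcripts_all=len({r.transcript_id for r in all_records if r.transcript_id}),
        n_transcripts_filtered=len({r.transcript_id for r in filtered_records}),
        n_genes_all=len({r.gene_symbol for r in all_records if r.gene_symbol}),
        n_genes_filtered=len({r.gene_symbol for r in filtered_records}),
        change_type_tumor=change_type_matrix(tumor_vars),
        change_type_normal=change_type_matrix(normal_vars),
    )


def read_cohort_manifest(path: str | Path) -> List[Tuple[str, Path]]:
    """Read a cohort manifest CSV (columns ``patient_id``, ``vcf_path``).
    Relative VCF paths are resolved against the manifest's directory."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = {"patient_id", "vcf_path"} - set(df.columns)
    if missing:
        raise ValueError(f"cohort manifest {path} lacks columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        p = Path(row["vcf_path"])
        if not p.is_absolute():
            p = path.parent / p
        out.append((str(row["patient_id"]), p))
    return out


def ingest_cohort(
    manifest_path: str | Path,
    field_map: CsqFieldMap = CsqFieldMap(),
    tumor_sample: str = "TUMOR",
    normal_sample: str = "NORMAL",
) -> Tuple[List[ParseResult], Dict[VariantKey, VariantFrequency]]:
    """Parse every VCF listed in a cohort manifest and build the frequency table."""
    results = [
        parse_vcf(vcf_path, patient_id, field_map, tumor_sample, normal_sample)
        for patient_id, vcf_path in read_cohort_manifest(manifest_path)
    ]
    return results, build_frequency_table(results)
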