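"""End-to-end orchestration: ingest -> merge scores -> score genes -> evaluate.

Thin composition layer over the stage modules; the CLI and the acceptance
script both run through these functions so that shell runs and library runs
cannot drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

from . import analyzers, evaluation, ingest, scoring
from .analyzers import AnalyzerSpec, MergeResult, DEFAULT_ANALYZERS
from .ingest import CohortSummary, CsqFieldMap, ParseResult
from .scoring import PathogenicGeneSet
from .variants import ConsequenceRecord, VariantFrequency, VariantKey


@dataclass
class CohortData:
    """An ingested cohort: parse results, the unique-variant frequency table,
    and the record set before/after the nonsynonymous protein-coding filter."""

    results: List[ParseResult]
    frequencies: Dict[VariantKey, VariantFrequency]
    records: List[ConsequenceRecord]
    filtered_records: List[ConsequenceRecord]

    def summary(self) -> CohortSummary:
        return ingest.summarize_cohort(self.results, self.frequencies, self.filtered_records)


def load_cohort(
    manifest_path: str | Path,
    field_map: CsqFieldMap = CsqFieldMap(),
    tumor_sample: str = "TUMOR",
    normal_sample: str = "NORMAL",
    nonsynonymous=ingest.DEFAULT_NONSYNONYMOUS,
) -> CohortData:
    results, frequencies = ingest.ingest_cohort(manifest_path, field_map,
                                                tumor_sample, normal_sample)
    records = [r for res in results for r in res.records]
    filtered = ingest.filter_nonsynonymous_protein_coding(records, nonsynonymous)
    return CohortData(results=results, frequencies=frequencies,
                      records=records, filtered_records=filtered)


@dataclass
class ScoredCohort:
    cohort: CohortData
    merge: MergeResult
    rankings: Dict[str, PathogenicGeneSet] = field(default_factory=dict)


def score_cohort(
    cohort: CohortData,
    variant_scores_path: Optional[str | Path] = None,
    transcript_scores_path: Optional[str | Path] = None,
    modes: Sequence[str] = ("integrative",),
    specs: Mapping[str, AnalyzerSpec] = DEFAULT_ANALYZERS,
    length_penalty: str = "ln",
) -> ScoredCohort:
    """Merge external analyzer tables onto the filtered records and rank
    pathogenic genes under each requested mode."""
    variant_scores = (analyzers.read_variant_score_table(variant_scores_path)
                      if variant_scores_path else None)
    transcript_scores = (analyzers.read_transcript_score_table(transcript_scores_path)
                         if transcript_scores_path else None)
    merge = analyzers.merge_scores(cohort.filtered_records, variant_scores,
                                   transcript_scores, specs)
    lookup = merge.lookup()
    out = ScoredCohort(cohort=cohort, merge=merge)
    for mode in modes:
        gene_scores = scoring.score_genes(cohort.filtered_records, lookup,
                                          cohort.frequencies, mode, length_penalty)
        out.rankings[mode] = scoring.rank_genes(gene_scores, mode)
    return out


def evaluate_ranking(
    ranking: PathogenicGeneSet,
    known_genes_path: str | Path,
    background_path: str | Path,
    n_resamples: int = 1000,
    seed: int = 0,
) -> evaluation.SARReport:
    known = evaluation.read_gene_list(known_genes_path)
    background = evaluation.read_gene_list(background_path)
    return evaluation.evaluate_sar(known, ranking, background,
                                   n_resamples=n_resamples, seed=seed)
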