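"""Cumulative gene-level variant scoring.

For a gene G with N_G annotated transcripts t_1..t_{N_G} of lengths l(t_j),
the cumulative score under a scoring mode is

    Q(G) = (1/N_G) * sum_j  (1/ln l(t_j)) * sum_{v in t_j} Score(v) * (tumor_v - normal_v)

where the inner sum runs over the deleterious SNVs on transcript t_j,
Score(v) is the mode's normalized score (a single analyzer's score for the
per-analyzer modes; the cross-analyzer mean AveScore(v) for the integrative
mode), and tumor_v / normal_v are the numbers of patients carrying v in
tumor and normal tissue.  The 1/ln(l) factor compensates for longer
transcripts accumulating more variants by chance; transcripts of the gene
with no deleterious variants contribute 0 but still count in N_G.  A gene
is "pathogenic" — eligible for ranking — iff it carries at least one
deleterious SNV under the mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .analyzers import IntegratedScore, MODES
from .variants import ConsequenceRecord, VariantFrequency, VariantKey

#: transcript-length penalty variants; ln is the default and the one used
#: throughout the analyses, the others exist for sensitivity comparison
LENGTH_PENALTIES: Dict[str, Callable[[float], float]] = {
    "ln": math.log,
    "sqrt": math.sqrt,
    "linear": float,
}


@dataclass
class GeneModel:
    """A gene as observed in the cohort's annotations: its symbol and the
    set of annotated transcripts with lengths."""

    gene_symbol: str
    transcripts: Dict[str, int]  # transcript_id -> length

    @property
    def n_transcripts(self) -> int:
        return len(self.transcripts)


@dataclass
class GeneScore:
    gene_symbol: str
    score: float
    mode: str
    n_transcripts: int
    n_variants: int  # distinct deleterious SNVs contributing under the mode
    rank: Optional[int] = None


@dataclass
class PathogenicGeneSet:
    """Ranked pathogenic genes for one scoring mode.  Ranks are competition
    style ("1224"): ties share the minimal rank of their block; output order
    is score-descending with gene symbol as the deterministic tiebreak."""

    genes: List[GeneScore]
    mode: str

    @property
    def p(self) -> int:
        return len(self.genes)

    def rank_lookup(self) -> Dict[str, int]:
        return {g.gene_symbol: g.rank for g in self.genes}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": g.gene_symbol,
                    "score": g.score,
                    "rank": g.rank,
                    "n_transcripts": g.n_transcripts,
                    "n_variants": g.n_variants,
                }
                for g in self.genes
            ],
            columns=["gene", "score", "rank", "n_transcripts", "n_variants"],
        )


def build_gene_models(records: Iterable[ConsequenceRecord]) -> Dict[str, GeneModel]:
    """Collect, per gene symbol, every annotated transcript with a usable
    length.  N_G counts the transcripts observed in the cohort's CSQ
    annotations, the universe the pipeline actually sees."""
    models: Dict[str, GeneModel] = {}
    for rec in records:
        if not rec.gene_symbol or not rec.transcript_id or rec.transcript_length is None:
            continue
        model = models.setdefault(rec.gene_symbol, GeneModel(rec.gene_symbol, {}))
        model.transcripts.setdefault(rec.transcript_id, rec.transcript_length)
    return models


def _mode_score(integ: IntegratedScore, mode: str) -> Tuple[Optional[float], bool]:
    """(score, deleterious flag) for one (variant, transcript) under a mode.

    Per-analyzer modes use that analyzer's own normalized score and its own
    flag — no cross-analyzer rescue; the integrative mode uses AveScore(v)
    with the any-analyzer flag.
    """
    if mode == "integrative":
        if not integ.normalized:
            return None, False
        return integ.ave_score, integ.is_deleterious_any
    if mode not in integ.normalized:
        return None, False
    return integ.normalized[mode], integ.deleterious.get(mode, False)


def transcript_score(
    length: int,
    contributions: Iterable[Tuple[float, int]],
    length_penalty: str = "ln",
) -> float:
    """Inner per-transcript sum: (1/penalty(length)) * sum score * (tumor - normal).

    ``contributions`` yields (score, tumor_v - normal_v) for the deleterious
    variants on the transcript.
    """
    if length < 2:
        raise ValueError(f"transcript length must be >= 2, got {length}")
    penalty = LENGTH_PENALTIES[length_penalty](float(length))
    return sum(score * diff for score, diff in contributions) / penalty


def score_genes(
    records: Sequence[ConsequenceRecord],
    integrated: Mapping[Tuple[VariantKey, str], IntegratedScore],
    frequencies: Mapping[VariantKey, VariantFrequency],
    mode: str = "integrative",
    length_penalty: str = "ln",
) -> List[GeneScore]:
    """Score every pathogenic gene under one mode (unranked).

    ``integrated`` maps (variant, transcript_id) to its IntegratedScore, as
    produced by :meth:`iqgene.analyzers.MergeResult.lookup`.  Variants
    without a score under the mode, or absent from the frequency table, are
    skipped for that mode.
    """
    if mode not in MODES:
        raise ValueError(f"unknown scoring mode {mode!r}; expected one of {MODES}")
    models = build_gene_models(records)
    # gene -> transcript -> set of variants annotated on it
    on_transcript: Dict[str, Dict[str, Set[VariantKey]]] = {}
    for rec in records:
        if rec.gene_symbol in models and rec.transcript_id in models[rec.gene_symbol].transcripts:
            on_transcript.setdefault(rec.gene_symbol, {}).setdefault(
                rec.transcript_id, set()
            ).add(rec.variant)

    out: List[GeneScore] = []
    for symbol, model in models.items():
        total = 0.0
        contributing: Set[VariantKey] = set()
        for tid, length in model.transcripts.items():
            contribs: List[Tuple[float, int]] = []
            for v in on_transcript.get(symbol, {}).get(tid, ()):
                integ = integrated.get((v, tid))
                if integ is None or v not in frequencies:
                    continue
                score, flag = _mode_score(integ, mode)
                if score is None or not flag:
                    continue
                contribs.append((score, frequencies[v].diff))
                contributing.add(v)
            if contribs:
                total += transcript_score(length, contribs, length_penalty)
        if contributing:  # pathogenic: at least one deleterious SNV under the mode
            out.append(
                GeneScore(
                    gene_symbol=symbol,
                    score=total / model.n_transcripts,
                    mode=mode,
                    n_transcripts=model.n_transcripts,
                    n_variants=len(contributing),
                )
            )
    return out


def rank_genes(scores: Iterable[GeneScore], mode: str = "integrative") -> PathogenicGeneSet:
    """Rank pathogenic genes 1..p by descending score, competition ranking."""
    ordered = sorted(scores, key=lambda g: (-g.score, g.gene_symbol))
    ranked: List[GeneScore] = []
    for i, g in enumerate(ordered):
        if i > 0 and g.score == ranked[-1].score:
            rank = ranked[-1].rank
        else:
            rank = i + 1
        ranked.append(
            GeneScore(g.gene_symbol, g.score, g.mode, g.n_transcripts, g.n_variants, rank)
        )
    return PathogenicGeneSet(genes=ranked, mode=mode)


def top_percent(genes: PathogenicGeneSet, fraction: float = 0.01) -> List[str]:
    """Symbols of the ceil(fraction * p) highest-scoring genes; score ties
    straddling the boundary are all included."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    if genes.p == 0:
        return []
    m = math.ceil(fraction * genes.p)
    boundary = genes.genes[m - 1].score
    return [g.gene_symbol for g in genes.genes if g.score >= boundary]


def write_top_list(symbols: Sequence[str], path: str | Path) -> None:
    """One symbol per line — paste-ready for gene-set web tools."""
    Path(path).write_text("\n".join(symbols) + ("\n" if symbols else ""))
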