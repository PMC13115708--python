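"""Functional-effect analyzer integration.

Each analyzer (FATHMM-XF, CADD, SIFT, PolyPhen) scores variant
deleteriousness on its own scale, direction and granularity.  This module
harmonizes directionality (higher = more deleterious everywhere), applies
each analyzer's published deleterious cutoff, and rescales scores with a
cutoff-anchored min-max normalization

    normalized(x) = (x - x_min) / (x_max - x_min),  clamped to [0, 1],

where x_min is the harmonized deleterious cutoff and x_max the harmonized
range maximum — e.g. FATHMM-XF uses (0.5, 1.0), CADD (10, 99), PolyPhen
(0.447, 1.0), and SIFT, after complementing x -> 1 - x, (0.95, 1.0).
Scores below the cutoff therefore normalize to 0: a benign call contributes
nothing to the averaged per-variant score, while any single deleterious
call keeps the variant in play.

AveScore(v), the integrative per-variant score, is the arithmetic mean of
all *available* normalized scores — deleterious or not — and a variant is
deleterious under the integrative mode as soon as at least one analyzer
flags it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .variants import ConsequenceRecord, VariantKey, strip_chr

logger = logging.getLogger(__name__)

_RANGE_TOL = 1e-9


@dataclass(frozen=True)
class AnalyzerSpec:
    """Scale, cutoff, direction and granularity of one effect analyzer."""

    name: str
    score_min: float
    score_max: float
    cutoff: float
    higher_is_deleterious: bool = True
    per_transcript: bool = False

    def __post_init__(self) -> None:
        if not self.score_min < self.score_max:
            raise ValueError(f"{self.name}: score_min must be < score_max")
        if not self.score_min <= self.cutoff <= self.score_max:
            raise ValueError(f"{self.name}: cutoff {self.cutoff} outside score range")

    # -- directionality -------------------------------------------------
    def harmonize(self, raw: float) -> float:
        """Map a raw score so that larger means more deleterious.

        Identity for higher-is-deleterious analyzers; the complement within
        the score range (1 - x for a [0, 1] scale, i.e. SIFT) otherwise.
        """
        self._check_range(raw)
        if self.higher_is_deleterious:
            return raw
        return self.score_min + self.score_max - raw

    def classify_deleterious(self, raw: float) -> bool:
        """Apply the analyzer's cutoff in its native direction."""
        self._check_range(raw)
        if self.higher_is_deleterious:
            return raw >= self.cutoff
        return raw <= self.cutoff

    # -- normalization anchors ------------------------------------------
    @property
    def x_min(self) -> float:
        """Harmonized deleterious cutoff: the lower normalization anchor."""
        return self.harmonize(self.cutoff)

    @property
    def x_max(self) -> float:
        """Harmonized most-deleterious extreme: the upper anchor.

        score_max for higher-is-deleterious scales; for a complemented scale
        the reflected score_min, which algebraically is again score_max.
        """
        return self.score_max

    def normalize(self, harmonized: float) -> float:
        z = (harmonized - self.x_min) / (self.x_max - self.x_min)
        return min(1.0, max(0.0, z))

    def score(self, raw: float) -> Tuple[float, bool]:
        """Raw score -> (normalized score in [0, 1], deleterious flag)."""
        return self.normalize(self.harmonize(raw)), self.classify_deleterious(raw)

    def in_range(self, raw: float) -> bool:
        return self.score_min - _RANGE_TOL <= raw <= self.score_max + _RANGE_TOL

    def _check_range(self, raw: float) -> None:
        if not self.in_range(raw):
            raise ValueError(
                f"{self.name} score {raw} outside declared range "
                f"[{self.score_min}, {self.score_max}]"
            )


#: published score ranges and deleterious cutoffs of the four analyzers
DEFAULT_ANALYZERS: Dict[str, AnalyzerSpec] = {
    "fathmm": AnalyzerSpec("FATHMM-XF", 0.0, 1.0, 0.5, higher_is_deleterious=True,
                           per_transcript=False),
    "cadd": AnalyzerSpec("CADD", 0.0, 99.0, 10.0, higher_is_deleterious=True,
                         per_transcript=True),
    "sift": AnalyzerSpec("SIFT", 0.0, 1.0, 0.05, higher_is_deleterious=False,
                         per_transcript=True),
    "polyphen": AnalyzerSpec("PolyPhen", 0.0, 1.0, 0.447, higher_is_deleterious=True,
                             per_transcript=True),
}

MODES = tuple(DEFAULT_ANALYZERS) + ("integrative",)


@dataclass
class IntegratedScore:
    """Per-(variant, transcript) normalized scores across analyzers."""

    variant: VariantKey
    transcript_id: str
    normalized: Dict[str, float] = field(default_factory=dict)
    deleterious: Dict[str, bool] = field(default_factory=dict)

    @property
    def ave_score(self) -> float:
        """Mean of the available normalized scores (requires >= 1 score)."""
        if not self.normalized:
            raise ValueError("AveScore undefined: no analyzer returned a score")
        return sum(self.normalized.values()) / len(self.normalized)

    @property
    def is_deleterious_any(self) -> bool:
        return any(self.deleterious.values())


# ---------------------------------------------------------------------------
# external score tables
# ---------------------------------------------------------------------------

FATHMM_COLUMNS = {"chrom": "chrom", "pos": "pos", "ref": "ref", "alt": "alt",
                  "score": "score"}
CADD_COLUMNS = {"chrom": "chrom", "pos": "pos", "ref": "ref", "alt": "alt",
                "transcript_id": "transcript_id", "score": "phred"}


def _variant_join_key(chrom: str, pos: int, ref: str, alt: str) -> tuple:
    return (strip_chr(str(chrom)), int(pos), str(ref), str(alt))


def read_variant_score_table(
    path: str | Path,
    columns: Mapping[str, str] = FATHMM_COLUMNS,
    sep: str = ",",
) -> Dict[tuple, float]:
    """Read a per-variant score file (FATHMM-XF style CSV) into a
    {(chrom, pos, ref, alt): score} lookup keyed chr-prefix-agnostically.
    Duplicate keys keep the first score; conflicting duplicates warn."""
    df = pd.read_csv(path, sep=sep, dtype={columns["chrom"]: str})
    out: Dict[tuple, float] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        key = _variant_join_key(d[columns["chrom"]], d[columns["pos"]],
                                d[columns["ref"]], d[columns["alt"]])
        score = float(d[columns["score"]])
        if key in out:
            if out[key] != score:
                logger.warning("%s: conflicting duplicate score for %s; keeping first", path, key)
            continue
        out[key] = score
    return out


def read_transcript_score_table(
    path: str | Path,
    columns: Mapping[str, str] = CADD_COLUMNS,
    sep: str = "\t",
) -> Dict[tuple, float]:
    """Read a per-(variant, transcript) score file (CADD style TSV) into a
    {(chrom, pos, ref, alt, transcript_id): score} lookup."""
    df = pd.read_csv(path, sep=sep, dtype={columns["chrom"]: str, columns["transcript_id"]: str})
    out: Dict[tuple, float] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        key = _variant_join_key(d[columns["chrom"]], d[columns["pos"]],
                                d[columns["ref"]], d[columns["alt"]]) + (d[columns["transcript_id"]],)
        score = float(d[columns["score"]])
        if key in out:
            if out[key] != score:
                logger.warning("%s: conflicting duplicate score for %s; keeping first", path, key)
            continue
        out[key] = score
    return out


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

@dataclass
class MergeResult:
    scores: List[IntegratedScore]
    n_unmatched_variant_rows: int = 0
    n_unmatched_transcript_rows: int = 0
    n_records_unscored: int = 0
    n_out_of_range: int = 0

    def lookup(self) -> Dict[Tuple[VariantKey, str], IntegratedScore]:
        return {(s.variant, s.transcript_id): s for s in self.scores}


def merge_scores(
    records: Sequence[ConsequenceRecord],
    variant_scores: Optional[Mapping[tuple, float]] = None,
    transcript_scores: Optional[Mapping[tuple, float]] = None,
    specs: Mapping[str, AnalyzerSpec] = DEFAULT_ANALYZERS,
    variant_analyzer: str = "fathmm",
    transcript_analyzer: str = "cadd",
) -> MergeResult:
    """Attach every available analyzer score to each (variant, transcript) pair.

    SIFT and PolyPhen come from the records' own CSQ cells; the per-variant
    external table (broadcast to all transcripts of the variant) and the
    per-transcript external table are joined on genomic coordinates, with
    the ``chr`` prefix stripped on both sides.  A pair scored by no analyzer
    yields no IntegratedScore and is excluded downstream.  Out-of-range
    external scores are rejected (counted, treated as missing).
    """
    variant_scores = dict(variant_scores or {})
    transcript_scores = dict(transcript_scores or {})
    result = MergeResult(scores=[])
    consumed_v: set = set()
    consumed_t: set = set()
    seen: set = set()

    def _apply(integ: IntegratedScore, mode: str, raw: float) -> None:
        spec = specs[mode]
        if not spec.in_range(raw):
            logger.warning("rejecting out-of-range %s score %s for %s",
                           spec.name, raw, integ.variant)
            result.n_out_of_range += 1
            return
        norm, flag = spec.score(raw)
        integ.normalized[mode] = norm
        integ.deleterious[mode] = flag

    for rec in records:
        pair = (rec.variant, rec.transcript_id)
        if pair in seen:  # one IntegratedScore per (variant, transcript)
            continue
        seen.add(pair)
        integ = IntegratedScore(variant=rec.variant, transcript_id=rec.transcript_id)
        if rec.sift_raw is not None and "sift" in specs:
            _apply(integ, "sift", rec.sift_raw)
        if rec.polyphen_raw is not None and "polyphen" in specs:
            _apply(integ, "polyphen", rec.polyphen_raw)
        vkey = rec.variant.join_key
        if vkey in variant_scores and variant_analyzer in specs:
            consumed_v.add(vkey)
            _apply(integ, variant_analyzer, variant_scores[vkey])
        tkey = vkey + (rec.transcript_id,)
        if tkey in transcript_scores and transcript_analyzer in specs:
            consumed_t.add(tkey)
            _apply(integ, transcript_analyzer, transcript_scores[tkey])
        if integ.normalized:
            result.scores.append(integ)
        else:
            result.n_records_unscored += 1

    result.n_unmatched_variant_rows = len(set(variant_scores) - consumed_v)
    result.n_unmatched_transcript_rows = len(set(transcript_scores) - consumed_t)
    if result.n_unmatched_variant_rows or result.n_unmatched_transcript_rows:
        logger.info(
            "external score rows matching no cohort record: %d per-variant, %d per-transcript",
            result.n_unmatched_variant_rows, result.n_unmatched_transcript_rows,
        )
    return result


def integrated_to_frame(scores: Iterable[IntegratedScore],
                        specs: Mapping[str, AnalyzerSpec] = DEFAULT_ANALYZERS) -> pd.DataFrame:
    """Integrated score table, one row per (variant, transcript)."""
    rows = []
    for s in scores:
        row = {
            "chrom": s.variant.chrom, "pos": s.variant.pos,
            "ref": s.variant.ref, "alt": s.variant.alt,
            "transcript_id": s.transcript_id,
        }
        for mode in specs:
            row[f"{mode}_norm"] = s.normalized.get(mode)
            row[f"{mode}_deleterious"] = s.deleterious.get(mode)
        row["ave_score"] = s.ave_score
        row["is_deleterious_any"] = s.is_deleterious_any
        rows.append(row)
    return pd.DataFrame(rows)


def specs_from_config(raw: Mapping[str, Mapping]) -> Dict[str, AnalyzerSpec]:
    """Build analyzer specs from a config mapping, overriding the defaults
    field-by-field (e.g. a YAML ``analyzers:`` section)."""
    specs = dict(DEFAULT_ANALYZERS)
    for mode, overrides in raw.items():
        base = specs.get(mode)
        if base is None:
            specs[mode] = AnalyzerSpec(**overrides)
        else:
            specs[mode] = replace(base, **overrides)
    return specs
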