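"""Core domain types for somatic SNV cohorts.

A cohort is a set of patients, each contributing one or more somatic VCF
files with paired tumor/normal genotype columns.  The unit of analysis is
the unique single-nucleotide variant (SNV), identified by its genomic
coordinates and base change, together with per-transcript consequence
annotation parsed from the VEP ``CSQ`` INFO field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

BASES = ("A", "C", "G", "T")

#: variant categories by which sample class of the cohort carries them
TUMOR_ONLY = "tumor_only"
NORMAL_ONLY = "normal_only"
COMMON = "common"
CATEGORIES = (NORMAL_ONLY, TUMOR_ONLY, COMMON)


def strip_chr(chrom: str) -> str:
    """Normalize a chromosome name by removing a leading ``chr`` prefix.

    Used symmetrically on both sides of every join so that cohorts
    annotated as ``chr17`` merge with score tables keyed as ``17``.
    """
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True, order=True)
class VariantKey:
    """A unique SNV: chromosome, 1-based position, reference and alternate base."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"SNVs only: ref/alt must be single bases, got {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ, got {self.ref!r} at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    @property
    def core_chrom(self) -> str:
        return strip_chr(self.chrom)

    @property
    def join_key(self) -> tuple:
        """Key used when merging with external score tables (chr-prefix agnostic)."""
        return (self.core_chrom, self.pos, self.ref, self.alt)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass
class ConsequenceRecord:
    """One (SNV, transcript) annotation row from a CSQ entry.

    ``transcript_length`` carries the transcript length l(t_j) used in the
    length penalty; it is taken from the denominator of the VEP
    ``cDNA_position`` field (``"123/2034"`` -> 2034) or a configured
    fallback field.  ``extra`` retains all other CSQ columns untouched.
    """

    variant: VariantKey
    gene_symbol: str
    transcript_id: str
    consequence: str
    biotype: str
    transcript_length: Optional[int] = None
    sift_raw: Optional[float] = None
    polyphen_raw: Optional[float] = None
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.transcript_length is not None and self.transcript_length < 2:
            raise ValueError(
                f"transcript_length must be >= 2 (ln undefined), got {self.transcript_length} "
                f"for {self.transcript_id}"
            )
        for name, val in (("sift_raw", self.sift_raw), ("polyphen_raw", self.polyphen_raw)):
            if val is not None and not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {val}")


@dataclass
class VariantFrequency:
    """Patient counts for one SNV: how many distinct patients carry it in tumor
    and in normal tissue.  Within-patient duplicates (same SNV in two files of
    one patient) count once; each additional patient counts once more."""

    variant: VariantKey
    tumor_count: int
    normal_count: int

    def __post_init__(self) -> None:
        if self.tumor_count < 0 or self.normal_count < 0:
            raise ValueError("patient counts must be nonnegative")
        if self.tumor_count + self.normal_count < 1:
            raise ValueError(f"variant {self.variant} carried by no patient")

    @property
    def category(self) -> str:
        if self.tumor_count > 0 and self.normal_count > 0:
            return COMMON
        return TUMOR_ONLY if self.tumor_count > 0 else NORMAL_ONLY

    @property
    def diff(self) -> int:
        """tumor_v - normal_v, the signed frequency difference entering the score."""
        return self.tumor_count - self.normal_count
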