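"""Ranking-quality evaluation with the standardized average rank (SAR).

Given a ranking of p pathogenic genes and a list of k genes of interest,
each listed gene takes its competition rank r_i in the ranking, or p + 1
when absent, and

    SAR = (sum_i r_i) / (k * p)  -  1 / p  =  (mean rank - 1) / p .

SAR always lies in [0, 1]: 0 when every listed gene sits at rank 1, 1 when
every listed gene is absent from the ranking.  Lower is better.  Statistical
calibration comes from a resampling null: SAR is recomputed for many random
same-size gene sets drawn without replacement from a background of human
protein-coding gene symbols, and a one-sided z-test asks whether the
observed SAR is significantly below the null mean.  The z denominator is
the null standard deviation (the observed list is a single draw, not a mean
of draws); the standard error of the null mean is reported alongside.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm

from .scoring import PathogenicGeneSet

logger = logging.getLogger(__name__)


def sar(gene_list: Iterable[str], ranking: PathogenicGeneSet,
        rank_lookup: Optional[Mapping[str, int]] = None) -> float:
    """Standardized average rank of a gene list within a ranking.

    Duplicate symbols in the list are collapsed; genes absent from the
    ranking take rank p + 1.
    """
    genes = sorted(set(gene_list))
    if not genes:
        raise ValueError("gene list is empty")
    p = ranking.p
    if p < 1:
        raise ValueError("ranking contains no pathogenic genes (p = 0)")
    ranks = rank_lookup if rank_lookup is not None else ranking.rank_lookup()
    total = sum(ranks.get(g, p + 1) for g in genes)
    return total / (len(genes) * p) - 1.0 / p


@dataclass
class NullDistribution:
    mean: float
    sd: float
    se: float
    samples: np.ndarray
    k: int
    n_resamples: int
    seed: int


def null_distribution(
    ranking: PathogenicGeneSet,
    background: Sequence[str],
    k: int,
    n_resamples: int = 1000,
    seed: int = 0,
) -> NullDistribution:
    """SAR null from random same-size gene sets.

    Draws ``n_resamples`` simple random samples of ``k`` symbols without
    replacement from the background list and computes the SAR of each.
    Reproducible bit-for-bit from ``seed``.
    """
    background = sorted(set(background))
    if k > len(background):
        raise ValueError(f"k = {k} exceeds background size {len(background)}")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    p = ranking.p
    ranks = ranking.rank_lookup()
    rank_arr = np.array([ranks.get(g, p + 1) for g in background], dtype=float)
    rng = np.random.default_rng(seed)
    samples = np.empty(n_resamples)
    n_bg = len(background)
    for i in range(n_resamples):
        idx = rng.choice(n_bg, size=k, replace=False)
        samples[i] = rank_arr[idx].mean() / p - 1.0 / p
    if n_resamples == 1:
        warnings.warn("single resample: null SD/SE are 0 by convention")
        sd = se = 0.0
    elif np.ptp(samples) == 0.0:  # exhaustive/degenerate sampling
        sd = se = 0.0
    else:
        sd = float(samples.std(ddof=1))
        se = sd / np.sqrt(n_resamples)
    return NullDistribution(mean=float(samples.mean()), sd=sd, se=float(se),
                            samples=samples, k=k, n_resamples=n_resamples, seed=seed)


def z_test(known_sar: float, null: NullDistribution) -> Tuple[float, float]:
    """One-sided lower-tail z-test of an observed SAR against the null.

    Returns (z, p_value) with z = (SAR - null mean) / null SD.  A degenerate
    null (SD = 0) yields p = 0 or 1 by the sign of the difference, with a
    warning.
    """
    if null.sd == 0.0:
        warnings.warn("null SAR distribution has zero SD; p-value set by sign")
        diff = known_sar - null.mean
        return (0.0 if diff == 0 else float("-inf") if diff < 0 else float("inf"),
                0.0 if diff < 0 else 1.0)
    z = (known_sar - null.mean) / null.sd
    return float(z), float(norm.cdf(z))


@dataclass
class SARReport:
    """Full evaluation of one gene list against one ranking."""

    sar: float
    k: int
    p: int
    null_mean: float
    null_sd: float
    null_se: float
    n_resamples: int
    z: float
    p_value: float
    empirical_p: float  # fraction of null samples <= observed SAR
    seed: int
    mode: str = ""

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def evaluate_sar(
    gene_list: Iterable[str],
    ranking: PathogenicGeneSet,
    background: Sequence[str],
    n_resamples: int = 1000,
    seed: int = 0,
) -> SARReport:
    """SAR of a gene list plus its resampling null and z-test, in one call.

    Listed symbols missing from the background are logged but still scored
    (they take rank p + 1 when absent from the ranking, like any other).
    """
    genes = sorted(set(gene_list))
    stray = [g for g in genes if g not in set(background)]
    if stray:
        logger.warning("%d listed gene(s) absent from the background list: %s",
                       len(stray), ", ".join(stray[:10]))
    observed = sar(genes, ranking)
    null = null_distribution(ranking, background, k=len(genes),
                             n_resamples=n_resamples, seed=seed)
    z, p_value = z_test(observed, null)
    empirical = float(np.mean(null.samples <= observed))
    return SARReport(
        sar=observed, k=len(genes), p=ranking.p,
        null_mean=null.mean, null_sd=null.sd, null_se=null.se,
        n_resamples=n_resamples, z=z, p_value=p_value,
        empirical_p=empirical, seed=seed, mode=ranking.mode,
    )


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line gene list (CSV with optional ``gene``
    header also accepted)."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    symbols = [ln.split(",")[0].strip() for ln in lines if ln]
    if symbols and symbols[0].lower() in {"gene", "symbol", "gene_symbol"}:
        symbols = symbols[1:]
    return symbols
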