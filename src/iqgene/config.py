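"""YAML run configuration.

Every pipeline default is overridable from a config file; CLI flags win
over the file.  The ``analyzers:`` section patches individual
:class:`~iqgene.analyzers.AnalyzerSpec` fields, e.g.::

    analyzers:
      cadd: {score_max: 60.0}
    nonsynonymous: [missense_variant, stop_gained]
    length_penalty: ln
    top_fraction: 0.01
    resampling: {n: 1000, seed: 7}
    samples: {tumor: TUMOR, normal: NORMAL}
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Optional

import yaml

from .analyzers import DEFAULT_ANALYZERS, AnalyzerSpec, specs_from_config
from .ingest import DEFAULT_NONSYNONYMOUS, CsqFieldMap


@dataclass
class RunConfig:
    specs: Dict[str, AnalyzerSpec] = field(default_factory=lambda: dict(DEFAULT_ANALYZERS))
    nonsynonymous: FrozenSet[str] = DEFAULT_NONSYNONYMOUS
    field_map: CsqFieldMap = field(default_factory=CsqFieldMap)
    tumor_sample: str = "TUMOR"
    normal_sample: str = "NORMAL"
    length_penalty: str = "ln"
    top_fraction: float = 0.01
    n_resamples: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Optional[str | Path]) -> "RunConfig":
        cfg = cls()
        if path is None:
            return cfg
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "analyzers" in raw:
            cfg.specs = specs_from_config(raw["analyzers"])
        if "nonsynonymous" in raw:
            cfg.nonsynonymous = frozenset(raw["nonsynonymous"])
        if "csq_fields" in raw:
            cfg.field_map = CsqFieldMap(**raw["csq_fields"])
        samples = raw.get("samples", {})
        cfg.tumor_sample = samples.get("tumor", cfg.tumor_sample)
        cfg.normal_sample = samples.get("normal", cfg.normal_sample)
        cfg.length_penalty = raw.get("length_penalty", cfg.length_penalty)
        cfg.top_fraction = float(raw.get("top_fraction", cfg.top_fraction))
        resampling = raw.get("resampling", {})
        cfg.n_resamples = int(resampling.get("n", cfg.n_resamples))
        cfg.seed = int(resampling.get("seed", cfg.seed))
        if not 0.0 < cfg.top_fraction <= 1.0:
            raise ValueError(f"top_fraction must lie in (0, 1], got {cfg.top_fraction}")
        return cfg
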