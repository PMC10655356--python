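"""Run-level configuration shared by the analysis workflows.

The defaults mirror the gates used throughout the study design this package
implements: a Benjamini–Hochberg adjusted-p threshold of 0.05 and a linear
1.5-fold ratio gate for the enrichment volcanoes, PCCA (the most abundant
endogenously biotinylated protein) as the normalization reference for
streptavidin-enrichment proteomics, and a 96 h sampling time for the
single-time-point half-life estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class RunConfig:
    """Gates, reference protein and sampling defaults for a pipeline run.

    Parameters
    ----------
    alpha : float
        Adjusted-p (FDR) significance threshold, 0 < alpha < 1.
    ratio_gate : float
        Linear fold-change gate for enrichment calls (applied as
        ``|log2 ratio| >= log2(ratio_gate)``); must be >= 1.
    reference_protein : str
        Accession of the normalization reference (endogenously biotinylated
        carboxylase; PCCA by default).
    min_replicates_quantified : int
        Minimum finite observations per group for a protein to be tested.
    sampling_time_h : float
        Sampling time (hours after heavy-medium switch) for the
        single-time-point half-life estimator.
    random_seed : int
        Seed for any stochastic step launched from this configuration.
    """

    alpha: float = 0.05
    ratio_gate: float = 1.5
    reference_protein: str = "PCCA"
    min_replicates_quantified: int = 3
    sampling_time_h: float = 96.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must lie in (0, 1); got {self.alpha}")
        if self.ratio_gate < 1.0:
            raise ConfigError(f"ratio_gate must be >= 1; got {self.ratio_gate}")
        if self.min_replicates_quantified < 1:
            raise ConfigError("min_replicates_quantified must be >= 1")
        if self.sampling_time_h <= 0:
            raise ConfigError("sampling_time_h must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)
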