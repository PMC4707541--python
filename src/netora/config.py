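"""Run configuration: every tunable of the pipeline, validated on load."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]

_ADJUST_METHODS = ("none", "bonferroni", "bh")


@dataclass
class RunConfig:
    """Configuration of an enrichment run.

    Attributes
    ----------
    permutations
        Number of permutation draws per gene set (default 1000).
    seed
        Master seed; every source of randomness derives from it.
    gpd_trigger
        Exceedance count below which the generalized-Pareto tail estimate
        replaces the empirical p-value (default 10).
    gpd_nexc_start, gpd_nexc_step
        Initial tail size for the GPD fit and the decrement applied while
        the goodness-of-fit test rejects (defaults 250 and 10).
    gpd_ad_alpha
        Significance level of the Anderson-Darling goodness-of-fit test
        (only 0.05 is supported; the critical-value table is fixed).
    set_size_min, set_size_max
        In-network gene-set size filter; ``None`` disables a bound.
    jaccard_threshold
        Strict lower bound on Jaccard similarity for gene-set graph edges.
    significance
        Significance level used when filtering enriched sets into modules.
    adjust_method
        P-value used by the cluster-and-filter step: ``none`` (raw final
        p), ``bonferroni`` or ``bh``.
    no_weight, no_neighbor, self_term
        Weighting-variant switches (ablation controls and the diagonal
        membership term).
    case_fold
        Case-insensitive gene identifier matching on input.
    """

    permutations: int = 1000
    seed: int = 0
    gpd_trigger: int = 10
    gpd_nexc_start: int = 250
    gpd_nexc_step: int = 10
    gpd_ad_alpha: float = 0.05
    set_size_min: int | None = None
    set_size_max: int | None = None
    jaccard_threshold: float = 0.15
    significance: float = 0.05
    adjust_method: str = "none"
    no_weight: bool = False
    no_neighbor: bool = False
    self_term: bool = True
    case_fold: bool = False

    def __post_init__(self) -> None:
        if self.permutations < 100:
            raise ValueError("permutations must be >= 100")
        if self.gpd_trigger < 0:
            raise ValueError("gpd_trigger must be non-negative")
        if self.gpd_nexc_start < 10 or self.gpd_nexc_step < 1:
            raise ValueError("invalid GPD fit constants")
        if self.gpd_ad_alpha != 0.05:
            raise ValueError("only gpd_ad_alpha = 0.05 is supported")
        if not (0.0 <= self.jaccard_threshold <= 1.0):
            raise ValueError("jaccard_threshold must lie in [0, 1]")
        if not (0.0 < self.significance <= 1.0):
            raise ValueError("significance must lie in (0, 1]")
        if self.adjust_method not in _ADJUST_METHODS:
            raise ValueError(f"adjust_method must be one of {_ADJUST_METHODS}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from a JSON or YAML mapping; unknown keys are rejected."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
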