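"""Run configuration shared by the command-line pipelines.

Numeric defaults are the analysis constants of the underlying method: the
-0.30 MPa apoplastic exclusion boundary, the five-point osmotic tail, the
0.96 adjusted-R^2 quality gate, the 1 s acoustic debounce gap and 95%
confidence level.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .errors import InvalidInputError
from .stats_core import DEFAULT_SEED


@dataclass
class RunConfig:
    exclusion_lo: float = -0.30  # MPa; points with psi above this are excluded
    exclusion_hi: float = 0.0  # MPa
    n_tail: int = 5  # points of the 1/psi osmotic line
    qc_adj_r2: float = 0.96  # exponential-fit quality gate
    min_gap: float = 1.0  # s, acoustic debounce
    ci_level: float = 0.95
    n_boot: int = 1000  # bootstrap resamples for the sigmoid band
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if not 0 < self.ci_level < 1:
            raise InvalidInputError("ci_level must lie in (0, 1)")
        if self.min_gap <= 0:
            raise InvalidInputError("min_gap must be positive")
        if self.n_tail < 3:
            raise InvalidInputError("n_tail must be at least 3")
        if self.exclusion_lo >= self.exclusion_hi:
            raise InvalidInputError("exclusion interval must satisfy lo < hi")

    @property
    def exclusion(self) -> tuple[float, float]:
        return (self.exclusion_lo, self.exclusion_hi)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        """Load a config file and apply keyword overrides (None values skipped)."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidInputError(f"unknown config key(s): {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def with_overrides(self, **overrides) -> "RunConfig":
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**data)
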