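"""Run configuration.

Defaults follow the published parameterisation of the method: the
miRNA-side augmentation threshold delta = 0.29, the disease-side threshold
eta = 0.13, and the degree-bias exponent gamma = 0.001 (all tuned by the
original authors on the HMDD corpus).  The semantic contribution factor
(0.5) and the Gaussian-kernel bandwidth numerators (1.0) are the
conventional choices in this literature.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ValidationError

DEGREE_MODES = ("binary", "weighted")


@dataclass
class RunConfig:
    delta: float = 0.29          # miRNA-side augmentation threshold, in [0, 1]
    eta: float = 0.13            # disease-side augmentation threshold, in [0, 1]
    gamma: float = 0.001         # degree-bias exponent of the return pass, >= 0
    semantic_delta: float = 0.5  # per-generation decay of semantic model 1, in (0, 1)
    gip_bandwidth_d: float = 1.0  # disease-kernel bandwidth numerator, > 0
    gip_bandwidth_m: float = 1.0  # miRNA-kernel bandwidth numerator, > 0
    degree_mode: str = "binary"  # "binary" (count edges) | "weighted" (sum weights)
    refit_similarity: bool = True  # rebuild kernels/integration per CV fold
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValidationError("delta must lie in [0, 1]")
        if not 0.0 <= self.eta <= 1.0:
            raise ValidationError("eta must lie in [0, 1]")
        if self.gamma < 0.0:
            raise ValidationError("gamma must be >= 0")
        if not 0.0 < self.semantic_delta < 1.0:
            raise ValidationError("semantic_delta must lie in (0, 1)")
        if self.gip_bandwidth_d <= 0.0 or self.gip_bandwidth_m <= 0.0:
            raise ValidationError("GIP bandwidths must be > 0")
        if self.degree_mode not in DEGREE_MODES:
            raise ValidationError(
                f"degree_mode must be one of {DEGREE_MODES}, got {self.degree_mode!r}"
            )
        self.seed = int(self.seed)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def field_names(cls) -> set[str]:
        return {f.name for f in dataclasses.fields(cls)}

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat key/value YAML document; keyword arguments (e.g. CLI
        flags) override file values.  Unknown keys are rejected."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} is not a mapping")
        unknown = set(raw) - cls.field_names()
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)
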