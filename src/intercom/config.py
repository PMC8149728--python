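"""Run configuration: every pipeline tunable with its default."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict

import yaml


@dataclass
class RunConfig:
    tf_percentile: float = 0.95
    tf_mode: str = "distribution"  # or "absolute"
    hotspot_quantile: float = 0.90
    damping: float = 0.0
    weight_mode: str = "fraction"  # or "mean"
    alpha: float = 0.05
    max_path_len: int = 5
    min_cofrac: float = 0.05
    min_ligand_frac: float = 0.05
    score_quantile: float = 0.90
    null_set: str = "scaffold"  # or "candidates"
    min_cells: int = 20
    seed: int | None = None

    def __post_init__(self):
        for name in (
            "tf_percentile", "hotspot_quantile", "min_cofrac",
            "min_ligand_frac", "score_quantile",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 <= self.damping < 1.0:
            raise ValueError(f"damping must be in [0, 1), got {self.damping}")
        if self.tf_mode not in ("distribution", "absolute"):
            raise ValueError(f"unknown tf_mode {self.tf_mode!r}")
        if self.weight_mode not in ("fraction", "mean"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")
        if self.null_set not in ("scaffold", "candidates"):
            raise ValueError(f"unknown null_set {self.null_set!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_sources(cls, yaml_path=None, **overrides) -> "RunConfig":
        """Build a config with precedence CLI override > YAML file > default.

        ``overrides`` entries that are None are treated as not-given.
        """
        values: dict = {}
        if yaml_path is not None:
            with open(yaml_path) as fh:
                loaded = yaml.safe_load(fh) or {}
            known = {f.name for f in fields(cls)}
            unknown = set(loaded) - known
            if unknown:
                raise ValueError(f"unknown config key(s) in {yaml_path}: {sorted(unknown)}")
            values.update(loaded)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)
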