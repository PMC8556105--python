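"""Declarative run configuration shared by the library pipelines and the CLI.

One :class:`RunConfig` carries every tunable of the workflow; unknown keys in
a config file are rejected rather than ignored, and every training run writes
back a resolved snapshot for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields, replace
from pathlib import Path

import yaml

from .cascade import RFParams, rf_factory
from .features import CHANNELS

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """All workflow tunables.

    w : sliding-window size (odd); padding : terminal padding policy;
    ratio_n : negatives per positive in undersampling; channels : feature
    channels to assemble; n_trees/max_depth/max_features : random-forest
    hyperparameters; threshold : stage-1 gate probability; cv_folds : k of
    the chain-level cross-validation; contact_cutoff/min_chain_length/
    max_identity : curation criteria; seed : master seed from which all
    per-fold seeds derive.
    """

    w: int = 9
    padding: str = "zero"
    ratio_n: int = 5
    channels: tuple[str, ...] = CHANNELS
    n_trees: int = 500
    max_depth: int | None = None
    max_features: str | float = "sqrt"
    threshold: float = 0.5
    stage2_on_predictions: bool = False
    cv_folds: int = 10
    contact_cutoff: float = 3.5
    min_chain_length: int = 50
    max_identity: float = 0.40
    seed: int = 0

    def rf_params(self) -> RFParams:
        return RFParams(self.n_trees, self.max_depth, self.max_features)

    def factory(self):
        return rf_factory(self.rf_params())

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channels"] = list(self.channels)
        return d

    def replace(self, **kwargs) -> "RunConfig":
        if "channels" in kwargs:
            kwargs["channels"] = tuple(kwargs["channels"])
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a YAML config; flag overrides win over file values."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "channels" in raw:
            raw["channels"] = tuple(raw["channels"])
        return cls(**raw)

    def write_snapshot(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
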