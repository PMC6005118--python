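"""Run configuration: every tunable of the model and the simulations.

Serializes losslessly to YAML and hashes its content so output files can
embed provenance.  Defaults are the package's reference conditions: weak
but accurate initial target beliefs (e0=0.25, e1=0.0625), visual
preferences (white, black, red) = (0, +4, -4) log-units, unit learning rate
and policy precision, depth-1 policies, a (3,3) start location, 20-saccade
trials and deterministic (high-precision) action selection.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .lesions import LesionSpec

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # initial Dirichlet counts: a = e0 + e1 * onehot(true outcome)
    e0: float = 0.25
    e1: float = 0.0625
    # visual log-preferences
    c_white: float = 0.0
    c_black: float = 4.0
    c_red: float = -4.0
    # policy machinery
    gamma: float = 1.0
    policy_depth: int = 1
    eta: float = 1.0
    action_mode: str = "argmax"
    # trial structure
    start_row: int = 3
    start_col: int = 3
    n_saccades: int = 20
    model_kind: str = "flat"
    # display
    n_targets: int = 16
    layout: str = "balanced"
    # lesion block
    lesion_kind: str = "none"
    lesion_side: str = "left"
    lesion_magnitude: float | None = None
    lesion_scale: str | None = None
    # randomness
    seed: int = 0
    n_seeds: int = 20

    def __post_init__(self) -> None:
        if self.action_mode not in ("argmax", "sample"):
            raise ValueError(f"unknown action mode: {self.action_mode!r}")
        if self.policy_depth < 1:
            raise ValueError("policy depth must be at least 1")
        self.lesion_spec()  # validates the lesion block

    def lesion_spec(self) -> LesionSpec:
        return LesionSpec(
            kind=self.lesion_kind,
            side=self.lesion_side,
            magnitude=self.lesion_magnitude,
            scale=self.lesion_scale,
        )

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
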