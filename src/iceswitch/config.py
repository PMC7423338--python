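"""Run configuration: a flat, human-editable description of one simulation run.

A :class:`RunConfig` names a network preset, optional rate overrides and
builder flags, the per-cell input distributions, the ensemble size and
horizon, recorded integration windows, and the root seed.  It round-trips
losslessly through YAML, and a completed run's JSON sidecar re-executes to
identical per-cell records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .ensemble import EnsembleResult, InputSpec, run_ensemble
from .network import NetworkModel, PRESETS

__all__ = ["RunConfig", "DEFAULT_INPUTS", "default_config"]

#: Shipped default input distribution per preset: the feedback-only loop
#: starts from binomially distributed BisDC (mean 8 molecules per cell);
#: kickstart and cascade presets start from uniform-integer regulator pulses
#: with mean 8, inside the copy-number range typical for transcription
#: factors.
DEFAULT_INPUTS: dict[str, dict] = {
    "feedback": {"species": "BisDC", "family": "binomial",
                 "params": {"trials": 16, "p": 0.5}},
    "kickstart": {"species": "BisR", "family": "uniform",
                  "params": {"low": 0, "high": 16}},
    "cascade": {"species": "TciR", "family": "uniform",
                "params": {"low": 0, "high": 16}},
}


@dataclass
class RunConfig:
    preset: str
    rates: dict = field(default_factory=dict)
    include_feedback: bool = True
    include_late: bool = False
    late_stability: str = "stable"
    inputs: list = field(default_factory=list)   # list of InputSpec dicts
    n_cells: int = 10_000
    t_end: float = 100.0
    windows: list = field(default_factory=list)  # [[species, t0, t1], ...]
    seed: int = 1
    outdir: str | None = None

    def __post_init__(self):
        if self.preset not in PRESETS:
            raise ValueError(
                f"unknown preset {self.preset!r}; expected one of {sorted(PRESETS)}"
            )
        if not self.inputs:
            self.inputs = [dict(DEFAULT_INPUTS[self.preset])]

    # -- model / ensemble construction -------------------------------------
    def build_model(self) -> NetworkModel:
        builder = PRESETS[self.preset]
        kwargs = {}
        if self.preset in ("kickstart", "cascade"):
            kwargs["include_feedback"] = self.include_feedback
        if self.preset == "cascade":
            kwargs["include_late"] = self.include_late
            kwargs["late_stability"] = self.late_stability
        return builder(self.rates or None, **kwargs)

    def input_specs(self) -> list[InputSpec]:
        return [InputSpec.from_dict(d) for d in self.inputs]

    def run(self) -> EnsembleResult:
        return run_ensemble(
            self.build_model(),
            self.input_specs(),
            n_cells=self.n_cells,
            t_end=self.t_end,
            root_seed=self.seed,
            windows=[tuple(w) for w in self.windows],
        )

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(preset: str, **overrides) -> RunConfig:
    """A RunConfig for ``preset`` with shipped defaults, fields overridable."""
    cfg = RunConfig(preset=preset)
    for key, val in overrides.items():
        if not hasattr(cfg, key):
            raise AttributeError(f"RunConfig has no field {key!r}")
        setattr(cfg, key, val)
    return cfg
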