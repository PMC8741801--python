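"""Run configuration: schema-validated settings shared by the CLI and the
reproduction pipeline, loadable from YAML or JSON."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .task_env import CONTEXTS, VARIANTS

#: frozen package calibration of the quantal-response temperatures
QRE_LAMBDA_SOLO = 0.22
QRE_LAMBDA_INTERACTIVE = 2.0

MODELS = ("pomdp", "l1h1", "l1h2")


@dataclass
class RunConfig:
    """Every tunable of the simulation / replay / analysis pipeline."""

    seed: int
    variant: str = "modified"
    context: str = "solo"
    model: str = "pomdp"
    p_growl: float = 0.7
    p_creak: float = 0.8
    gamma: float = 0.95
    qre_lambda: Optional[float] = None   # None -> model default
    n_particles: int = 1000
    n_trials: int = 10
    n_sessions: int = 3
    n_dyads: int = 31
    n_completions: int = 30

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory for stochastic commands")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.context not in CONTEXTS:
            raise ValueError(f"context must be one of {CONTEXTS}")
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        for name in ("p_growl", "p_creak"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must be in (0, 1)")
        for name in ("n_particles", "n_trials", "n_sessions", "n_dyads",
                     "n_completions"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def horizon(self) -> int:
        return 2 if self.model == "l1h2" else 1

    def resolved_lambda(self) -> float:
        if self.qre_lambda is not None:
            return self.qre_lambda
        return (QRE_LAMBDA_SOLO if self.model == "pomdp"
                else QRE_LAMBDA_INTERACTIVE)


def load_config(path, **overrides) -> RunConfig:
    """Load a YAML/JSON config file; unknown keys are rejected."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) if not str(path).endswith(".json") \
        else json.loads(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
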