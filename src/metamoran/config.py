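"""Scenario configuration, named fixtures and run output writers.

No standard bioinformatics format applies to abstract trait trajectories,
so runs are written as tidy CSV tables plus a JSON manifest (config, seed,
library versions, wall-clock) from which any documented run is reproducible
bit-for-bit.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kernels import ModelKernels, preset_kernels, two_trait_kernels, PRESET_NAMES
from .meanfield import AtomicMeasure, MeasureTrajectory, ParticleTrajectory
from .micro import JumpTrajectory, MicroState
from .replicator import build_interaction_matrix
from .tss import TSSState, TSSTrajectory

__all__ = ["ScenarioConfig", "load_config", "make_fixture", "write_run", "FIXTURE_NAMES"]

_LEVELS = ("micro", "tss", "meanfield", "replicator", "canonical")
_STOCHASTIC_LEVELS = ("micro", "tss", "canonical")


@dataclass
class ScenarioConfig:
    """Validated description of one simulation run."""

    level: str
    preset: str = "neutral"
    kernel_params: dict = field(default_factory=dict)
    N: int = 5
    d: int = 1
    K: int = 1
    M: int = 200
    gamma: float = 1.0
    dt: float = 1e-3
    t_end: float = 1.0
    grid_m: int = 32
    mode: str = "atomic"       # meanfield: atomic | particle
    traits: Optional[list] = None
    w0: str | list = "uniform"
    x0: float | list = 0.0
    seed: Optional[int] = None
    out: Optional[str] = None
    fmt: str = "csv"

    def validate(self) -> "ScenarioConfig":
        errors = []
        if self.level not in _LEVELS:
            errors.append(f"level must be one of {_LEVELS}, got {self.level!r}")
        if self.N < 1:
            errors.append("N must be >= 1")
        if self.K < 1:
            errors.append("K must be >= 1")
        if self.t_end < 0:
            errors.append("t_end must be non-negative")
        if self.dt <= 0:
            errors.append("dt must be positive")
        needs_seed = self.level in _STOCHASTIC_LEVELS or (
            self.level == "meanfield" and self.mode == "particle"
        )
        if needs_seed and self.seed is None:
            errors.append(f"seed is mandatory for stochastic level {self.level!r}")
        if self.level == "meanfield" and self.mode not in ("atomic", "particle"):
            errors.append("meanfield mode must be 'atomic' or 'particle'")
        if self.level == "replicator" and not self.traits:
            errors.append("replicator level requires traits")
        if errors:
            raise ValueError("invalid scenario config:\n  - " + "\n  - ".join(errors))
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> ScenarioConfig:
    """Load and validate a YAML or JSON scenario config."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    known = set(ScenarioConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"invalid scenario config:\n  - unknown fields: {sorted(unknown)}")
    return ScenarioConfig(**data).validate()


FIXTURE_NAMES = ("case1_exclusion", "case2_cycling", "neutral", "monomorphic", "two_trait")


def make_fixture(name: str, seed: int = 0, N: int = 5, K: int = 5, **params) -> dict:
    """Reproducible named scenario: kernels plus matching initial conditions.

    * ``case1_exclusion`` / ``case2_cycling``: traits {0.2, 0.5, 0.8},
      uniform initial weights, migration-fixation kernels of the exclusion
      and cycling regimes, with the replicator interaction matrix attached.
    * ``neutral``: neutral kernels with Gaussian mutation; monomorphic
      initial states at trait 0 for K patches.
    * ``monomorphic``: mutation-free neutral-migration kernels and a
      single-atom measure (everything at trait 0.5) — a fixed point of the
      measure flow.
    * ``two_trait``: discrete two-trait kernels with selection, monomorphic
      initial states at the disfavoured trait.
    """
    if name in ("case1_exclusion", "case2_cycling"):
        kernels = preset_kernels(name, N=N, **params)
        traits = [0.2, 0.5, 0.8]
        w0 = np.full(3, 1.0 / 3.0)
        return {
            "kernels": kernels,
            "traits": traits,
            "w0": w0,
            "interaction_matrix": build_interaction_matrix(traits, kernels),
        }
    if name == "neutral":
        kernels = preset_kernels("neutral", N=N, **params)
        return {
            "kernels": kernels,
            "tss_state": TSSState(np.zeros((K, 1))),
            "micro_state": MicroState.monomorphic(K, N, 0.0),
        }
    if name == "monomorphic":
        kernels = preset_kernels("neutral", N=N, theta0=0.0, **params)
        measure = AtomicMeasure(positions=[0.5], traits=[[0.5]], weights=[1.0])
        return {"kernels": kernels, "measure": measure}
    if name == "two_trait":
        kernels = two_trait_kernels(N=N, **params)
        a = kernels.params["a"]
        return {
            "kernels": kernels,
            "tss_state": TSSState(np.full((K, 1), float(a))),
            "micro_state": MicroState.monomorphic(K, N, float(a)),
        }
    raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")


# ---------------------------------------------------------------------------
# output writers
# ---------------------------------------------------------------------------

def _fmt_trait(x) -> str:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    return ";".join(repr(float(v)) for v in arr)


def _event_frame(events, key_to_trait=None) -> pd.DataFrame:
    rows = []
    for (t, typ, patch, old, new, src) in events:
        if key_to_trait is not None:
            old, new = key_to_trait[old], key_to_trait[new]
        rows.append(
            {
                "time": t,
                "type": typ,
                "patch": patch,
                "from_trait": _fmt_trait(old),
                "to_trait": _fmt_trait(new),
                "src_patch": src,
            }
        )
    return pd.DataFrame(rows, columns=["time", "type", "patch", "from_trait", "to_trait", "src_patch"])


def trajectory_frame(obj) -> pd.DataFrame:
    """Tidy DataFrame view of a trajectory or ensemble object."""
    if isinstance(obj, TSSTrajectory):
        return _event_frame(obj.events)
    if isinstance(obj, JumpTrajectory):
        return _event_frame(obj.events, key_to_trait=obj.state0.traits | (obj.final_state.traits if obj.final_state else {}))
    if isinstance(obj, MeasureTrajectory):
        rows = []
        for ti, t in enumerate(obj.times):
            for k, r in enumerate(obj.positions):
                for i, x in enumerate(obj.traits):
                    rows.append({"time": t, "r": r, "trait_index": i, "trait": _fmt_trait(x), "weight": obj.weights[ti, k, i]})
        return pd.DataFrame(rows, columns=["time", "r", "trait_index", "trait", "weight"])
    if isinstance(obj, ParticleTrajectory):
        rows = []
        for ti, t in enumerate(obj.record_times):
            for m in range(obj.M):
                rows.append({"time": t, "particle": m, "trait": _fmt_trait(obj.snapshots[ti, m])})
        return pd.DataFrame(rows, columns=["time", "particle", "trait"])
    if isinstance(obj, pd.DataFrame):
        return obj
    raise TypeError(f"no tabular view for {type(obj).__name__}")


def replicator_frame(times, W) -> pd.DataFrame:
    """Tidy (time, index, weight) table for a replicator trajectory."""
    times = np.asarray(times)
    W = np.asarray(W)
    rows = [
        {"time": t, "index": i, "weight": W[ti, i]}
        for ti, t in enumerate(times)
        for i in range(W.shape[1])
    ]
    return pd.DataFrame(rows, columns=["time", "index", "weight"])


def write_run(obj, path, config: Optional[ScenarioConfig] = None, seed: Optional[int] = None) -> Path:
    """Write a run as CSV plus a JSON manifest; returns the CSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = trajectory_frame(obj)
    frame.to_csv(path, index=False)
    manifest = {
        "config": config.to_dict() if config is not None else None,
        "seed": seed if seed is not None else (config.seed if config is not None else None),
        "versions": {
            "metamoran": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "rows": int(len(frame)),
    }
    with open(path.with_suffix(path.suffix + ".manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
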