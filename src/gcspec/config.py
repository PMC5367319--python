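"""Run configuration, deterministic seeding, and result readers/writers."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import DIRECTED_BONDS, ModelParams

__all__ = ["RunConfig", "load_config", "save_config", "write_trajectory", "read_trajectory"]

_MODELS = (
    "two_island",
    "three_island",
    "oracle",
    "sweep_threshold",
    "sweep_epsilon",
    "ratio_sd",
)

_NUMERIC_DEFAULTS = dict(dt=1.0, t_max=1e5, record_stride=1, reps=1, seed=0)


@dataclass
class RunConfig:
    """Everything needed to reproduce one run: model, parameters, controls."""

    model: str = "three_island"
    params: ModelParams = field(default_factory=ModelParams)
    dt: float = 1.0
    t_max: float = 1e5
    record_stride: int = 1
    reps: int = 1
    seed: int = 0
    out: str | None = None

    def __post_init__(self):
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {_MODELS}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.t_max <= 0:
            raise ValueError(f"t_max must be positive, got {self.t_max}")
        if self.record_stride < 1:
            raise ValueError(f"record_stride must be >= 1, got {self.record_stride}")
        if self.reps < 1:
            raise ValueError(f"reps must be >= 1, got {self.reps}")

    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if k != "params"}
        d["params"] = self.params.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {"model", "params", "dt", "t_max", "record_stride", "reps", "seed", "out"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "params" in d:
            d["params"] = ModelParams.from_dict(d["params"])
        return cls(**d)


def load_config(path) -> RunConfig:
    """Load and validate a run configuration from a YAML (or JSON) file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    try:
        return RunConfig.from_dict(data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config {path}: {exc}") from exc


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def write_trajectory(records: pd.DataFrame, path, fmt: str = "csv", metadata: dict | None = None) -> None:
    """Write a trajectory table with provenance metadata.

    CSV output carries the metadata as a ``#``-prefixed JSON comment line
    above the header (full float precision via ``repr`` round-trip); JSON
    output is an object with ``metadata`` and ``records`` keys.
    """
    path = Path(path)
    metadata = metadata or {}
    if fmt == "csv":
        with path.open("w") as fh:
            if metadata:
                fh.write("# " + json.dumps(metadata) + "\n")
            records.to_csv(fh, index=False, float_format=None)
    elif fmt == "json":
        payload = {
            "metadata": metadata,
            "columns": list(records.columns),
            "records": records.to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload))
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")


def read_trajectory(path, fmt: str = "csv") -> tuple[pd.DataFrame, dict]:
    """Read back a trajectory written by :func:`write_trajectory`."""
    path = Path(path)
    if fmt == "csv":
        metadata = {}
        with path.open() as fh:
            first = fh.readline()
            if first.startswith("#"):
                metadata = json.loads(first.lstrip("# "))
            else:
                fh.seek(0)
            df = pd.read_csv(fh)
        return df, metadata
    if fmt == "json":
        payload = json.loads(path.read_text())
        df = pd.DataFrame(payload["records"], columns=payload["columns"])
        return df, payload.get("metadata", {})
    raise ValueError(f"unknown trajectory format {fmt!r}")
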