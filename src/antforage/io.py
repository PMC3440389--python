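"""Configuration files, time-series CSV and run manifests.

All outputs are small, diff-able text: per-run time series as CSV
(columns ``step,N1,N2,P1,P2,dissatisfied``), configuration as YAML/JSON
mirroring :class:`~antforage.engine.SimConfig`, and a JSON manifest per
experiment directory sufficient to reproduce it bit-exactly.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agents import BehaviourParams
from .engine import RunResult, SimConfig
from .errors import ConfigError, ParseError
from .metrics import CountSeries
from .world import Geometry, PheromoneParams

_NESTED = {
    "pheromone": PheromoneParams,
    "behaviour": BehaviourParams,
    "geometry": Geometry,
}


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["thresholds"] = list(config.thresholds)
    return d


def _build_nested(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{context} must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {sorted(unknown)}")
    try:
        return cls(**data)
    except TypeError as exc:
        raise ConfigError(f"bad value in {context}: {exc}") from exc


def dict_to_config(data: dict | None) -> SimConfig:
    """Build a SimConfig from a (possibly partial) mapping; absent keys take
    the standard defaults, unknown keys are rejected by name."""
    data = dict(data or {})
    names = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    kwargs: dict = {}
    for key, value in data.items():
        if key in _NESTED:
            kwargs[key] = _build_nested(_NESTED[key], value, key)
        elif key == "thresholds":
            if not isinstance(value, (list, tuple)) or len(value) != 2:
                raise ConfigError("thresholds must be a pair")
            kwargs[key] = (int(value[0]), int(value[1]))
        else:
            kwargs[key] = value
    try:
        return SimConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"bad configuration value: {exc}") from exc


def load_config(path: str | Path) -> SimConfig:
    """Read a YAML or JSON run configuration (empty file = all defaults)."""
    path = Path(path)
    text = path.read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path} must contain a mapping at the top level")
    return dict_to_config(data)


def save_config(config: SimConfig, path: str | Path) -> None:
    path = Path(path)
    d = config_to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


TIMESERIES_COLUMNS = ["step", "N1", "N2", "P1", "P2", "dissatisfied"]


@dataclass
class TimeseriesData:
    """A loaded per-run time series; pheromone/dissatisfied columns are
    optional in the file and None when absent."""

    counts: CountSeries
    pheromone: np.ndarray | None    # (T, 2) or None
    dissatisfied: np.ndarray | None


def write_timeseries(result: RunResult, path: str | Path) -> None:
    result.to_frame().to_csv(path, index=False)


def read_timeseries(path: str | Path) -> TimeseriesData:
    path = Path(path)
    df = pd.read_csv(path)
    required = ["step", "N1", "N2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    for col in [c for c in TIMESERIES_COLUMNS if c in df.columns]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # 1-based incl. header
            raise ParseError(f"{path}: non-numeric value in column {col!r} at row {row}")
        df[col] = coerced
    if df[["step", "N1", "N2"]].isna().any().any():
        raise ParseError(f"{path}: empty cells in required columns")
    counts = CountSeries(
        times=df["step"].to_numpy(dtype=float),
        counts_1=df["N1"].to_numpy(),
        counts_2=df["N2"].to_numpy(),
        source="simulation",
    )
    pher = None
    if "P1" in df.columns and "P2" in df.columns:
        pher = df[["P1", "P2"]].to_numpy(dtype=float)
    dis = df["dissatisfied"].to_numpy() if "dissatisfied" in df.columns else None
    return TimeseriesData(counts=counts, pheromone=pher, dissatisfied=dis)


def write_manifest(
    config: SimConfig,
    seeds: list[int],
    outputs: list[str],
    path: str | Path,
) -> None:
    """JSON manifest echoing the full configuration, package version, seeds
    and output inventory — enough to reproduce the directory bit-exactly."""
    manifest = {
        "package": "antforage",
        "version": __version__,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": config_to_dict(config),
        "seeds": [int(s) for s in seeds],
        "outputs": list(outputs),
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")


def load_manifest(path: str | Path) -> tuple[SimConfig, dict]:
    data = json.loads(Path(path).read_text())
    return dict_to_config(data["config"]), data
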