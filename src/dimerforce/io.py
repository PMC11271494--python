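"""Delimited-text and JSON I/O for traces, dwell tables and results.

File conventions: tab-separated values with a header row and '.' decimals.
Trace files carry columns ``time_s``, ``force_pN``, ``height_nm``; metadata
travels in ``#``-prefixed JSON comment lines before the header. Dwell
tables carry ``force_pN``, ``dwell_s``, ``censored``. Result files are JSON
with explicit units in the field names and enough metadata (seed, config
hash, package version) to regenerate them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .traces import Trace

__all__ = [
    "read_trace",
    "write_trace",
    "read_dwells",
    "write_dwells",
    "write_events",
    "write_results",
    "load_config",
    "config_hash",
    "ConfigError",
]


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the field."""


def write_trace(trace: Trace, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if trace.metadata:
            fh.write("# " + json.dumps(trace.metadata, default=_json_default) + "\n")
        fh.write(f"# sampling_rate_hz={trace.sampling_rate}\n")
        trace.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    metadata: dict = {}
    sampling_rate = 200.0
    n_comment = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line.strip().split("\t")
                break
            n_comment += 1
            body = line[1:].strip()
            if body.startswith("{"):
                metadata.update(json.loads(body))
            elif body.startswith("sampling_rate_hz="):
                sampling_rate = float(body.split("=", 1)[1])
        else:
            raise ValueError(f"{path}: no header line found")
    required = {"time_s", "force_pN", "height_nm"}
    if not required.issubset(header):
        raise ValueError(
            f"{path}: malformed trace header at line {n_comment + 1}: "
            f"expected columns {sorted(required)}, got {header}"
        )
    df = pd.read_csv(path, sep="\t", comment="#")
    return Trace(
        time=df["time_s"].to_numpy(),
        force=df["force_pN"].to_numpy(),
        height=df["height_nm"].to_numpy(),
        sampling_rate=sampling_rate,
        metadata=metadata,
    )


def write_dwells(dwells: pd.DataFrame, path: str | Path) -> None:
    dwells.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_dwells(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"force_pN", "dwell_s", "censored"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: dwell table needs columns {sorted(required)}")
    df["censored"] = df["censored"].astype(bool)
    return df


def write_events(events, path: str | Path) -> None:
    rows = [
        {
            "time_s": e.time,
            "force_pN": e.force_at_step,
            "step_nm": e.step_size,
            "label": e.label or "",
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=["time_s", "force_pN", "step_nm", "label"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=_json_default)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_results(results: dict, path: str | Path, config: dict | None = None,
                  seed: int | None = None) -> None:
    """Write a JSON results file with config echo, hash, seed and version."""
    from . import __version__

    payload = dict(results)
    payload["_meta"] = {
        "package": "dimerforce",
        "version": __version__,
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config) if config is not None else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


_KNOWN_TOP_KEYS = {
    "environment",
    "construct",
    "kinetics",
    "protocol",
    "noise",
    "bootstrap",
    "seed",
    "output_dir",
    "forces",
}


def load_config(path: str | Path) -> dict:
    """Load and validate a YAML/JSON run configuration.

    Unknown top-level keys and malformed sections raise :class:`ConfigError`
    naming the offending field path.
    """
    path = Path(path)
    config = yaml.safe_load(path.read_text())
    if not isinstance(config, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    for key in config:
        if key not in _KNOWN_TOP_KEYS:
            raise ConfigError(f"{path}: unknown key '{key}'")
    env = config.get("environment", {})
    for field_name in ("kBT", "persistence_length", "contour_per_residue"):
        if field_name in env and env[field_name] <= 0:
            raise ConfigError(f"environment.{field_name}: must be > 0")
    if "seed" in config and not isinstance(config["seed"], int):
        raise ConfigError("seed: must be an integer")
    if "forces" in config:
        forces = config["forces"]
        if not isinstance(forces, list) or any(
            not isinstance(f, (int, float)) for f in forces
        ):
            raise ConfigError("forces: must be a list of numbers")
    return config
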