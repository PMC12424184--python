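"""Quantity parsing, config loading and atomic file output."""

from __future__ import annotations

import json
import os
import re
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidParameterError, IOErrorClass, UnitParseError

__all__ = [
    "parse_quantity",
    "parse_grid",
    "load_config",
    "read_csv",
    "write_json_atomic",
    "write_csv_atomic",
    "write_provenance",
]


def read_csv(path: str | Path) -> pd.DataFrame:
    """CSV reader that round-trips the writer's floats bit-exactly."""
    return pd.read_csv(path, float_precision="round_trip")

_CONC_FACTORS = {
    "M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12,
}
_ENERGY_FACTORS = {"kJ/mol": 1.0, "kcal/mol": 4.184}
_TEMP_FACTORS = {"K": 1.0}

_QUANTITY_RE = re.compile(r"^\s*([+-]?\d+\.?\d*(?:[eE][+-]?\d+)?)\s*([^\s\d].*)?\s*$")


def parse_quantity(text: str, kind: str) -> float:
    """Parse ``"0.2uM"``-style strings into canonical units.

    Canonical units are molar for concentrations, kJ/mol for energies and
    kelvin for temperatures; a bare number is taken to already be canonical.
    """
    factors = {"concentration": _CONC_FACTORS, "energy": _ENERGY_FACTORS,
               "temperature": _TEMP_FACTORS}.get(kind)
    if factors is None:
        raise InvalidParameterError(f"unknown quantity kind {kind!r}")
    if isinstance(text, (int, float)):
        return float(text)
    m = _QUANTITY_RE.match(text)
    if not m:
        raise UnitParseError(f"cannot parse {kind} {text!r}")
    value, unit = float(m.group(1)), m.group(2)
    if unit is None:
        return value
    unit = unit.strip()
    if unit not in factors:
        raise UnitParseError(
            f"unknown {kind} unit {unit!r}; accepted: {sorted(factors)}"
        )
    return value * factors[unit]


def parse_grid(text: str) -> np.ndarray:
    """Parse ``"1nM:1mM:60log"`` / ``"1uM:10uM:20lin"`` dose-grid strings."""
    m = re.match(r"^([^:]+):([^:]+):(\d+)(log|lin)$", text.strip())
    if not m:
        raise UnitParseError(
            f"cannot parse grid {text!r}; expected start:stop:COUNT(log|lin)"
        )
    start = parse_quantity(m.group(1), "concentration")
    stop = parse_quantity(m.group(2), "concentration")
    n = int(m.group(3))
    if not (0 < start < stop) or n < 1:
        raise InvalidParameterError(f"grid {text!r} must have 0 < start < stop and n >= 1")
    if m.group(4) == "log":
        return np.geomspace(start, stop, n)
    return np.linspace(start, stop, n)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON config file mirroring the CLI flags."""
    path = Path(path)
    if not path.exists():
        raise IOErrorClass(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    elif path.suffix == ".json":
        data = json.loads(text)
    else:
        raise UnitParseError(f"config must be .yaml/.yml/.json, got {path.suffix!r}")
    if not isinstance(data, dict):
        raise UnitParseError(f"config {path} must be a mapping")
    return data


def _atomic_write(path: str | Path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_json_atomic(path: str | Path, obj: dict) -> None:
    _atomic_write(path, json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_csv_atomic(path: str | Path, df) -> None:
    """CSV with headers at 17 significant digits (bit-exact float round trip)."""
    _atomic_write(path, df.to_csv(index=False, float_format="%.17g"))


def write_provenance(out_path: str | Path, subcommand: str, params: dict,
                     seed: int | None = None) -> None:
    """JSON sidecar recording what produced an output file."""
    from . import __version__

    sidecar = Path(str(out_path) + ".provenance.json")
    write_json_atomic(sidecar, {
        "tool": "ternacoop",
        "version": __version__,
        "subcommand": subcommand,
        "parameters": {k: (v if not isinstance(v, np.ndarray) else v.tolist())
                       for k, v in params.items()},
        "seed": seed,
    })
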