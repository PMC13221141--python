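"""Reading and writing the delimited tables the toolkit exchanges.

Conventions: UTF-8 CSV with "." decimal and no thousands separators,
times always in minutes (`time_min`), temperatures in degrees Celsius
(`temperature_C`), missing values written as ``NA``.  All writes are
atomic (temp file then rename) and every pipeline run is accompanied by
a YAML manifest echoing the effective configuration, the package and
dependency versions, and the seed, so a run can be reproduced
bit-for-bit.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .fluctuating import TemperatureProfile
from .static_fit import FailureDataset

__all__ = [
    "TableFormatError",
    "read_failure_table",
    "write_failure_table",
    "read_profile_table",
    "write_profile_table",
    "read_observed_sets",
    "write_table",
    "write_text",
    "write_manifest",
    "read_config",
]

REQUIRED_FAILURE_COLUMNS = ("species", "temperature_C", "time_min", "trial_id")


class TableFormatError(ValueError):
    """A delimited input does not match the expected layout."""


def _read_csv(path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TableFormatError(f"{path}: file not found")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path}: file is empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise TableFormatError(f"{path}: no data rows")
    return df


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    s = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[s.isna() & df[col].notna()]
    if len(bad):
        # +2: header line plus 1-based numbering
        lines = [int(i) + 2 for i in bad[:5]]
        raise TableFormatError(
            f"{path}: unparsable number in column {col!r} at line(s) {lines}"
        )
    if s.isna().any():
        lines = [int(i) + 2 for i in df.index[s.isna()][:5]]
        raise TableFormatError(f"{path}: missing value in column {col!r} at line(s) {lines}")
    return s.astype(float)


def read_failure_table(path) -> FailureDataset:
    """Load a constant-temperature failure table.

    Columns (any order): species, temperature_C, time_min, trial_id and
    optionally sex.  Rows with nonpositive times raise an error citing
    the offending line numbers.
    """
    df = _read_csv(path, REQUIRED_FAILURE_COLUMNS)
    df["temperature_C"] = _numeric(df, "temperature_C", path)
    df["time_min"] = _numeric(df, "time_min", path)
    bad = df.index[df["time_min"] <= 0]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]
        raise TableFormatError(
            f"{path}: nonpositive time_min at line(s) {lines}"
        )
    if "sex" not in df.columns:
        df["sex"] = None
    return FailureDataset(df)


def write_failure_table(data: FailureDataset, path) -> None:
    write_table(data.frame, path)


def read_profile_table(path) -> dict[str, TemperatureProfile]:
    """Load temperature profiles: columns time_min, temperature_C, and
    optionally set_id (one profile per set) and interpolation."""
    df = _read_csv(path, ("time_min", "temperature_C"))
    df["time_min"] = _numeric(df, "time_min", path)
    df["temperature_C"] = _numeric(df, "temperature_C", path)
    if "set_id" not in df.columns:
        df["set_id"] = "set00"
    out = {}
    for set_id, g in df.groupby("set_id", sort=True):
        interp = "stepwise"
        if "interpolation" in g.columns:
            vals = g["interpolation"].dropna().unique()
            if len(vals) > 1:
                raise TableFormatError(f"{path}: set {set_id!r} mixes interpolation kinds")
            if len(vals):
                interp = str(vals[0])
        out[str(set_id)] = TemperatureProfile(
            g["time_min"].to_numpy(), g["temperature_C"].to_numpy(), interpolation=interp
        )
    return out


def write_profile_table(profiles: Mapping[str, TemperatureProfile], path) -> None:
    rows = []
    for set_id, p in profiles.items():
        for t, T in zip(p.times, p.temperatures):
            rows.append(dict(set_id=set_id, time_min=t, temperature_C=T,
                             interpolation=p.interpolation))
    write_table(pd.DataFrame(rows), path)


def read_observed_sets(path) -> pd.DataFrame:
    """Load observed failure times per assay set: columns set_id,
    time_min and optionally sex."""
    df = _read_csv(path, ("set_id", "time_min"))
    df["time_min"] = _numeric(df, "time_min", path)
    bad = df.index[df["time_min"] <= 0]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]
        raise TableFormatError(f"{path}: nonpositive time_min at line(s) {lines}")
    if "sex" not in df.columns:
        df["sex"] = None
    return df


def _atomic_write(path, writer) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            writer(fh)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_table(df: pd.DataFrame, path) -> None:
    """CSV with '.' decimal and NA for missing values, written atomically."""
    _atomic_write(path, lambda fh: df.to_csv(fh, index=False, na_rep="NA"))


def write_text(text: str, path) -> None:
    _atomic_write(path, lambda fh: fh.write(text))


def write_manifest(path, config: Mapping, seed=None) -> None:
    """Echo the effective configuration plus versions into a YAML
    manifest; a run is reproducible bit-for-bit from this file."""
    import scipy

    from . import __version__

    manifest = {
        "tdtsurv": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "seed": seed,
        "config": {k: _plain(v) for k, v in dict(config).items()},
    }
    _atomic_write(path, lambda fh: yaml.safe_dump(manifest, fh, sort_keys=True))


def _plain(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, (tuple, list, np.ndarray)):
        return [_plain(x) for x in v]
    if isinstance(v, Mapping):
        return {k: _plain(x) for k, x in v.items()}
    if isinstance(v, Path):
        return str(v)
    return v


def read_config(path) -> dict:
    """Flat key-value YAML config; CLI flags override its entries."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise TableFormatError(f"{path}: config must be a flat mapping")
    return cfg
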