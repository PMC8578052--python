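"""Readers and writers for measurement tables, IDV matrices and configs.

CSV dialect everywhere: comma separator, '.' decimal, LF endings, %ID
scale.  Writers always emit the canonical channel order; the reader
accepts permuted columns and reorders them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .layout import CHANNELS, ConfigurationError
from .measurements import MeasurementSet
from .mixing import validate_idv

__all__ = [
    "read_measurements",
    "write_measurements",
    "read_idv",
    "write_idv",
    "read_config",
]

TIME_COLUMN = "time_h"


class SchemaError(ValueError):
    """Raised when an input file does not match the expected schema."""


def read_measurements(path, provenance: str = "simulated") -> MeasurementSet:
    """Read an organ-fluorescence table (time_h + 9 channel columns)."""
    df = pd.read_csv(path)
    if TIME_COLUMN not in df.columns:
        raise SchemaError(f"missing column {TIME_COLUMN!r}")
    for ch in CHANNELS:
        if ch not in df.columns:
            raise SchemaError(f"missing channel column {ch!r}")
    df = df.sort_values(TIME_COLUMN)
    times = df[TIME_COLUMN].to_numpy(float)
    if np.any(np.diff(times) == 0):
        raise SchemaError("duplicate time points")
    values = df[list(CHANNELS)].to_numpy(float).T
    neg = np.argwhere(values < 0)
    if neg.size:
        ch, row = neg[0]
        raise ValueError(
            f"negative value in channel {CHANNELS[ch]!r} at row {int(row)}"
        )
    return MeasurementSet(times_h=times, values=values, provenance=provenance)


def write_measurements(meas: MeasurementSet, path) -> None:
    df = pd.DataFrame({TIME_COLUMN: meas.times_h})
    for i, ch in enumerate(CHANNELS):
        df[ch] = meas.values[i]
    df.to_csv(path, index=False, lineterminator="\n")


def read_idv(path) -> np.ndarray:
    """Read a 9x9 IDV matrix CSV with a 'source' label column."""
    df = pd.read_csv(path, index_col=0)
    if list(df.columns) != list(CHANNELS) or list(df.index) != list(CHANNELS):
        raise SchemaError("IDV file must be labeled with the 9 canonical channels")
    idv = df.to_numpy(float)
    validate_idv(idv)
    return idv


def write_idv(idv: np.ndarray, path) -> None:
    df = pd.DataFrame(np.asarray(idv), index=list(CHANNELS), columns=list(CHANNELS))
    df.index.name = "source"
    df.to_csv(path, lineterminator="\n")


def read_config(path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigurationError("config file must contain a mapping")
    return data
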