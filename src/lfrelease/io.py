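"""File I/O: time-series CSV, batch-configuration JSON, fit reports, manifests.

Formats are deliberately plain: CSV with a ``t_min,y[,sd]`` header for
measurements (``t_h`` accepted and converted), strict JSON for batch
configurations.  Validation is fail-fast — the parameter sheets mix scales
across ten orders of magnitude, so a silently mis-keyed field is the main
operational risk.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from lfrelease.fitting import FitResult, TimeSeries
from lfrelease.kinetics import BatchConfig, Trajectory

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_batch_config",
    "write_batch_config",
    "batch_config_from_dict",
    "write_trajectory",
    "read_trajectory",
    "write_fit_report",
    "RunManifest",
]

_REQUIRED_CONFIG_KEYS = {
    "W_s", "V_s", "V_ads0", "V_h", "V_b0", "k_v",
    "n_s0", "n_ads0", "n_b0", "H_Lf", "beta_sl", "beta_ll",
}
_OPTIONAL_CONFIG_KEYS = {"t_dissolve", "mw_lf", "stirred", "label"}


class ParseError(ValueError):
    """A file's content does not match the expected schema."""


def read_timeseries(path: str | Path, kind: str) -> TimeSeries:
    """Read a measurement CSV with header ``t_min,y[,sd]`` (or ``t_h``).

    An hours column ``t_h`` is converted to minutes on ingest.  Raises
    :class:`ParseError` naming the offending column or row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if "t_min" in df.columns:
        t = df["t_min"]
    elif "t_h" in df.columns:
        t = df["t_h"] * 60.0
    else:
        raise ParseError(f"{path}: missing time column 't_min' (or 't_h')")
    if "y" not in df.columns:
        raise ParseError(f"{path}: missing value column 'y'")
    for col in ("t_min", "t_h", "y", "sd"):
        if col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ParseError(
                    f"{path}: non-numeric value in column {col!r} at data row {row}"
                )
    sd = df["sd"].to_numpy(float) if "sd" in df.columns else None
    try:
        return TimeSeries(t=t.to_numpy(float), y=df["y"].to_numpy(float),
                          sd=sd, kind=kind, label=path.stem)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_timeseries(series: TimeSeries, path: str | Path) -> None:
    """Write a series as ``t_min,y[,sd]`` CSV at full double precision."""
    cols = {"t_min": series.t, "y": series.y}
    if series.sd is not None:
        cols["sd"] = series.sd
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def batch_config_from_dict(raw: dict) -> BatchConfig:
    """Validate a raw mapping into a :class:`BatchConfig` (strict keys)."""
    if not isinstance(raw, dict):
        raise ParseError("batch configuration must be a JSON object")
    unknown = set(raw) - _REQUIRED_CONFIG_KEYS - _OPTIONAL_CONFIG_KEYS
    if unknown:
        raise ParseError(f"unknown configuration keys: {sorted(unknown)}")
    missing = _REQUIRED_CONFIG_KEYS - set(raw)
    if missing:
        raise ParseError(f"missing configuration keys: {sorted(missing)}")
    try:
        return BatchConfig(**raw)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"invalid batch configuration: {exc}") from exc


def read_batch_config(path: str | Path) -> BatchConfig:
    """Read and strictly validate a batch-configuration JSON file."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON ({exc})") from exc
    try:
        return batch_config_from_dict(raw)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_batch_config(config: BatchConfig, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(dataclasses.asdict(config), indent=2) + "\n"
    )


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write the standard trajectory CSV (t_min ... release_fraction, dissolved)."""
    trajectory.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_trajectory(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"t_min", "n_b_mol", "release_fraction"}
    missing = expected - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing trajectory columns {sorted(missing)}")
    return df


def write_fit_report(result: FitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2) + "\n")


@dataclass
class RunManifest:
    """Provenance record written alongside every command-line run's outputs."""

    command: str
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    seed: int | None = None
    mode: str | None = None
    options: dict = field(default_factory=dict)
    timestamp: str = ""
    version: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()
        if not self.version:
            from lfrelease import __version__

            self.version = __version__

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2) + "\n"
        )
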