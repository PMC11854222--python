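"""Synthetic measurement generator and packaged reference fixtures.

The release curves of the source study were only plotted, never tabulated,
so every estimation stage is exercised against data generated here: forward
trajectories of the swelling / two-film release model plus additive Gaussian
measurement noise (SD 0.008 in the measured unit for release observables,
the study's stated replicate scatter).  The swelling-weight generator
mirrors the weighing protocol: a dry-mass baseline, a first-order uptake
curve, and a noise-free zero-time point (the dry mass is weighed exactly
once, before immersion).

The packaged fixtures carry the study's printed inputs verbatim: the three
batch parameter sheets, the weight-vs-time swelling table, the swelling
degree table and the encapsulation-efficiency table.

What the generator does *not* emulate: the aliquot withdrawal/return of the
real sampling protocol, particle-to-particle size variability, and any
heteroscedasticity of the assay.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from lfrelease.fitting import TimeSeries
from lfrelease.kinetics import (
    WATER_DENSITY,
    BatchConfig,
    SwellingParams,
    simulate_release,
    swelling_closed_form,
)

__all__ = [
    "NoiseSpec",
    "generate_swelling_series",
    "generate_release_series",
    "relative_error_bars",
    "StudyFixtures",
    "study_fixtures",
    "load_batch_config",
    "BATCH_NAMES",
]

BATCH_NAMES = ("batch1", "batch2", "batch3")

#: replicate standard deviation of the release measurements (fraction units)
DEFAULT_RELEASE_SD = 0.008


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian measurement noise, in the measured unit."""

    sd: float = DEFAULT_RELEASE_SD
    seed: int | None = None
    model: str = "additive_gaussian"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if self.model != "additive_gaussian":
            raise ValueError(f"unknown noise model {self.model!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def generate_swelling_series(
    params: SwellingParams,
    dry_mass: float,
    times: Sequence[float],
    noise: NoiseSpec,
) -> TimeSeries:
    """Swelling weights W(t) = dry_mass + rho * V_ads(t) + noise.

    ``times`` in minutes, sorted and starting at 0; the t = 0 weight is
    noise-free (it is the dry-mass reference every later point is compared
    against).  Mass unit is whatever ``dry_mass`` is expressed in, with the
    water density interpreted consistently.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0 or t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be sorted, start at 0, and be distinct")
    clean = dry_mass + WATER_DENSITY * swelling_closed_form(t, params)
    eps = noise.rng().normal(0.0, noise.sd, size=t.size) if noise.sd > 0 else 0.0
    w = clean + eps
    if noise.sd > 0:
        w[0] = clean[0]
    sd = np.full(t.size, noise.sd) if noise.sd > 0 else None
    return TimeSeries(t=t, y=w, sd=sd, kind="swelling_weight",
                      label="synthetic swelling weights")


def generate_release_series(
    config: BatchConfig,
    times: Sequence[float],
    noise: NoiseSpec,
    observable: str = "release_fraction",
    rtol: float = 1e-9,
) -> TimeSeries:
    """Sample a simulated release trajectory and add measurement noise.

    ``observable`` is ``"release_fraction"`` (dimensionless cumulative
    fraction, clipped to [0, 1] after noise — it is a physical fraction) or
    ``"bulk_concentration"`` (mol/cm^3).  Noise is additive Gaussian with
    ``noise.sd`` in the unit of the observable; the per-point SD is attached
    to the returned series.
    """
    t = np.asarray(times, dtype=float)
    if t.size and t[0] != 0:
        grid = np.concatenate([[0.0], t])
        drop_first = True
    else:
        grid = t
        drop_first = False
    traj = simulate_release(config, grid, rtol=rtol)
    if observable == "release_fraction":
        clean = traj.release_fraction
    elif observable == "bulk_concentration":
        clean = traj.C_b
    else:
        raise ValueError(f"unknown observable {observable!r}")
    if drop_first:
        clean = clean[1:]
    y = clean.copy()
    if noise.sd > 0:
        y = y + noise.rng().normal(0.0, noise.sd, size=y.size)
    if observable == "release_fraction":
        y = np.clip(y, 0.0, 1.0)
    sd = np.full(t.size, noise.sd) if noise.sd > 0 else None
    return TimeSeries(t=t, y=y, sd=sd, kind=observable,
                      label=f"synthetic {observable} ({config.label or 'batch'})")


def relative_error_bars(series: TimeSeries) -> np.ndarray:
    """Error bars as the ratio SD / value, the study's plotting convention.

    Points with zero measured value get ``nan`` (an undefined ratio).
    """
    if series.sd is None:
        raise ValueError("series carries no standard deviations")
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(series.y != 0.0, series.sd / series.y, np.nan)


class StudyFixtures(NamedTuple):
    """The study's printed inputs as in-memory objects."""

    batches: dict[str, BatchConfig]
    swelling_weights: TimeSeries      # weight table, mg, hours -> minutes
    swelling_degree: pd.DataFrame     # Q(%) per sample and time
    encapsulation: pd.DataFrame       # EE(%) per preparation batch


def _data_text(name: str) -> str:
    return (resources.files("lfrelease.data") / name).read_text()


def load_batch_config(name: str) -> BatchConfig:
    """Load one of the packaged batch parameter sheets (``batch1``..``batch3``)."""
    if name not in BATCH_NAMES:
        raise ValueError(f"unknown batch {name!r}; expected one of {BATCH_NAMES}")
    from lfrelease.io import batch_config_from_dict

    return batch_config_from_dict(json.loads(_data_text(f"{name}.json")))


def study_fixtures() -> StudyFixtures:
    """All packaged reference data.

    The swelling-weight series is in mg with times converted from hours to
    minutes; ``k_v`` fits are invariant to the mass unit.
    """
    batches = {name: load_batch_config(name) for name in BATCH_NAMES}
    from io import StringIO

    wt = pd.read_csv(StringIO(_data_text("swelling_weights.csv")))
    weights = TimeSeries(
        t=wt["t_h"].to_numpy() * 60.0,
        y=wt["y"].to_numpy(),
        sd=wt["sd"].to_numpy(),
        kind="swelling_weight",
        label="measured swelling weights (mg)",
    )
    q = pd.read_csv(StringIO(_data_text("swelling_degree.csv")))
    ee = pd.read_csv(StringIO(_data_text("encapsulation_efficiency.csv")))
    return StudyFixtures(batches=batches, swelling_weights=weights,
                         swelling_degree=q, encapsulation=ee)
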