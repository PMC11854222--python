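"""Scalar descriptive metrics: swelling degree, encapsulation efficiency.

These are the bench-top numbers reported alongside the kinetic model: the
percent mass gain of a particle after water uptake, the fraction of offered
protein actually captured during encapsulation, their across-batch summary,
and the cumulative-release-percent view of a simulated trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from lfrelease.fitting import InsufficientDataError, TimeSeries
from lfrelease.kinetics import DomainError, Trajectory

__all__ = [
    "MetricRecord",
    "swelling_degree",
    "encapsulation_efficiency",
    "summarize_batches",
    "cumulative_release_percent",
]


@dataclass(frozen=True)
class MetricRecord:
    """A labelled percent value with its operands echoed for provenance."""

    label: str
    value: float
    inputs: dict = field(default_factory=dict)


def swelling_degree(m_sw: float, m_d: float) -> float:
    """Swelling degree Q(%) = (M_sw - M_d) / M_d * 100.

    ``m_sw`` is the swollen (wet) mass and ``m_d`` the dry mass, in the same
    unit.  Scale-invariant: multiplying both masses by a constant leaves Q
    unchanged.
    """
    if not m_d > 0:
        raise DomainError(f"dry mass must be > 0, got {m_d}")
    if m_sw < m_d:
        raise DomainError(
            f"swollen mass ({m_sw}) below dry mass ({m_d}); Q is undefined"
        )
    return (m_sw - m_d) / m_d * 100.0


def encapsulation_efficiency(m_total: float, m_free: float) -> float:
    """Encapsulation efficiency EE(%) = (m - m_f) / m * 100.

    ``m_total`` is the protein mass offered and ``m_free`` the unencapsulated
    mass recovered in the supernatant.
    """
    if not m_total > 0:
        raise DomainError(f"total mass must be > 0, got {m_total}")
    if m_free < 0 or m_free > m_total:
        raise DomainError(
            f"free mass ({m_free}) must lie in [0, total mass ({m_total})]"
        )
    return (m_total - m_free) / m_total * 100.0


def summarize_batches(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1 denominator) of batch values.

    Returns full-precision floats; round to one decimal for display to match
    the usual table convention.  The sample (rather than population) SD is
    the convention for a handful of independently prepared batches.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise InsufficientDataError(
            f"need >= 2 values to summarise, got {vals.size}"
        )
    return float(vals.mean()), float(vals.std(ddof=1))


def cumulative_release_percent(trajectory: Trajectory) -> TimeSeries:
    """Cumulative release C(%) = 100 * n_b(t) / N_total as a time series."""
    if trajectory.t.size == 0:
        raise ValueError("trajectory is empty")
    return TimeSeries(
        t=trajectory.t,
        y=100.0 * trajectory.release_fraction,
        kind="release_fraction",
        label="cumulative release (%)",
    )
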