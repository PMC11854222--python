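"""Parameter estimation for the swelling and release models.

Two estimation problems arise:

* the swelling constant ``k_v`` from particle weight-vs-time data, using the
  analytic swelling curve (no ODE solves needed);
* the transport parameters ``beta_sl``, ``beta_ll`` and ``H_Lf`` from bulk
  release curves, by bounded nonlinear least squares wrapped around the
  forward simulator.

The transport parameters span several orders of magnitude, so the release
fit works in log10-parameter space with a seeded Latin-hypercube multi-start.
``beta_sl`` is weakly identifiable by construction: the solid/adsorbed
exchange it governs equilibrates orders of magnitude faster than either the
swelling or the liquid-liquid transfer, so release curves carry almost no
information about it.  ``fit_release`` therefore defaults to freeing only
``beta_ll`` and ``H_Lf``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from lfrelease.kinetics import (
    WATER_DENSITY,
    BatchConfig,
    SwellingParams,
    Trajectory,
    simulate_release,
    swelling_closed_form,
)

__all__ = [
    "TimeSeries",
    "FitResult",
    "GoodnessReport",
    "InsufficientDataError",
    "EstimationError",
    "fit_kv",
    "fit_release",
    "cross_validate",
    "sensitivity_profile",
    "TRANSPORT_PARAMETERS",
    "DEFAULT_BOUNDS",
]

#: the three transport parameters of the release model
TRANSPORT_PARAMETERS = ("beta_sl", "beta_ll", "H_Lf")

#: default fit bounds; they bracket the reference values by >= 2 decades
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "beta_sl": (1e-8, 1e6),
    "beta_ll": (1e-8, 1e6),
    "H_Lf": (1e-8, 1.0),
}

_KINDS = ("swelling_weight", "bulk_concentration", "release_fraction")


class InsufficientDataError(ValueError):
    """Too few data points for the requested estimation."""


class EstimationError(RuntimeError):
    """Every optimisation start failed."""


@dataclass(frozen=True)
class TimeSeries:
    """A (time, value, optional SD) measurement table.

    ``t`` is in minutes; ``y`` is grams for swelling weights and mol/cm^3 or
    a dimensionless fraction for release observables (any consistent mass
    unit works for swelling fits, since ``k_v`` is invariant to rescaling the
    weights).  Points are sorted by time on construction, so downstream
    objectives do not depend on input ordering.
    """

    t: np.ndarray
    y: np.ndarray
    sd: np.ndarray | None = None
    kind: str = "release_fraction"
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("t and y must be 1-D arrays of equal length")
        sd = self.sd
        if sd is not None:
            sd = np.asarray(sd, dtype=float)
            if sd.shape != t.shape:
                raise ValueError("sd must match t in length")
            if np.any(sd <= 0):
                raise ValueError("sd must be strictly positive where present")
        if self.kind not in _KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; expected {_KINDS}")
        order = np.argsort(t, kind="stable")
        t, y = t[order], y[order]
        sd = sd[order] if sd is not None else None
        if t.size and t[0] < 0:
            raise ValueError("times must be nonnegative")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be distinct")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "sd", sd)

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class FitResult:
    """Outcome of a bounded least-squares fit."""

    estimates: dict[str, float]
    sse: float
    residuals: np.ndarray = field(repr=False)
    converged: bool
    n_evaluations: int
    bounds_hit: dict[str, bool] = field(default_factory=dict)
    seed: int | None = None
    n_starts_failed: int = 0

    def to_dict(self) -> dict:
        """JSON-serialisable report."""
        return {
            "estimates": dict(self.estimates),
            "sse": float(self.sse),
            "converged": bool(self.converged),
            "n_evaluations": int(self.n_evaluations),
            "bounds_hit": dict(self.bounds_hit),
            "seed": self.seed,
            "n_starts_failed": int(self.n_starts_failed),
        }


@dataclass(frozen=True)
class GoodnessReport:
    """Goodness-of-fit of fixed parameters against an independent series."""

    sse: float
    rmse: float
    max_abs_residual: float
    n: int


def _weights(series: TimeSeries, weighted: bool) -> np.ndarray | None:
    if not weighted:
        return None
    if series.sd is None:
        raise ValueError("weighted fit requested but the series carries no sd")
    return 1.0 / series.sd


def fit_kv(
    series: TimeSeries,
    dry_mass: float,
    v_max_policy: str = "fixed_from_plateau",
    v_max: float | None = None,
    weighted: bool = False,
) -> FitResult:
    """Estimate the swelling constant ``k_v`` (1/min) from weight data.

    Weights are converted to adsorbed volume, ``V_ads(t_i) = (W(t_i) -
    W(0)) / rho_water``, and the analytic swelling curve is fitted by
    bounded least squares.  ``v_max_policy``:

    ``fixed_from_plateau``
        ``V_max = (max W - W(0)) / rho_water`` (the swelling plateau); only
        ``k_v`` is free.  Default, reflecting that the plateau is observed.
    ``fixed_value``
        ``V_max`` supplied via ``v_max``; only ``k_v`` is free.
    ``co_fit``
        ``k_v`` and ``V_max`` fitted jointly.
    """
    if series.kind != "swelling_weight":
        raise ValueError(f"expected a swelling_weight series, got {series.kind!r}")
    if not dry_mass > 0:
        raise ValueError(f"dry_mass must be > 0, got {dry_mass}")
    if len(series) < 3:
        raise InsufficientDataError(
            f"need >= 3 time points to fit k_v, got {len(series)}"
        )
    if series.t[0] != 0:
        raise InsufficientDataError("the series must include a t = 0 point")

    W = series.y
    drops = np.diff(W)
    if series.sd is not None:
        tol = 3.0 * series.sd[1:]
    else:
        tol = np.zeros_like(drops)
    if np.any(drops < -tol):
        warnings.warn(
            "swelling weights decrease beyond 3 sd between some points; "
            "fitting anyway", stacklevel=2,
        )

    v_obs = (W - W[0]) / WATER_DENSITY
    w = _weights(series, weighted)

    plateau = v_obs.max()
    if plateau <= 0:
        raise ValueError("weights show no uptake; cannot fit a swelling curve")

    def curve(k: float, vmax: float) -> np.ndarray:
        return vmax * (1.0 - np.exp(-k * series.t))

    if v_max_policy == "fixed_from_plateau":
        vmax0, free_vmax = plateau, False
    elif v_max_policy == "fixed_value":
        if v_max is None or not v_max > 0:
            raise ValueError("v_max_policy='fixed_value' requires v_max > 0")
        vmax0, free_vmax = v_max, False
    elif v_max_policy == "co_fit":
        vmax0, free_vmax = plateau, True
    else:
        raise ValueError(f"unknown v_max_policy {v_max_policy!r}")

    def residuals(x: np.ndarray) -> np.ndarray:
        vmax = x[1] if free_vmax else vmax0
        r = curve(x[0], vmax) - v_obs
        return r * w if w is not None else r

    # crude rate scale from the first point past half the plateau
    above = series.t[1:][v_obs[1:] >= 0.5 * plateau]
    k0 = np.log(2.0) / above[0] if above.size else 1.0 / series.t[-1]
    if free_vmax:
        x0, lo, hi = [k0, vmax0], [1e-8, 1e-12], [1e2, 1e6]
    else:
        x0, lo, hi = [k0], [1e-8], [1e2]

    res = least_squares(residuals, x0, bounds=(lo, hi),
                        ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=500)
    estimates = {"k_v": float(res.x[0]),
                 "V_max": float(res.x[1]) if free_vmax else float(vmax0)}
    return FitResult(
        estimates=estimates,
        sse=float(2.0 * res.cost),
        residuals=res.fun,
        converged=bool(res.success),
        n_evaluations=int(res.nfev),
        bounds_hit={"k_v": bool(res.x[0] <= lo[0] * 1.01 or res.x[0] >= hi[0] * 0.99)},
        seed=None,
    )


def _observable(traj: Trajectory, kind: str) -> np.ndarray:
    if kind == "bulk_concentration":
        return traj.C_b
    if kind == "release_fraction":
        return traj.release_fraction
    raise ValueError(f"cannot predict observable of kind {kind!r}")


def _predict(config: BatchConfig, series: TimeSeries, rtol: float) -> np.ndarray:
    t = series.t
    if t[0] != 0:
        grid = np.concatenate([[0.0], t])
        traj = simulate_release(config, grid, rtol=rtol)
        return _observable(traj, series.kind)[1:]
    traj = simulate_release(config, t, rtol=rtol)
    return _observable(traj, series.kind)


def fit_release(
    series: TimeSeries,
    config: BatchConfig,
    free: Sequence[str] = ("beta_ll", "H_Lf"),
    n_starts: int = 8,
    seed: int = 0,
    rtol: float = 1e-9,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    weighted: bool = False,
) -> FitResult:
    """Fit transport parameters of the release model to a measured curve.

    Bounded least squares in log10-parameter space, multi-started from a
    seeded Latin hypercube of ``n_starts`` points over the bounds; the best
    start wins.  Starts whose forward simulation fails are discarded with a
    warning.  ``free`` is a subset of ``("beta_sl", "beta_ll", "H_Lf")``; an
    empty ``free`` evaluates the forward model at the configured values
    without optimisation.  The returned estimates always carry all three
    transport parameters (fixed ones echoed from ``config``) so they can be
    applied to other batches directly.
    """
    free = tuple(free)
    for name in free:
        if name not in TRANSPORT_PARAMETERS:
            raise ValueError(
                f"unknown free parameter {name!r}; expected a subset of "
                f"{TRANSPORT_PARAMETERS}"
            )
    if series.kind == "swelling_weight":
        raise ValueError("fit_release expects a release observable series")
    w = _weights(series, weighted)

    def full_estimates(values: Mapping[str, float]) -> dict[str, float]:
        out = {p: float(getattr(config, p)) for p in TRANSPORT_PARAMETERS}
        out.update({k: float(v) for k, v in values.items()})
        return out

    if not free:
        pred = _predict(config, series, rtol)
        r = pred - series.y
        rw = r * w if w is not None else r
        return FitResult(
            estimates=full_estimates({}), sse=float(np.dot(rw, rw)),
            residuals=r, converged=True, n_evaluations=1, seed=seed,
        )

    if len(series) < 5:
        raise InsufficientDataError(
            f"need >= 5 time points to fit release parameters, got {len(series)}"
        )

    bnds = dict(DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    lo = np.log10([bnds[p][0] for p in free])
    hi = np.log10([bnds[p][1] for p in free])

    def residuals(logp: np.ndarray) -> np.ndarray:
        cfg = config.replace(**{p: 10.0 ** v for p, v in zip(free, logp)})
        r = _predict(cfg, series, rtol) - series.y
        return r * w if w is not None else r

    sampler = qmc.LatinHypercube(d=len(free), seed=seed)
    starts = qmc.scale(sampler.random(n_starts), lo, hi)

    best = None
    n_eval = 0
    n_failed = 0
    for x0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # LSODA grumbles near bounds
                res = least_squares(
                    residuals, x0, bounds=(lo, hi),
                    ftol=1e-12, xtol=1e-12, gtol=1e-12,
                    diff_step=1e-3, max_nfev=500,
                )
        except RuntimeError as exc:
            n_failed += 1
            warnings.warn(f"multi-start point discarded ({exc})", stacklevel=2)
            continue
        n_eval += res.nfev
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise EstimationError(
            f"all {n_starts} optimisation starts failed to simulate"
        )

    est = {p: float(10.0 ** v) for p, v in zip(free, best.x)}
    hit = {
        p: bool(x <= l + 1e-6 or x >= h - 1e-6)
        for p, x, l, h in zip(free, best.x, lo, hi)
    }
    return FitResult(
        estimates=full_estimates(est),
        sse=float(2.0 * best.cost),
        residuals=best.fun,
        converged=bool(best.success),
        n_evaluations=n_eval,
        bounds_hit=hit,
        seed=seed,
        n_starts_failed=n_failed,
    )


def cross_validate(
    fitted: FitResult | Mapping[str, float],
    other_series: TimeSeries,
    other_config: BatchConfig,
    rtol: float = 1e-9,
) -> GoodnessReport:
    """Score transport parameters fitted on one batch against another batch.

    The batch-specific geometry and loading (``W_s``, ``V_b0``, ``n_s0``,
    ...) come from ``other_config``; only the three transport parameters are
    taken from ``fitted``.
    """
    estimates = fitted.estimates if isinstance(fitted, FitResult) else dict(fitted)
    missing = [p for p in TRANSPORT_PARAMETERS if p not in estimates]
    if missing:
        raise ValueError(f"fitted estimates lack transport parameters {missing}")
    if len(other_series) == 0:
        raise InsufficientDataError("cannot validate against an empty series")
    cfg = other_config.replace(
        **{p: float(estimates[p]) for p in TRANSPORT_PARAMETERS}
    )
    r = _predict(cfg, other_series, rtol) - other_series.y
    return GoodnessReport(
        sse=float(np.dot(r, r)),
        rmse=float(np.sqrt(np.mean(r * r))),
        max_abs_residual=float(np.max(np.abs(r))),
        n=len(other_series),
    )


def sensitivity_profile(
    config: BatchConfig,
    parameter: str,
    factors: Iterable[float],
    t_grid: Sequence[float] | None = None,
    rtol: float = 1e-11,
) -> dict[float, float]:
    """SSE of perturbed forward simulations against the configured reference.

    Multiplies ``parameter`` by each factor, re-simulates, and sums squared
    deviations of the release fraction from the reference trajectory.  A
    tight integration tolerance is used so that genuinely insensitive
    parameters (``beta_sl``) report an SSE governed by the model, not by
    integrator noise.
    """
    if not hasattr(config, parameter) or parameter in (
        "stirred", "label", "t_dissolve",
    ):
        raise ValueError(f"unknown or non-numeric parameter {parameter!r}")
    factors = [float(f) for f in factors]
    if any(f <= 0 for f in factors):
        raise ValueError("factors must be strictly positive")
    if t_grid is None:
        t_grid = np.concatenate([[0.0], np.geomspace(0.2, 2880.0, 50)])
    ref = simulate_release(config, t_grid, rtol=rtol).release_fraction
    out: dict[float, float] = {}
    base = getattr(config, parameter)
    for f in factors:
        pert = simulate_release(
            config.replace(**{parameter: base * f}), t_grid, rtol=rtol
        ).release_fraction
        out[f] = float(np.sum((pert - ref) ** 2))
    return out
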