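"""Nonlinear least-squares fitting of the two-population Gompertz model.

Two protocols are implemented:

* **In vitro** (:func:`fit_invitro_well`): both compartments are observed
  per well.  The objective is the unweighted sum of the per-compartment
  mean squared errors ``MSE_S + MSE_R``; the dose is a step function
  (0 before drug onset, 1 after) in drug wells and identically 0
  otherwise; ``lam`` is a free parameter only when drug was applied.
  The fit is anchored at a configurable measured time point whose values
  fix the initial state (optionally the initial state can be freed).

* **In vivo** (:func:`fit_invivo_series`): only the total tumor volume is
  observed.  The total at the first visit is split into sensitive and
  resistant fractions by a grid search over the initial sensitive
  fraction ``p0``; for each grid value, (rho, K, lam) are fitted under
  constant dose ``C == 1`` minimizing the MSE of the predicted total.

Both protocols use a deterministic multi-start local search: starting
points are rows of a seeded Latin-hypercube sample over the bounded
parameter box (rho and K on a log scale), refined with a trust-region
least-squares solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .model_core import (
    GompertzParams,
    PopulationTrajectory,
    TreatmentSchedule,
    simulate,
)

__all__ = [
    "WellRecord",
    "TumorSeries",
    "FitConfig",
    "FitResult",
    "mse_pair",
    "mse_total",
    "fit_invitro_well",
    "fit_invivo_series",
    "filter_min_measurements",
]

# size of the fixed start pool the first n_starts rows are taken from;
# using one pool makes the best objective non-increasing in n_starts
_START_POOL = 16


@dataclass(frozen=True)
class WellRecord:
    """One plate well: condition flags plus the measured two-population series."""

    well_id: str
    drug: bool
    caf: bool
    seeding_proportion: float
    replicate: int
    measured: PopulationTrajectory

    def __post_init__(self) -> None:
        if not 0.0 <= self.seeding_proportion <= 1.0:
            raise ValueError(
                f"seeding_proportion must be in [0, 1], got {self.seeding_proportion}"
            )
        if self.measured.n < 4:
            raise ValueError(
                f"well {self.well_id}: need >= 4 measured time points, have {self.measured.n}"
            )

    @property
    def is_monotypic(self) -> bool:
        return self.seeding_proportion in (0.0, 1.0)


@dataclass(frozen=True)
class TumorSeries:
    """One patient's tumor-volume series (times in days from first visit)."""

    patient_id: str
    times: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "volumes", np.asarray(self.volumes, dtype=float))
        if self.times.shape != self.volumes.shape:
            raise ValueError("times and volumes must have identical shapes")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.volumes <= 0):
            raise ValueError("volumes must be strictly positive")

    @property
    def n(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class FitConfig:
    """Fitting protocol knobs; fully serializable (see cli_io).

    fit_start_index is 0-based: in vitro the fit is anchored at the
    third measured time point by default and earlier points are ignored.
    """

    fit_start_index: int = 2
    drug_onset_time: float = 20.0
    p0_grid: tuple[float, ...] = tuple(np.round(np.linspace(0.0, 1.0, 21), 3))
    rho_bounds: tuple[float, float] = (1e-4, 2.0)
    K_upper_factor: float = 1e8
    lam_bounds: tuple[float, float] = (0.0, 10.0)
    n_starts: int = 5
    seed: int = 0
    free_initial_state: bool = False
    xtol: float = 1e-8
    ftol: float = 1e-8
    max_nfev: int = 60  # per-start evaluation budget; ridge crawls stop early


@dataclass
class FitResult:
    """Outcome of one model fit.

    ``params`` is a :class:`GompertzParams` for the polymorphic model or a
    plain name->value mapping for the comparator growth laws.
    ``initial_state`` records the state actually used: (S0, R0) for the
    polymorphic model, (V0,) for one-dimensional comparators.
    """

    params: GompertzParams | dict
    initial_state: tuple[float, ...]
    objective: float
    per_point_residuals: np.ndarray
    converged: bool
    n_starts_used: int
    p0: float | None = None
    model_id: str = "polymorphic_gompertz"
    diagnostics: dict = field(default_factory=dict)


def _check_grids(t_a: np.ndarray, t_b: np.ndarray) -> None:
    if t_a.shape != t_b.shape or not np.allclose(t_a, t_b, rtol=0, atol=1e-9):
        raise ValueError("time grids of prediction and measurement do not match")


def mse_pair(pred: PopulationTrajectory, mes: PopulationTrajectory) -> tuple[float, float]:
    """Per-compartment mean squared errors (MSE_S, MSE_R) on a shared grid."""
    _check_grids(pred.times, mes.times)
    mse_s = float(np.mean((pred.S - mes.S) ** 2))
    mse_r = float(np.mean((pred.R - mes.R) ** 2))
    return mse_s, mse_r


def mse_total(pred: PopulationTrajectory, mes: TumorSeries) -> float:
    """Mean squared error of the predicted total against measured volumes."""
    _check_grids(pred.times, mes.times)
    return float(np.mean((pred.N - mes.volumes) ** 2))


def filter_min_measurements(
    cohort: Iterable[TumorSeries], min_n: int
) -> list[TumorSeries]:
    """Keep series with at least `min_n` time points, preserving order."""
    if min_n < 1:
        raise ValueError(f"min_n must be >= 1, got {min_n}")
    return [s for s in cohort if s.n >= min_n]


def _lhs_starts(lo: np.ndarray, hi: np.ndarray, n: int, seed: int) -> np.ndarray:
    """First `n` rows of a seeded Latin-hypercube sample over [lo, hi]."""
    sampler = qmc.LatinHypercube(d=lo.size, seed=seed)
    unit = sampler.random(max(_START_POOL, n))[:n]
    return lo + unit * (hi - lo)


def _multistart_least_squares(residual_fn, lo, hi, config: FitConfig):
    """Run seeded multi-start bounded least squares; return (z_best, cost, ok, n)."""
    starts = _lhs_starts(np.asarray(lo, float), np.asarray(hi, float), config.n_starts, config.seed)
    best_z, best_cost, any_ok = None, np.inf, False
    for z0 in starts:
        try:
            res = least_squares(
                residual_fn,
                z0,
                bounds=(lo, hi),
                method="trf",
                xtol=config.xtol,
                ftol=config.ftol,
                max_nfev=config.max_nfev,
            )
        except Exception:  # solver blow-up on a bad start: try the next one
            continue
        any_ok = any_ok or bool(res.success)
        if res.cost < best_cost:
            best_cost, best_z = res.cost, res.x
    if best_z is None:
        raise RuntimeError("all optimizer starts failed")
    return best_z, best_cost, any_ok, len(starts)


def fit_invitro_well(well: WellRecord, config: FitConfig | None = None) -> FitResult:
    """Fit (rho, K[, lam]) to one well's two-population dynamics.

    The minor population of a monotypic well (seeding proportion 0 or 1)
    is zeroed before fitting — its readout is fluorescent noise — and its
    fitted trajectory is identically zero with zero objective share.
    """
    config = config or FitConfig()
    t = well.measured.times
    i0 = config.fit_start_index
    if t.size - i0 < 2:
        raise ValueError(
            f"well {well.well_id}: need >= 2 time points at/after index {i0}, have {t.size - i0}"
        )

    S = well.measured.S.copy()
    R = well.measured.R.copy()
    if well.seeding_proportion == 1.0:
        R[:] = 0.0
    elif well.seeding_proportion == 0.0:
        S[:] = 0.0
    if np.all(S == 0) and np.all(R == 0):
        raise ValueError(f"well {well.well_id}: all measurements are zero")

    tf, Sf, Rf = t[i0:], S[i0:], R[i0:]
    mes = PopulationTrajectory(tf, Sf, Rf)
    s0, r0 = float(Sf[0]), float(Rf[0])
    if s0 + r0 <= 0:
        raise ValueError(f"well {well.well_id}: zero total at the fit-start point")

    schedule = (
        TreatmentSchedule.step(config.drug_onset_time, 0.0, 1.0)
        if well.drug
        else TreatmentSchedule.no_treatment()
    )
    fit_lam = bool(well.drug)
    max_n = float(np.max(Sf + Rf))
    sqrt_n = np.sqrt(tf.size)

    lo = [np.log10(config.rho_bounds[0]), np.log10(max_n)]
    hi = [np.log10(config.rho_bounds[1]), np.log10(max_n * config.K_upper_factor)]
    if fit_lam:
        lo.append(config.lam_bounds[0])
        hi.append(config.lam_bounds[1])
    free_s = config.free_initial_state and s0 > 0
    free_r = config.free_initial_state and r0 > 0
    if free_s:
        lo.append(np.log10(s0 / 10.0))
        hi.append(np.log10(s0 * 10.0))
    if free_r:
        lo.append(np.log10(r0 / 10.0))
        hi.append(np.log10(r0 * 10.0))

    def unpack(z: np.ndarray) -> tuple[GompertzParams, float, float]:
        rho, K = 10.0 ** z[0], 10.0 ** z[1]
        j = 2
        lam = 0.0
        if fit_lam:
            lam = z[j]
            j += 1
        si, ri = s0, r0
        if free_s:
            si = 10.0 ** z[j]
            j += 1
        if free_r:
            ri = 10.0 ** z[j]
        return GompertzParams(rho, K, lam), si, ri

    def residual(z: np.ndarray) -> np.ndarray:
        params, si, ri = unpack(z)
        traj = simulate(params, schedule, si, ri, tf)
        return np.concatenate([(traj.S - Sf), (traj.R - Rf)]) / sqrt_n

    z_best, _, converged, n_used = _multistart_least_squares(residual, lo, hi, config)
    params, si, ri = unpack(z_best)
    traj = simulate(params, schedule, si, ri, tf)
    mse_s, mse_r = mse_pair(traj, mes)
    return FitResult(
        params=params,
        initial_state=(si, ri),
        objective=mse_s + mse_r,
        per_point_residuals=np.concatenate([traj.S - Sf, traj.R - Rf]),
        converged=converged,
        n_starts_used=n_used,
        diagnostics={
            "mse_S": mse_s,
            "mse_R": mse_r,
            "fit_start_time": float(tf[0]),
            "lam_fitted": fit_lam,
        },
    )


def _fit_invivo_at_p0(
    series: TumorSeries, p0: float, config: FitConfig
) -> tuple[GompertzParams, float, bool, int]:
    t, x = series.times, series.volumes
    n0 = float(x[0])
    s0, r0 = p0 * n0, (1.0 - p0) * n0
    schedule = TreatmentSchedule.constant(1.0)
    max_n = float(np.max(x))
    sqrt_n = np.sqrt(t.size)
    lo = np.array(
        [np.log10(config.rho_bounds[0]), np.log10(max_n), config.lam_bounds[0]]
    )
    hi = np.array(
        [
            np.log10(config.rho_bounds[1]),
            np.log10(max_n * config.K_upper_factor),
            config.lam_bounds[1],
        ]
    )

    def residual(z: np.ndarray) -> np.ndarray:
        params = GompertzParams(10.0 ** z[0], 10.0 ** z[1], z[2])
        traj = simulate(params, schedule, s0, r0, t)
        return (traj.N - x) / sqrt_n

    z, cost, ok, n_used = _multistart_least_squares(residual, lo, hi, config)
    params = GompertzParams(10.0 ** z[0], 10.0 ** z[1], z[2])
    # cost = 0.5 * sum(residual^2) = 0.5 * MSE
    return params, 2.0 * cost, ok, n_used


def fit_invivo_series(series: TumorSeries, config: FitConfig | None = None) -> FitResult:
    """Fit the polymorphic model to a total-volume series.

    The initial total is fixed to the first measured volume; its split
    into sensitive and resistant parts is found by a grid search over the
    initial sensitive fraction p0 (ties broken toward smaller p0).
    """
    config = config or FitConfig()
    if series.n < 2:
        raise ValueError(f"series {series.patient_id}: need >= 2 points, have {series.n}")

    # ties (e.g. the lam -> 0 ridge, where every split fits equally) go to
    # the smaller p0; "tie" is judged against numerical noise on the MSE scale
    tie_tol = 1e-9 * float(np.mean(series.volumes)) ** 2
    best = None
    for p0 in config.p0_grid:
        params, mse, ok, n_used = _fit_invivo_at_p0(series, float(p0), config)
        if best is None or mse < best[1] - tie_tol:
            best = (params, mse, ok, n_used, float(p0))

    params, _, ok, n_used, p0 = best
    n0 = float(series.volumes[0])
    s0, r0 = p0 * n0, (1.0 - p0) * n0
    traj = simulate(params, TreatmentSchedule.constant(1.0), s0, r0, series.times)
    objective = mse_total(traj, series)
    return FitResult(
        params=params,
        initial_state=(s0, r0),
        objective=objective,
        per_point_residuals=traj.N - series.volumes,
        converged=ok,
        n_starts_used=n_used,
        p0=p0,
        diagnostics={"n_grid": len(config.p0_grid)},
    )
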