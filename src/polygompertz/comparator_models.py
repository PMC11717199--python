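"""Classical one-dimensional growth-law baselines.

Two comparator models are provided, the two best-performing classical
growth laws for sparse clinical volume series:

* General Gompertz:        dV/dt = alpha * V * ln(K_c / V) - beta * C(t) * V
* General von Bertalanffy: dV/dt = alpha * V**gamma - beta * V

NOTE: these functional forms are provisional defaults.  The
:class:`ComparatorSpec` abstraction keeps the growth law as data (a
right-hand side plus named, bounded parameters), so replacing a form is a
configuration change, not a code change.

Being one-dimensional and autonomous under constant dose, both laws
produce monotone trajectories between fixed points: they cannot describe
a decline followed by regrowth (the U-shape trend), which is precisely
the qualitative gap the two-population model closes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .fit_engine import FitConfig, FitResult, TumorSeries, _multistart_least_squares
from .model_core import SimulationError, TreatmentSchedule

__all__ = [
    "ComparatorSpec",
    "GENERAL_GOMPERTZ",
    "GENERAL_BERTALANFFY",
    "COMPARATORS",
    "simulate_comparator",
    "fit_comparator",
]


@dataclass(frozen=True)
class ComparatorSpec:
    """A one-dimensional growth law dV/dt = f(V, t; theta, C(t)).

    ``bounds`` are (lo, hi) per parameter; parameters flagged in
    ``scale_by_max`` have both bounds multiplied by the series' largest
    observed volume at fit time (used for capacity-like parameters);
    parameters flagged in ``log_scale`` are searched on a log10 scale.
    """

    model_id: str
    param_names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    log_scale: tuple[bool, ...]
    scale_by_max: tuple[bool, ...]
    rhs: Callable[[float, float, np.ndarray, float], float]
    per_capita_log_rhs: Callable[[float, float, np.ndarray, float], float] | None = None

    def __post_init__(self) -> None:
        k = len(self.param_names)
        if not (len(self.bounds) == len(self.log_scale) == len(self.scale_by_max) == k):
            raise ValueError("parameter metadata lengths do not match param_names")

    def bounds_for(self, max_obs: float) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for (a, b), scaled in zip(self.bounds, self.scale_by_max):
            if scaled:
                a, b = a * max_obs, b * max_obs
            lo.append(a)
            hi.append(b)
        return np.asarray(lo, float), np.asarray(hi, float)


def _gg_rhs(v: float, t: float, theta: np.ndarray, dose: float) -> float:
    alpha, k_c, beta = theta
    return alpha * v * np.log(k_c / v) - beta * dose * v


def _gg_log_rhs(y: float, t: float, theta: np.ndarray, dose: float) -> float:
    alpha, k_c, beta = theta
    return alpha * (np.log(k_c) - y) - beta * dose


def _gvb_rhs(v: float, t: float, theta: np.ndarray, dose: float) -> float:
    alpha, beta, gamma = theta
    return alpha * v**gamma - beta * v


def _gvb_log_rhs(y: float, t: float, theta: np.ndarray, dose: float) -> float:
    alpha, beta, gamma = theta
    # alpha * V**(gamma-1) - beta, overflow-safe for large V when gamma <= 1
    return alpha * np.exp(np.clip((gamma - 1.0) * y, -700.0, 700.0)) - beta


GENERAL_GOMPERTZ = ComparatorSpec(
    model_id="general_gompertz",
    param_names=("alpha", "K_c", "beta"),
    bounds=((1e-4, 2.0), (1.0, 1e8), (0.0, 2.0)),
    log_scale=(True, True, False),
    scale_by_max=(False, True, False),
    rhs=_gg_rhs,
    per_capita_log_rhs=_gg_log_rhs,
)

GENERAL_BERTALANFFY = ComparatorSpec(
    model_id="general_bertalanffy",
    param_names=("alpha", "beta", "gamma"),
    bounds=((1e-4, 5.0), (0.0, 5.0), (0.1, 1.2)),
    log_scale=(True, False, False),
    scale_by_max=(False, False, False),
    rhs=_gvb_rhs,
    per_capita_log_rhs=_gvb_log_rhs,
)

COMPARATORS: dict[str, ComparatorSpec] = {
    s.model_id: s for s in (GENERAL_GOMPERTZ, GENERAL_BERTALANFFY)
}


def simulate_comparator(
    spec: ComparatorSpec,
    theta: Sequence[float],
    v0: float,
    times: Sequence[float],
    schedule: TreatmentSchedule | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Solve the growth law on the requested grid (log-volume coordinates)."""
    if v0 <= 0:
        raise ValueError(f"v0 must be > 0, got {v0}")
    theta = np.asarray(theta, dtype=float)
    if theta.size != len(spec.param_names):
        raise ValueError(
            f"{spec.model_id} expects {len(spec.param_names)} parameters, got {theta.size}"
        )
    schedule = schedule or TreatmentSchedule.constant(1.0)
    t = np.asarray(times, dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    out = np.empty_like(t)
    out[0] = v0
    if t.size == 1:
        return out

    y = np.log(v0)
    for a, b, dose in schedule.segments(t[0], t[-1]):

        if spec.per_capita_log_rhs is not None:

            def fun(tt: float, yy: np.ndarray, _d=dose) -> list[float]:
                return [spec.per_capita_log_rhs(yy[0], tt, theta, _d)]

        else:

            def fun(tt: float, yy: np.ndarray, _d=dose) -> list[float]:
                v = np.exp(yy[0])
                return [spec.rhs(v, tt, theta, _d) / v]

        mask = (t > a) & (t <= b)
        t_eval = np.union1d(t[mask], [b])
        sol = solve_ivp(fun, (a, b), [y], t_eval=t_eval, rtol=rtol, atol=atol, method="LSODA")
        if not sol.success:
            raise SimulationError(
                f"{spec.model_id} integration failed on [{a}, {b}]: {sol.message}"
            )
        idx = np.searchsorted(sol.t, t[mask])
        out[mask] = np.exp(np.clip(sol.y[0, idx], -745.0, 700.0))
        y = sol.y[0, -1]
    return out


def fit_comparator(
    series: TumorSeries,
    spec: ComparatorSpec,
    config: FitConfig | None = None,
    schedule: TreatmentSchedule | None = None,
) -> FitResult:
    """Fit a comparator growth law to a volume series (V0 fixed to the first point)."""
    config = config or FitConfig()
    if series.n < 2:
        raise ValueError(f"series {series.patient_id}: need >= 2 points, have {series.n}")
    schedule = schedule or TreatmentSchedule.constant(1.0)
    t, x = series.times, series.volumes
    v0 = float(x[0])
    sqrt_n = np.sqrt(t.size)

    lo_nat, hi_nat = spec.bounds_for(float(np.max(x)))
    log_mask = np.asarray(spec.log_scale)
    lo = np.where(log_mask, np.log10(np.maximum(lo_nat, 1e-300)), lo_nat)
    hi = np.where(log_mask, np.log10(hi_nat), hi_nat)

    def to_theta(z: np.ndarray) -> np.ndarray:
        return np.where(log_mask, 10.0**z, z)

    def residual(z: np.ndarray) -> np.ndarray:
        pred = simulate_comparator(spec, to_theta(z), v0, t, schedule)
        return (pred - x) / sqrt_n

    z, _, ok, n_used = _multistart_least_squares(residual, lo, hi, config)
    theta = to_theta(z)
    pred = simulate_comparator(spec, theta, v0, t, schedule)
    return FitResult(
        params=dict(zip(spec.param_names, (float(v) for v in theta))),
        initial_state=(v0,),
        objective=float(np.mean((pred - x) ** 2)),
        per_point_residuals=pred - x,
        converged=ok,
        n_starts_used=n_used,
        model_id=spec.model_id,
    )
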