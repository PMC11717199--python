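"""Two-population Gompertzian tumor model: definition and simulation.

The model describes a tumor as a mixture of treatment-sensitive cells
``S(t)`` and treatment-resistant cells ``R(t)`` that share a single
carrying capacity ``K`` and intrinsic growth rate ``rho``::

    dS/dt = rho * ln(K / N) * (1 - lam * C(t)) * S
    dR/dt = rho * ln(K / N) * R,            N = S + R

``C(t)`` is the (piecewise-constant) treatment dose and ``lam`` the
treatment sensitivity of the sensitive compartment.  There is no cost of
resistance: off treatment both compartments grow at the same per-capita
rate, so the composition ``S/N`` is conserved whenever ``C == 0``.  When
``lam * C > 1`` the sensitive compartment declines while ``N < K``.

Integration is carried out in log-population coordinates, which makes
positivity structural; a compartment seeded at exactly zero is dropped
from the state and reported as zero throughout (zero is absorbing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "GompertzParams",
    "TreatmentSchedule",
    "PopulationTrajectory",
    "SimulationError",
    "rhs",
    "simulate",
    "closed_form_total",
]

#: default integrator tolerances (log-space state)
RTOL = 1e-8
ATOL = 1e-10


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails to produce a solution."""


@dataclass(frozen=True)
class GompertzParams:
    """Parameter triple (rho, K, lam) shared by both cell populations.

    Parameters
    ----------
    rho : float
        Intrinsic growth rate, per unit time (> 0).
    K : float
        Carrying capacity in cells or volume units (> 0).
    lam : float
        Treatment sensitivity (>= 0, dimensionless).  Values above 1 are
        meaningful: ``lam * C > 1`` turns sensitive growth into decline
        while the population is below ``K``.
    """

    rho: float
    K: float
    lam: float = 0.0

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise ValueError(f"rho must be > 0, got {self.rho}")
        if not self.K > 0:
            raise ValueError(f"K must be > 0, got {self.K}")
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")


@dataclass(frozen=True)
class TreatmentSchedule:
    """Right-continuous piecewise-constant dose function C(t).

    ``doses[0]`` applies before the first breakpoint; ``doses[i]`` applies
    on ``[breakpoints[i-1], breakpoints[i])``-style intervals, i.e.
    evaluation exactly at a breakpoint returns the *new* dose.
    """

    breakpoints: tuple[float, ...] = ()
    doses: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        if bp.size and np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if len(self.doses) != len(self.breakpoints) + 1:
            raise ValueError(
                f"need {len(self.breakpoints) + 1} doses for "
                f"{len(self.breakpoints)} breakpoints, got {len(self.doses)}"
            )
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be >= 0")

    @classmethod
    def no_treatment(cls) -> "TreatmentSchedule":
        return cls((), (0.0,))

    @classmethod
    def constant(cls, dose: float) -> "TreatmentSchedule":
        return cls((), (float(dose),))

    @classmethod
    def step(cls, onset: float, before: float = 0.0, after: float = 1.0) -> "TreatmentSchedule":
        """Dose switching from `before` to `after` at time `onset`."""
        return cls((float(onset),), (float(before), float(after)))

    def dose_at(self, t: float) -> float:
        idx = int(np.searchsorted(self.breakpoints, t, side="right"))
        return self.doses[idx]

    def segments(self, t0: float, t1: float) -> Iterator[tuple[float, float, float]]:
        """Yield (start, end, dose) for each constant-dose piece of [t0, t1]."""
        inner = [b for b in self.breakpoints if t0 < b < t1]
        edges = [t0, *inner, t1]
        for a, b in zip(edges[:-1], edges[1:]):
            yield a, b, self.dose_at(a)


@dataclass(frozen=True)
class PopulationTrajectory:
    """Sensitive/resistant population sizes on a strictly increasing time grid."""

    times: np.ndarray
    S: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "S", np.asarray(self.S, dtype=float))
        object.__setattr__(self, "R", np.asarray(self.R, dtype=float))
        if not (self.times.shape == self.S.shape == self.R.shape):
            raise ValueError("times, S and R must have identical shapes")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.S < 0) or np.any(self.R < 0):
            raise ValueError("population sizes must be >= 0")

    @property
    def N(self) -> np.ndarray:
        """Total population N = S + R."""
        return self.S + self.R

    @property
    def n(self) -> int:
        return int(self.times.size)


def rhs(
    S: float,
    R: float,
    t: float,
    params: GompertzParams,
    schedule: TreatmentSchedule,
) -> tuple[float, float]:
    """Right-hand side (dS/dt, dR/dt) of the two-population system."""
    N = S + R
    if N <= 0:
        raise ValueError(f"total population must be positive, got N={N}")
    g = params.rho * np.log(params.K / N)
    c = schedule.dose_at(t)
    return (g * (1.0 - params.lam * c) * S, g * R)


def _integrate_segment(
    y0: np.ndarray,
    t_span: tuple[float, float],
    t_req: np.ndarray,
    params: GompertzParams,
    dose: float,
    sensitive_active: bool,
    resistant_active: bool,
    rtol: float,
    atol: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate one constant-dose segment in log coordinates.

    Returns (values at t_req as a (n_active, len(t_req)) array, final state).
    """
    rho, K, lam = params.rho, params.K, params.lam
    kill = 1.0 - lam * dose
    # below ~e^-700 a declining compartment is numerically extinct; its
    # decline is tapered continuously to zero over a band above the float
    # underflow limit so the (linear-in-log) collapse cannot race to -inf
    # or put the solver in a sliding mode, without touching any value a
    # caller can distinguish from zero
    floor, band = -745.0, 45.0

    def _taper(y: float, dy: float) -> float:
        if dy >= 0 or y > floor + band:
            return dy
        return dy * max(0.0, (y - floor) / band)

    if sensitive_active and resistant_active:

        def fun(t: float, y: np.ndarray) -> list[float]:
            g = rho * (np.log(K) - np.logaddexp(y[0], y[1]))
            return [_taper(y[0], g * kill), g]

    elif sensitive_active:

        def fun(t: float, y: np.ndarray) -> list[float]:
            return [_taper(y[0], rho * (np.log(K) - y[0]) * kill)]

    else:

        def fun(t: float, y: np.ndarray) -> list[float]:
            return [_taper(y[0], rho * (np.log(K) - y[0]))]

    t_eval = np.union1d(t_req, [t_span[1]])
    sol = solve_ivp(fun, t_span, y0, t_eval=t_eval, rtol=rtol, atol=atol, method="LSODA")
    if not sol.success:
        raise SimulationError(
            f"ODE integration failed on [{t_span[0]}, {t_span[1]}] "
            f"with params {params}: {sol.message}"
        )
    idx = np.searchsorted(sol.t, t_req)
    return sol.y[:, idx], sol.y[:, -1]


def simulate(
    params: GompertzParams,
    schedule: TreatmentSchedule,
    s0: float,
    r0: float,
    times: Sequence[float],
    rtol: float = RTOL,
    atol: float = ATOL,
) -> PopulationTrajectory:
    """Simulate the two-population system on the requested time grid.

    Integration restarts at every dose breakpoint so the discontinuity is
    honored exactly rather than smeared across an adaptive step.  A
    compartment with initial size exactly 0 stays exactly 0.

    Parameters
    ----------
    params, schedule
        Model parameters and dose function.
    s0, r0 : float
        Initial sensitive/resistant sizes (>= 0, not both zero).
    times : sequence of float
        Strictly increasing output grid; ``times[0]`` is the initial time.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if s0 < 0 or r0 < 0:
        raise ValueError("initial sizes must be >= 0")
    if s0 + r0 <= 0:
        raise ValueError("initial total population must be positive")

    S_out = np.empty_like(t)
    R_out = np.empty_like(t)
    S_out[0], R_out[0] = s0, r0
    if t.size == 1:
        return PopulationTrajectory(t, S_out, R_out)

    s_active, r_active = s0 > 0, r0 > 0
    y = np.log([v for v, a in ((s0, s_active), (r0, r_active)) if a])

    for a, b, dose in schedule.segments(t[0], t[-1]):
        mask = (t > a) & (t <= b)
        vals, y = _integrate_segment(
            y, (a, b), t[mask], params, dose, s_active, r_active, rtol, atol
        )
        row = 0
        if s_active:
            S_out[mask] = np.exp(vals[row])
            row += 1
        else:
            S_out[mask] = 0.0
        if r_active:
            R_out[mask] = np.exp(vals[row])
        else:
            R_out[mask] = 0.0

    return PopulationTrajectory(t, S_out, R_out)


def closed_form_total(n0: float, rho: float, K: float, t) -> np.ndarray | float:
    """Closed-form Gompertz solution for an untreated (or monotypic) total.

    ``N(t) = K * exp(ln(n0 / K) * exp(-rho * t))`` — used throughout the
    test suite as an independent oracle for the numerical integrator.
    """
    if n0 <= 0:
        raise ValueError(f"n0 must be > 0, got {n0}")
    if K <= 0:
        raise ValueError(f"K must be > 0, got {K}")
    if rho <= 0:
        raise ValueError(f"rho must be > 0, got {rho}")
    t = np.asarray(t, dtype=float)
    out = K * np.exp(np.log(n0 / K) * np.exp(-rho * t))
    return out if out.ndim else float(out)
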