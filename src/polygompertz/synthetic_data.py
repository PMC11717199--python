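"""Synthetic in-vitro plates and in-vivo cohorts with stored ground truth.

The generators emulate the statistical structure the analysis assumes:

* :func:`gen_invitro_plate` — a factorial co-culture plate: 8 seeding
  proportions of sensitive cells x 4 conditions (drug +/-, CAF +/-) x 6
  replicates = 192 wells, measured every 4 h out to 120 h, with drug
  added 20 h after seeding.  Each well follows the two-population
  Gompertz model with per-well parameters jittered around condition
  means; the CAF condition halves the mean treatment sensitivity.
  Measurement noise is multiplicative lognormal on counts (variance
  grows with signal, as in fluorescence imaging) and is mean-corrected
  so the expected measured trajectory tracks the latent one.  Monotypic
  wells carry the minor population as exactly zero.

* :func:`gen_invivo_cohort` — sparse volume series: baseline plus
  roughly 6-week visits, 4-12 points per patient (some below the
  6-measurement analysis filter by design), with measurement noise
  applied to the implied sphere *diameter* and cubed back to volume
  (right-skewed volume noise).  Patients are drawn to cover all five
  trend categories; delayed-response series start treatment only after
  the first visit or two, and U-shape series combine a high initial
  sensitive fraction with lam > 1 so sensitive collapse precedes
  resistant regrowth.

* :func:`gen_canonical_series` — small archetypal series (5 per
  category) for exercising the trend classifier directly.

All generators are deterministic given their design seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fit_engine import TumorSeries, WellRecord
from .model_core import GompertzParams, PopulationTrajectory, TreatmentSchedule, simulate
from .trend_classifier import TrendCategory, TrendThresholds, classify_trend

__all__ = [
    "PlateDesign",
    "CohortDesign",
    "volume_from_diameter",
    "diameter_from_volume",
    "gen_invitro_plate",
    "gen_invivo_cohort",
    "gen_canonical_series",
]


def volume_from_diameter(d: float | np.ndarray) -> float | np.ndarray:
    """Sphere volume from the longest lesion diameter: (pi/6) d^3."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("diameter must be >= 0")
    v = np.pi / 6.0 * d**3
    return v if v.ndim else float(v)


def diameter_from_volume(v: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`volume_from_diameter`."""
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("volume must be >= 0")
    d = (6.0 * v / np.pi) ** (1.0 / 3.0)
    return d if d.ndim else float(d)


@dataclass(frozen=True)
class PlateDesign:
    """Factorial in-vitro plate layout and generative parameters.

    Times are hours; populations are cell counts.  ``lam_mean_caf`` /
    ``lam_mean_nocaf`` encode the stromal protection effect (CAF halve
    the mean drug sensitivity).  ``noise_floor`` optionally adds a small
    fluorescent background to the minor population of monotypic wells;
    it is off by default so those wells stay exactly zero.
    """

    seeding_proportions: tuple[float, ...] = (0.0, 0.1, 0.2, 0.4, 0.6, 0.8, 0.9, 1.0)
    drug_levels: tuple[bool, ...] = (False, True)
    caf_levels: tuple[bool, ...] = (False, True)
    replicates: int = 6
    sample_times: tuple[float, ...] = tuple(np.arange(0.0, 121.0, 4.0))
    seed_total: float = 1000.0
    drug_onset: float = 20.0
    noise_sigma: float = 0.05
    rho_mean: float = 0.04  # per hour
    rho_cv: float = 0.10
    K_mean: float = 6000.0  # cells
    K_cv: float = 0.15
    lam_mean_nocaf: float = 1.2
    lam_mean_caf: float = 0.6
    lam_cv: float = 0.15
    noise_floor: float = 0.0
    seed: int = 0

    @property
    def n_wells(self) -> int:
        return (
            len(self.seeding_proportions)
            * len(self.drug_levels)
            * len(self.caf_levels)
            * self.replicates
        )


def _lognormal_around(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Draw from a lognormal with the requested mean and coefficient of variation."""
    if cv <= 0:
        return mean
    sigma = np.sqrt(np.log1p(cv**2))
    return float(rng.lognormal(np.log(mean) - 0.5 * sigma**2, sigma))


def _mult_noise(rng: np.random.Generator, values: np.ndarray, sigma: float) -> np.ndarray:
    """Mean-one multiplicative lognormal noise; zeros stay exactly zero."""
    if sigma <= 0:
        return values.copy()
    factors = np.exp(sigma * rng.standard_normal(values.shape) - 0.5 * sigma**2)
    return np.where(values > 0, values * factors, 0.0)


def gen_invitro_plate(
    design: PlateDesign | None = None,
) -> tuple[list[WellRecord], pd.DataFrame]:
    """Generate one plate; returns (wells, ground-truth table keyed by well_id)."""
    design = design or PlateDesign()
    for p in design.seeding_proportions:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"seeding proportion outside [0, 1]: {p}")
    rng = np.random.default_rng(design.seed)
    times = np.asarray(design.sample_times, dtype=float)

    wells: list[WellRecord] = []
    truth_rows: list[dict] = []
    combos = itertools.product(
        design.seeding_proportions, design.drug_levels, design.caf_levels
    )
    idx = 0
    for p, drug, caf in combos:
        for rep in range(design.replicates):
            rho = _lognormal_around(rng, design.rho_mean, design.rho_cv)
            K = _lognormal_around(rng, design.K_mean, design.K_cv)
            lam_mean = design.lam_mean_caf if caf else design.lam_mean_nocaf
            lam = _lognormal_around(rng, lam_mean, design.lam_cv) if drug else 0.0
            s0 = p * design.seed_total
            r0 = (1.0 - p) * design.seed_total
            schedule = (
                TreatmentSchedule.step(design.drug_onset, 0.0, 1.0)
                if drug
                else TreatmentSchedule.no_treatment()
            )
            params = GompertzParams(rho, K, lam)
            latent = simulate(params, schedule, s0, r0, times)
            S_mes = _mult_noise(rng, latent.S, design.noise_sigma)
            R_mes = _mult_noise(rng, latent.R, design.noise_sigma)
            if design.noise_floor > 0:
                floor = design.noise_floor
                if s0 == 0:
                    S_mes = floor * rng.random(times.size)
                if r0 == 0:
                    R_mes = floor * rng.random(times.size)
            well_id = f"w{idx:03d}"
            idx += 1
            wells.append(
                WellRecord(
                    well_id=well_id,
                    drug=drug,
                    caf=caf,
                    seeding_proportion=float(p),
                    replicate=rep,
                    measured=PopulationTrajectory(times, S_mes, R_mes),
                )
            )
            truth_rows.append(
                {
                    "well_id": well_id,
                    "drug": drug,
                    "caf": caf,
                    "seeding_proportion": float(p),
                    "replicate": rep,
                    "rho": rho,
                    "K": K,
                    "lam": lam,
                    "s0": s0,
                    "r0": r0,
                }
            )
    return wells, pd.DataFrame(truth_rows).set_index("well_id")


@dataclass(frozen=True)
class CohortDesign:
    """In-vivo cohort layout and generative parameter ranges.

    Times are days; volumes are mm^3 (sphere volumes from lesion
    diameters in mm).  Patients cycle through the five trend categories.
    Category-specific draws follow the mechanism that produces each
    shape: Growth is resistant-dominated (p0 near 0), Decline
    sensitive-dominated with lam > 1, U-shape mixes a high p0 with
    lam > 1, DelayedResponse additionally starts treatment only after
    ``delay_visits`` visits, and Fluctuate sits near carrying capacity
    with larger measurement noise.
    """

    n_patients: int = 100
    visit_interval: float = 42.0
    visit_jitter: float = 7.0
    n_points_range: tuple[int, int] = (4, 12)
    baseline_diameter_range: tuple[float, float] = (20.0, 60.0)  # mm
    rho_range: tuple[float, float] = (0.003, 0.010)  # per day
    K_factor_range: tuple[float, float] = (3.0, 30.0)  # K as multiple of V0
    lam_range: tuple[float, float] = (1.5, 3.0)
    diameter_noise_sigma: float = 0.02
    fluctuate_noise_sigma: float = 0.08
    delay_visits: tuple[int, int] = (1, 2)
    min_diameter: float = 5.0  # mm; detection floor of lesion measurement
    max_attempts: int = 40
    seed: int = 0


_CATEGORY_CYCLE = (
    TrendCategory.GROWTH,
    TrendCategory.DECLINE,
    TrendCategory.DELAYED_RESPONSE,
    TrendCategory.U_SHAPE,
    TrendCategory.FLUCTUATE,
)


def _draw_patient(
    rng: np.random.Generator, design: CohortDesign, category: TrendCategory
) -> tuple[np.ndarray, np.ndarray, dict]:
    """One attempt at a patient of the intended category; returns
    (times, noisy volumes, truth record)."""
    n_pts = int(rng.integers(design.n_points_range[0], design.n_points_range[1] + 1))
    gaps = design.visit_interval + rng.uniform(
        -design.visit_jitter, design.visit_jitter, size=n_pts - 1
    )
    times = np.concatenate([[0.0], np.cumsum(gaps)])

    d0 = rng.uniform(*design.baseline_diameter_range)
    v0 = volume_from_diameter(d0)
    rho = rng.uniform(*design.rho_range)
    k_factor = rng.uniform(*design.K_factor_range)
    lam = rng.uniform(*design.lam_range)
    sigma = design.diameter_noise_sigma
    t_on = 0.0

    if category is TrendCategory.GROWTH:
        p0 = rng.uniform(0.0, 0.1)
    elif category is TrendCategory.DECLINE:
        # a monotone decline that never relapses implies a fully sensitive
        # tumor: any resistant remnant would regrow on this timescale
        p0 = 1.0
    elif category is TrendCategory.U_SHAPE:
        p0 = rng.uniform(0.7, 0.95)
        rho = rng.uniform(0.006, 0.015)
    elif category is TrendCategory.DELAYED_RESPONSE:
        p0 = 1.0
        n_delay = int(rng.integers(design.delay_visits[0], design.delay_visits[1] + 1))
        t_on = float(times[min(n_delay, n_pts - 1)])
    else:  # Fluctuate: sit near K, let noise dominate
        p0 = rng.uniform(0.3, 0.7)
        k_factor = rng.uniform(1.0, 1.1)
        lam = rng.uniform(0.8, 1.2)
        sigma = design.fluctuate_noise_sigma

    params = GompertzParams(rho, k_factor * v0, lam)
    schedule = (
        TreatmentSchedule.step(t_on, 0.0, 1.0) if t_on > 0 else TreatmentSchedule.constant(1.0)
    )
    latent = simulate(params, schedule, p0 * v0, (1.0 - p0) * v0, times)
    # lesions below the detection floor are reported at the floor
    d_latent = np.maximum(diameter_from_volume(latent.N), design.min_diameter)
    d_noisy = _mult_noise(rng, d_latent, sigma)
    volumes = volume_from_diameter(d_noisy)
    truth = {
        "category": str(category),
        "rho": rho,
        "K": params.K,
        "lam": lam,
        "p0": p0,
        "v0": v0,
        "treatment_start": t_on,
        "n_points": n_pts,
    }
    return times, volumes, truth


def gen_invivo_cohort(
    design: CohortDesign | None = None,
    thresholds: TrendThresholds | None = None,
) -> tuple[list[TumorSeries], pd.DataFrame]:
    """Generate a cohort; returns (series list, truth table keyed by patient_id).

    Each patient is redrawn (bounded retries) until the noisy series
    classifies as the intended category; if no attempt succeeds the last
    draw is kept (the truth table always records the intended category
    and whether it was realized).
    """
    design = design or CohortDesign()
    thresholds = thresholds or TrendThresholds()
    root = np.random.SeedSequence(design.seed)
    cohort: list[TumorSeries] = []
    rows: list[dict] = []
    for i, child in enumerate(root.spawn(design.n_patients)):
        rng = np.random.default_rng(child)
        category = _CATEGORY_CYCLE[i % len(_CATEGORY_CYCLE)]
        times = volumes = truth = None
        realized = False
        for _ in range(design.max_attempts):
            times, volumes, truth = _draw_patient(rng, design, category)
            if np.any(volumes <= 0):
                continue
            if classify_trend(volumes, thresholds) is category:
                realized = True
                break
        pid = f"pt{i:03d}"
        cohort.append(TumorSeries(patient_id=pid, times=times, volumes=volumes))
        rows.append({"patient_id": pid, "realized": realized, **truth})
    return cohort, pd.DataFrame(rows).set_index("patient_id")


# archetypal shapes per category; each row is scaled and perturbed per variant
_CANONICAL_BASE: dict[TrendCategory, np.ndarray] = {
    TrendCategory.GROWTH: np.array([10.0, 12.0, 15.0, 20.0, 26.0, 33.0, 41.0, 50.0]),
    TrendCategory.DECLINE: np.array([50.0, 41.0, 33.0, 26.0, 20.0, 15.0, 12.0, 10.0]),
    TrendCategory.DELAYED_RESPONSE: np.array([10.0, 13.0, 17.0, 12.0, 8.0, 5.5, 4.0, 3.0]),
    TrendCategory.U_SHAPE: np.array([30.0, 20.0, 12.0, 8.0, 10.0, 15.0, 21.0, 28.0]),
    TrendCategory.FLUCTUATE: np.array([10.0, 14.0, 9.0, 13.0, 8.0, 12.0, 9.0, 13.0]),
}


def gen_canonical_series(
    n_per_category: int = 5,
    noise_sigma: float = 0.0,
    seed: int = 0,
    visit_interval: float = 42.0,
) -> list[tuple[TumorSeries, TrendCategory]]:
    """Archetypal volume series for the classifier (5 variants per category).

    Variants differ by an overall scale and a mild stretch of the shape;
    optional multiplicative lognormal noise is applied to the volumes.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[TumorSeries, TrendCategory]] = []
    i = 0
    for category, base in _CANONICAL_BASE.items():
        for v in range(n_per_category):
            stretch = 1.0 + 0.15 * (v / max(n_per_category - 1, 1))
            x1 = base[0]
            shaped = x1 * (base / x1) ** stretch  # preserves x1, stretches excursions
            scale = float(10.0 ** rng.uniform(2.0, 4.0))  # volumes across decades
            volumes = _mult_noise(rng, shaped * scale, noise_sigma)
            times = visit_interval * np.arange(base.size)
            out.append(
                (
                    TumorSeries(patient_id=f"canon{i:03d}", times=times, volumes=volumes),
                    category,
                )
            )
            i += 1
    return out
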