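"""Evaluation statistics for the fitted models.

Covers the accuracy metrics (MAPE, normalized MSE), the Welch
unequal-variance t-test used to compare fitted treatment sensitivities
between stromal conditions, the per-category matrix of pairwise nMSE
t-tests across models, and the Gompertzian-vs-exponential fit-regime
diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fit_engine import FitResult, TumorSeries, WellRecord
from .model_core import PopulationTrajectory
from .trend_classifier import TrendCategory

__all__ = [
    "WelchResult",
    "mape",
    "nmse",
    "welch_t",
    "compare_lambda_by_caf",
    "nmse_ttest_matrix",
    "classify_fit_regime",
]


@dataclass(frozen=True)
class WelchResult:
    """Welch's unequal-variance t-test: statistic, Welch-Satterthwaite
    (fractional) degrees of freedom, and two-sided p-value."""

    t_statistic: float
    degrees_of_freedom: float
    p_value: float


def mape(pred: Sequence[float], mes: Sequence[float]) -> float:
    """Mean absolute percentage error, in percent.

    Points with a zero measurement are excluded from the average (rather
    than regularized with an epsilon): a structurally absent population
    measured as zero and predicted as zero contributes no error, so an
    all-zero pair returns exactly 0.
    """
    p = np.asarray(pred, dtype=float)
    m = np.asarray(mes, dtype=float)
    if p.shape != m.shape:
        raise ValueError("pred and mes must have equal lengths")
    pos = m > 0
    if not np.any(pos):
        if np.allclose(p, 0.0):
            return 0.0
        raise ValueError("MAPE undefined: all measurements zero but predictions nonzero")
    return float(100.0 * np.mean(np.abs(p[pos] - m[pos]) / m[pos]))


def nmse(fit: FitResult, series: TumorSeries, normalization: str = "mean_squared") -> float:
    """MSE normalized to a per-series scale (comparable across patients).

    ``normalization="mean_squared"`` (default) divides by the squared mean
    measured volume; ``"variance"`` divides by the variance of the
    measured volumes (undefined for constant series, which is why it is
    not the default).
    """
    if fit.per_point_residuals.size != series.n:
        raise ValueError(
            f"fit residuals ({fit.per_point_residuals.size}) do not match "
            f"series length ({series.n})"
        )
    if normalization == "mean_squared":
        denom = float(np.mean(series.volumes)) ** 2
    elif normalization == "variance":
        denom = float(np.var(series.volumes))
    else:
        raise ValueError(f"unknown normalization: {normalization!r}")
    if denom == 0:
        raise ValueError(f"nMSE undefined: zero {normalization} for this series")
    return float(fit.objective / denom)


def welch_t(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Welch's t-test for two independent samples with unequal variances."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError(f"each sample needs >= 2 values, got {na} and {nb}")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both samples have zero variance; Welch test degenerate")
    sa, sb = va / na, vb / nb
    se2 = sa + sb
    t = float((a.mean() - b.mean()) / np.sqrt(se2))
    df = float(se2**2 / (sa**2 / (na - 1) + sb**2 / (nb - 1)))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return WelchResult(t_statistic=t, degrees_of_freedom=df, p_value=p)


def _is_monotypic_fit(well: WellRecord) -> bool:
    return bool(np.all(well.measured.S == 0) or np.all(well.measured.R == 0))


def compare_lambda_by_caf(
    fits: Iterable[tuple[WellRecord, FitResult]],
    exclude_outliers: bool = False,
) -> WelchResult:
    """Welch test of fitted lam, CAF+ vs CAF-, restricted to drug wells.

    With ``exclude_outliers`` the monotypic wells (one population
    identically zero, where lam is structurally unconstrained or the fit
    degenerates) are dropped before testing.  The returned statistic is
    mean(lam | CAF+) - mean(lam | CAF-), so a reduced drug effect under
    CAF shows up as a negative t.
    """
    caf_lams: list[float] = []
    nocaf_lams: list[float] = []
    for well, fit in fits:
        if not well.drug:
            continue
        if exclude_outliers and _is_monotypic_fit(well):
            continue
        lam = fit.params.lam if hasattr(fit.params, "lam") else fit.params["lam"]
        (caf_lams if well.caf else nocaf_lams).append(float(lam))
    if len(caf_lams) < 2 or len(nocaf_lams) < 2:
        raise ValueError(
            f"need >= 2 drug wells per CAF group, got CAF+ {len(caf_lams)}, CAF- {len(nocaf_lams)}"
        )
    return welch_t(caf_lams, nocaf_lams)


def nmse_ttest_matrix(
    fits_by_model: Mapping[str, Mapping[str, FitResult]],
    series_by_id: Mapping[str, TumorSeries],
    categories: Mapping[str, TrendCategory],
    paired: bool = False,
) -> dict[str, pd.DataFrame]:
    """Per-category matrices of pairwise two-sided t-test p-values on nMSE.

    For each trend category and each model pair, the nMSE values of the
    series in that category are compared with a two-sided t-test
    (unpaired Welch by default; ``paired=True`` uses a paired test since
    the same series underlie every model).  Diagonals are 1; categories
    with fewer than 2 series are omitted with a warning.
    """
    models = list(fits_by_model)
    nmse_tbl = pd.DataFrame(
        {
            model: {
                sid: nmse(fit, series_by_id[sid])
                for sid, fit in fits_by_model[model].items()
            }
            for model in models
        }
    )
    out: dict[str, pd.DataFrame] = {}
    cat_of = {sid: str(c) for sid, c in categories.items()}
    for cat in sorted(set(cat_of.values())):
        sids = [s for s in nmse_tbl.index if cat_of.get(s) == cat]
        if len(sids) < 2:
            warnings.warn(f"category {cat}: fewer than 2 series, omitted from matrix")
            continue
        mat = pd.DataFrame(np.ones((len(models), len(models))), index=models, columns=models)
        for i, mi in enumerate(models):
            for mj in models[i + 1 :]:
                x = nmse_tbl.loc[sids, mi].to_numpy()
                y = nmse_tbl.loc[sids, mj].to_numpy()
                if np.allclose(x, y):
                    p = 1.0
                elif paired:
                    p = float(stats.ttest_rel(x, y).pvalue)
                else:
                    p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
                mat.loc[mi, mj] = mat.loc[mj, mi] = p
        out[cat] = mat
    return out


def classify_fit_regime(
    fit: FitResult,
    trajectory: PopulationTrajectory,
    threshold: float = 1e3,
) -> str:
    """Label a fit 'exponential_limit' when the fitted carrying capacity
    dwarfs the population (K / max N above `threshold`), else 'gompertzian'.

    In the limit K >> N the Gompertz factor ln(K/N) is nearly constant,
    so the fitted dynamics degenerate to exponential growth of the
    resistant and exponential decay of the sensitive compartment.
    """
    k = fit.params.K if hasattr(fit.params, "K") else float(fit.params["K_c"])
    max_n = float(np.max(trajectory.N))
    if max_n <= 0:
        raise ValueError("trajectory has no positive totals")
    return "exponential_limit" if k / max_n > threshold else "gompertzian"
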