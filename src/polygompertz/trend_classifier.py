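"""Five-way classification of tumor-volume trends.

Each volume series is assigned exactly one of five categories —
Growth, Decline, DelayedResponse, UShape, Fluctuate — used to stratify
the in-vivo model evaluation.  The rules are deliberately simple: all
magnitude comparisons are relative to the first measured volume ``x1``
through a single threshold ``delta`` (default 0.2, i.e. a change counts
as significant when it exceeds 20% of the baseline), which makes the
classification invariant to rescaling volumes and to shifting times.

Precedence of the rules:

1. Fluctuate  — significant successive differences change sign at least
   ``max_sign_changes`` times;
2. Growth     — never drops significantly below baseline and ends
   significantly above it;
3. Decline    — never rises significantly above baseline and ends
   significantly below it;
4. UShape     — a significant interior minimum followed by significant
   regrowth (relapse);
5. DelayedResponse — a significant maximum preceding the minimum, with a
   significant drop from that maximum by the end;
6. otherwise Fluctuate.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .fit_engine import TumorSeries

__all__ = ["TrendCategory", "TrendThresholds", "classify_trend"]


class TrendCategory(str, Enum):
    GROWTH = "Growth"
    DECLINE = "Decline"
    DELAYED_RESPONSE = "DelayedResponse"
    U_SHAPE = "UShape"
    FLUCTUATE = "Fluctuate"

    def __str__(self) -> str:  # cleaner CSV output
        return self.value


@dataclass(frozen=True)
class TrendThresholds:
    """delta: relative-change significance threshold (fraction of x1);
    max_sign_changes: significant direction changes at which a series is
    called Fluctuate outright."""

    delta: float = 0.2
    max_sign_changes: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise ValueError(f"delta must be in (0, 1), got {self.delta}")
        if self.max_sign_changes < 1:
            raise ValueError("max_sign_changes must be >= 1")


def classify_trend(
    series: TumorSeries | np.ndarray,
    thresholds: TrendThresholds | None = None,
) -> TrendCategory:
    """Assign one trend category to a volume series (needs >= 3 points)."""
    th = thresholds or TrendThresholds()
    x = np.asarray(series.volumes if isinstance(series, TumorSeries) else series, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError(f"need a 1-D series with >= 3 points, got shape {x.shape}")

    x1, xn = x[0], x[-1]
    tol = th.delta * x1

    diffs = np.diff(x)
    signs = np.sign(diffs[np.abs(diffs) >= tol])
    n_changes = int(np.sum(signs[1:] != signs[:-1])) if signs.size > 1 else 0
    if n_changes >= th.max_sign_changes:
        return TrendCategory.FLUCTUATE

    if np.min(x) >= x1 - tol and xn >= x1 + tol:
        return TrendCategory.GROWTH
    if np.max(x) <= x1 + tol and xn <= x1 - tol:
        return TrendCategory.DECLINE

    i_min = int(np.argmin(x))
    x_min = x[i_min]
    if x_min <= x1 - tol and 0 < i_min < x.size - 1 and xn >= x_min * (1.0 + th.delta):
        return TrendCategory.U_SHAPE

    i_max = int(np.argmax(x))
    x_max = x[i_max]
    if x_max >= x1 + tol and i_max < i_min and xn <= x_max * (1.0 - th.delta):
        return TrendCategory.DELAYED_RESPONSE

    return TrendCategory.FLUCTUATE
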