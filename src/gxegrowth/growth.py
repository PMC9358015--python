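"""Logistic parameterization of individual plant growth.

Plant height over time follows an S-shaped curve that rises from 0 at sowing
and saturates at the terminal height K. We use the logistic form

    y(t) = (K + y0) / (1 + (K / y0) * exp(-r t)) - y0

which is anchored so that y(0) = 0 exactly: K is the upper bound (cm), r the
growth rate (per day), and y0 a shape parameter fixed empirically at 50 cm
for every individual. With K fixed to the individual's maximum observed
height, only r is estimated, by least squares on the observed weekly
(day, height) points. The fitted (K, r) pair then serves as a pair of
growth traits for downstream modelling.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .containers import TraitTable

__all__ = [
    "LogisticParams",
    "GrowthSeries",
    "DegenerateSeriesError",
    "logistic_height",
    "fit_growth_rate",
    "weekly_increments",
    "extract_growth_traits",
]


class DegenerateSeriesError(ValueError):
    """Raised when a height series cannot support a curve fit."""


@dataclass(frozen=True)
class LogisticParams:
    """Logistic growth-curve parameters: upper bound K (cm), rate r (1/day),
    shape parameter y0 (cm, default 50)."""

    K: float
    r: float
    y0: float = 50.0

    def __post_init__(self) -> None:
        for name in ("K", "r", "y0"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")


@dataclass
class GrowthSeries:
    """Per-individual (day-from-sowing, height) observations."""

    days: np.ndarray
    heights: np.ndarray
    individual: str = ""
    cultivar: str = ""
    environment: str = ""

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.days.shape != self.heights.shape or self.days.ndim != 1:
            raise ValueError("days and heights must be matching 1-D arrays")
        if (self.days < 0).any():
            raise ValueError("days from sowing must be >= 0")
        if (np.diff(self.days) <= 0).any():
            raise ValueError("days must be strictly increasing")
        if (self.heights < 0).any():
            raise ValueError("heights must be >= 0")

    def __len__(self) -> int:
        return len(self.days)


def logistic_height(t, params: LogisticParams):
    """Height (cm) at ``t`` days from sowing under a logistic growth curve.

    Evaluates ``(K + y0) / (1 + (K / y0) exp(-r t)) - y0`` in the
    algebraically equivalent form ``y0 K (1 - exp(-r t)) / (y0 + K exp(-r t))``
    so that the anchor y(0) = 0 holds exactly in floating point. The curve is
    strictly increasing in t and approaches K from below.
    """
    t = np.asarray(t, dtype=float)
    e = np.exp(-params.r * t)
    out = params.y0 * params.K * (1.0 - e) / (params.y0 + params.K * e)
    return out if out.ndim else float(out)


def _sse(r: float, days: np.ndarray, heights: np.ndarray, K: float, y0: float) -> float:
    e = np.exp(-r * days)
    model = y0 * K * (1.0 - e) / (y0 + K * e)
    d = heights - model
    return float(d @ d)


def fit_growth_rate(
    series: GrowthSeries,
    y0: float = 50.0,
    r_bounds: tuple[float, float] = (1e-6, 2.0),
) -> LogisticParams:
    """Fit the growth rate ``r`` of one individual by least squares.

    K is fixed to the maximum observed height and y0 to the supplied shape
    constant, so the fit is a bounded 1-D least-squares problem in r. A coarse
    log-spaced bracket scan precedes a bounded scalar minimization, making the
    result robust to local flatness at very small or very large rates.

    Raises
    ------
    DegenerateSeriesError
        If fewer than 3 observations are available or all heights are zero.
    """
    if len(series) < 3:
        raise DegenerateSeriesError(
            f"need >= 3 observations to fit, got {len(series)} ({series.individual!r})"
        )
    K = float(series.heights.max())
    if K <= 0:
        raise DegenerateSeriesError(f"all-zero heights for {series.individual!r}")

    lo, hi = r_bounds
    grid = np.geomspace(lo, hi, 160)
    sse_grid = [_sse(r, series.days, series.heights, K, y0) for r in grid]
    i = int(np.argmin(sse_grid))
    blo = grid[max(i - 1, 0)]
    bhi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        _sse,
        bounds=(blo, bhi),
        args=(series.days, series.heights, K, y0),
        method="bounded",
        options={"xatol": 1e-12},
    )
    r_hat = float(np.clip(res.x, lo, hi))
    return LogisticParams(K=K, r=r_hat, y0=y0)


def weekly_increments(series: GrowthSeries) -> list[tuple[int, float]]:
    """Height increments between consecutive observations.

    Each increment is labelled by the week (day // 7) of the later
    observation, so gaps in the record simply span a longer interval.
    """
    if len(series) < 2:
        raise ValueError("need >= 2 observations for increments")
    weeks = (series.days[1:] // 7).astype(int)
    deltas = np.diff(series.heights)
    return list(zip(weeks.tolist(), deltas.tolist()))


def extract_growth_traits(
    all_series: Iterable[GrowthSeries],
    y0: float = 50.0,
) -> dict[str, TraitTable]:
    """Fit every individual and assemble replicate-level K and r trait tables.

    Individuals whose series are degenerate (too few points, all-zero heights)
    are skipped with a warning; replicate averaging downstream then simply
    uses the remaining individuals of each cultivar x environment cell.
    """
    rows_K: list[dict] = []
    rows_r: list[dict] = []
    for s in all_series:
        try:
            params = fit_growth_rate(s, y0=y0)
        except DegenerateSeriesError as exc:
            warnings.warn(f"skipping degenerate series: {exc}", stacklevel=2)
            continue
        base = {"cultivar": s.cultivar, "environment": s.environment, "replicate": s.individual}
        rows_K.append({**base, "value": params.K})
        rows_r.append({**base, "value": params.r})
    if not rows_K:
        raise DegenerateSeriesError("no fittable growth series supplied")
    return {
        "K": TraitTable("K", pd.DataFrame(rows_K)),
        "r": TraitTable("r", pd.DataFrame(rows_r)),
    }
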