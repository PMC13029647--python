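"""Specific growth-rate estimation from cascade cell-count time series.

Rearranging the cascade cell balances gives pointwise estimators from
measured counts: for the upstream (control) reactor

    mu1(t) = D + X1'(t) / X1(t)

and for the downstream (experimental) reactor

    mu2(t) = (X2'(t) - D * X1(t) + D * X2(t)) / X2(t).

Derivatives are taken by second-order finite differences on the (possibly
irregular) sampling grid; the control series is linearly interpolated onto
the experimental sampling times, without extrapolation.  A global
constant-mu2 fit to the closed-form X2 solution is also provided, with a
seeded residual-bootstrap confidence half-width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .cascade import CascadeParams, analytic_X2, linear_growth_X2, REGIME_ATOL

__all__ = [
    "CellCountSeries",
    "Mu2Fit",
    "estimate_mu1",
    "estimate_mu2_pointwise",
    "fit_mu2_constant",
]


@dataclass
class CellCountSeries:
    """Cell counts over time for one reactor.

    times in days (strictly increasing), counts in 10^7 cells/mL,
    ``reactor_id`` one of ``"control"`` or ``"experimental"``.
    """

    times: np.ndarray
    counts: np.ndarray
    reactor_id: str = "control"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.times) != len(self.counts):
            raise ValueError("times and counts must have equal length")
        if len(self.times) < 3:
            raise ValueError("need at least 3 points for derivative estimation")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")
        if self.reactor_id not in ("control", "experimental"):
            raise ValueError(f"unknown reactor_id {self.reactor_id!r}")


def _derivative(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    # np.gradient: second-order central differences on a non-uniform grid,
    # second-order one-sided at the endpoints.
    return np.gradient(values, times, edge_order=2)


def estimate_mu1(series: CellCountSeries, D: float) -> np.ndarray:
    """Pointwise mu1(t) = D + X1'/X1 from a control-reactor count series.

    At chemostat steady state (constant counts) this returns D at every
    interior point.  Raises ``ValueError`` on zero counts.
    """
    if np.any(series.counts == 0):
        raise ValueError("zero cell count: mu1 = D + X'/X is undefined")
    return D + _derivative(series.times, series.counts) / series.counts


def _align_control(
    control: CellCountSeries, experimental: CellCountSeries
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interpolate control counts onto experimental times (overlap only)."""
    lo = max(control.times[0], experimental.times[0])
    hi = min(control.times[-1], experimental.times[-1])
    if lo >= hi:
        raise ValueError("control and experimental series do not overlap in time")
    keep = (experimental.times >= lo) & (experimental.times <= hi)
    t = experimental.times[keep]
    x2 = experimental.counts[keep]
    x1 = np.interp(t, control.times, control.counts)
    return t, x1, x2


def estimate_mu2_pointwise(
    control: CellCountSeries, experimental: CellCountSeries, D: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mu2(t) from paired count series.

    Returns ``(times, mu2)`` on the experimental sampling grid restricted to
    the overlap with the control series.  Zero experimental counts are
    floored at half the smallest positive count, with a warning (the balance
    divides by X2).
    """
    t, x1, x2 = _align_control(control, experimental)
    if len(t) < 3:
        raise ValueError("fewer than 3 overlapping points")
    if np.any(x2 == 0):
        positive = x2[x2 > 0]
        if len(positive) == 0:
            raise ValueError("all experimental counts are zero")
        floor = positive.min() / 2
        warnings.warn(
            f"zero experimental counts floored at {floor:g} (half the smallest "
            "positive count) for the pointwise mu2 estimate",
            stacklevel=2,
        )
        x2 = np.where(x2 == 0, floor, x2)
    dx2 = _derivative(t, x2)
    mu2 = (dx2 - D * x1 + D * x2) / x2
    return t, mu2


@dataclass
class Mu2Fit:
    """Result of the global constant-mu2 fit."""

    mu2: float
    half_width: float  # 1.96 * bootstrap SD; nan when n_boot = 0
    n_points: int
    n_boot: int
    rss: float


def _model_X2(tau: np.ndarray, mu2: float, D: float, X1: float, X2_0: float) -> np.ndarray:
    p = CascadeParams(D=D, mu1=D, mu2=mu2, X1_0=X1, X2_0=X2_0)
    if abs(mu2 - D) <= REGIME_ATOL:
        return linear_growth_X2(tau, p)
    return analytic_X2(tau, p)


def fit_mu2_constant(
    control: CellCountSeries,
    experimental: CellCountSeries,
    D: float,
    n_boot: int = 200,
    seed: int = 0,
    bounds: tuple[float, float] = (-10.0, 5.0),
) -> Mu2Fit:
    """Least-squares fit of a constant mu2 to the observed X2 series.

    The upstream concentration X1 is taken as the mean of the aligned
    control counts (reactor 1 near steady state); X2(0) is the first
    experimental observation; time is measured from that observation.  The
    confidence half-width is 1.96 times the SD of a seeded residual
    bootstrap (``n_boot`` refits; 0 skips the bootstrap).
    """
    t, x1, x2 = _align_control(control, experimental)
    if len(t) < 4:
        raise ValueError("need at least 4 overlapping points for the global fit")
    X1 = float(np.mean(x1))
    X2_0 = float(x2[0])
    tau = t - t[0]

    def fit_once(obs: np.ndarray) -> float:
        res = minimize_scalar(
            lambda m: float(np.sum((_model_X2(tau, m, D, X1, X2_0) - obs) ** 2)),
            bounds=bounds,
            method="bounded",
            options={"xatol": 1e-10},
        )
        if not res.success:
            raise RuntimeError(f"mu2 fit failed to converge: {res.message}")
        return float(res.x)

    mu2_hat = fit_once(x2)
    fitted = _model_X2(tau, mu2_hat, D, X1, X2_0)
    residuals = x2 - fitted
    rss = float(np.sum(residuals**2))

    half_width = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            resampled = fitted + rng.choice(residuals, size=len(residuals), replace=True)
            boots.append(fit_once(resampled))
        half_width = 1.96 * float(np.std(boots, ddof=1))

    return Mu2Fit(
        mu2=mu2_hat,
        half_width=half_width,
        n_points=len(t),
        n_boot=n_boot,
        rss=rss,
    )
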