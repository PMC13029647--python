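"""Two-reactor cascade chemostat model.

A control reactor (reactor 1) is fed fresh medium and its overflow feeds an
experimental reactor (reactor 2) at the same dilution rate D.  Cell balances::

    dX1/dt = X1 * (mu1 - D)
    dX2/dt = D * X1 + mu2 * X2 - D * X2

with X1, X2 cell concentrations (10^7 cells/mL), mu1, mu2 specific growth
rates (day^-1, mu2 may be negative under toxic stress) and D the dilution
rate (day^-1).  At chemostat steady state in reactor 1, mu1 = D and X1 is
constant, in which case X2 has the closed form

    X2(t) = D*X1/(D - mu2) + C * exp((mu2 - D) * t),   C = X2(0) - D*X1/(D - mu2)

valid for mu2 != D; the degenerate mu2 = D case grows linearly with slope
D*X1.  The long-run behaviour of X2 relative to X1 falls into regimes set by
the sign and magnitude of mu2, which is how a sustained cell-count deficit in
the downstream reactor diagnoses net cell death (mu2 < 0).

Units are fixed: time in days, concentrations in 10^7 cells/mL.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "CascadeParams",
    "CascadeTrajectory",
    "RegimeLabel",
    "cascade_rhs",
    "analytic_X2",
    "linear_growth_X2",
    "steady_state_X2",
    "classify_regime",
    "simulate_cascade",
]

#: Absolute tolerance for regime boundaries (mu2 == 0, mu2 == D).
REGIME_ATOL = 1e-12

#: Integrator tolerances; the system is stiff when mu2 << 0.
_RTOL = 1e-8
_ATOL = 1e-10


class RegimeLabel(enum.Enum):
    """Long-run behaviour of X2 relative to the upstream steady level X1."""

    EXPONENTIAL_GROWTH = "exponential_growth"  # mu2 > D: no finite steady state
    STABILIZE_ABOVE_X1 = "stabilize_above_x1"  # 0 < mu2 < D
    EQUAL_X1 = "equal_x1"                      # mu2 = 0: X2 -> X1
    BELOW_X1 = "below_x1"                      # mu2 < 0: net death, X2 < X1
    LINEAR_GROWTH = "linear_growth"            # mu2 = D: X2 grows linearly


@dataclass(frozen=True)
class CascadeParams:
    """Parameter set for the cascade.

    Parameters
    ----------
    D : float
        Dilution rate (day^-1), reciprocal of retention time; must be > 0.
    mu1 : float
        Specific growth rate in reactor 1 (day^-1).
    mu2 : float
        Specific growth rate in reactor 2 (day^-1); may be negative.
    X1_0 : float
        Initial (and, at steady state, constant) cell concentration in
        reactor 1 (10^7 cells/mL).
    X2_0 : float
        Initial cell concentration in reactor 2 (10^7 cells/mL).
    """

    D: float
    mu1: float
    mu2: float
    X1_0: float
    X2_0: float

    def __post_init__(self) -> None:
        if not self.D > 0:
            raise ValueError(f"dilution rate D must be > 0, got {self.D}")
        if self.X1_0 < 0 or self.X2_0 < 0:
            raise ValueError(
                f"initial concentrations must be >= 0, got X1_0={self.X1_0}, X2_0={self.X2_0}"
            )
        for name in ("D", "mu1", "mu2", "X1_0", "X2_0"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class CascadeTrajectory:
    """Time course of both reactors.

    ``floored`` is True when the integrator produced (tiny) negative X2
    values that were clipped to zero.
    """

    times: np.ndarray
    X1: np.ndarray
    X2: np.ndarray
    floored: bool = field(default=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.X1 = np.asarray(self.X1, dtype=float)
        self.X2 = np.asarray(self.X2, dtype=float)
        if not (len(self.times) == len(self.X1) == len(self.X2)):
            raise ValueError("times, X1 and X2 must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.X1 < 0) or np.any(self.X2 < 0):
            raise ValueError("concentrations must be non-negative")


def cascade_rhs(X1: float, X2: float, params: CascadeParams) -> tuple[float, float]:
    """Right-hand side of the cascade cell balances.

    Returns ``(dX1/dt, dX2/dt)`` evaluated at concentrations ``X1``, ``X2``.

    Raises
    ------
    ValueError
        If either concentration is negative.
    """
    if X1 < 0 or X2 < 0:
        raise ValueError(f"concentrations must be >= 0, got X1={X1}, X2={X2}")
    dX1 = X1 * (params.mu1 - params.D)
    dX2 = params.D * X1 + params.mu2 * X2 - params.D * X2
    return dX1, dX2


def _require_nondegenerate(params: CascadeParams) -> None:
    if abs(params.mu2 - params.D) <= REGIME_ATOL:
        raise ValueError(
            "mu2 == D: the closed form is singular; use linear_growth_X2 "
            "(X2 grows linearly with slope D*X1)"
        )


def analytic_X2(tau, params: CascadeParams):
    """Closed-form X2(tau) under reactor-1 steady state (X1 constant).

    ``X2(tau) = D*X1/(D - mu2) + C * exp((mu2 - D) * tau)`` with C fixed by
    the initial condition X2(0) = X2_0.  Accepts scalar or array ``tau``.

    Raises
    ------
    ValueError
        If mu2 == D (within absolute tolerance 1e-12); that degenerate case
        is handled by :func:`linear_growth_X2`.
    """
    _require_nondegenerate(params)
    tau = np.asarray(tau, dtype=float)
    particular = params.D * params.X1_0 / (params.D - params.mu2)
    C = params.X2_0 - particular
    out = particular + C * np.exp((params.mu2 - params.D) * tau)
    return float(out) if out.ndim == 0 else out


def linear_growth_X2(tau, params: CascadeParams):
    """X2(tau) in the degenerate mu2 = D regime: X2_0 + D*X1*tau."""
    tau = np.asarray(tau, dtype=float)
    out = params.X2_0 + params.D * params.X1_0 * tau
    return float(out) if out.ndim == 0 else out


def steady_state_X2(params: CascadeParams) -> float:
    """Steady-state X2 for mu2 < D; ``math.inf`` signals divergence.

    For mu2 < D the exponential term decays and X2 -> D*X1/(D - mu2).
    For mu2 >= D there is no finite steady state (linear or exponential
    growth) and ``math.inf`` is returned as the divergence indicator.
    """
    if params.mu2 >= params.D - REGIME_ATOL:
        return math.inf
    if abs(params.mu2) <= REGIME_ATOL:
        return params.X1_0  # exact: D*X1/D
    return params.D * params.X1_0 / (params.D - params.mu2)


def classify_regime(params: CascadeParams) -> RegimeLabel:
    """Classify the long-run behaviour of X2 from (mu2, D).

    Boundaries are compared with absolute tolerance 1e-12.
    """
    mu2, D = params.mu2, params.D
    if abs(mu2 - D) <= REGIME_ATOL:
        return RegimeLabel.LINEAR_GROWTH
    if mu2 > D:
        return RegimeLabel.EXPONENTIAL_GROWTH
    if abs(mu2) <= REGIME_ATOL:
        return RegimeLabel.EQUAL_X1
    if mu2 > 0:
        return RegimeLabel.STABILIZE_ABOVE_X1
    return RegimeLabel.BELOW_X1


def simulate_cascade(
    params: CascadeParams,
    times,
    steady_reactor1: bool = True,
) -> CascadeTrajectory:
    """Numerically integrate the cascade over the requested time points.

    Parameters
    ----------
    params : CascadeParams
    times : array-like
        Strictly increasing, starting at 0 (days).
    steady_reactor1 : bool, default True
        If True, hold X1 at X1_0 (reactor 1 at chemostat steady state) and
        integrate only the X2 balance.  If False, integrate both balances
        (transient X1 with growth rate mu1).

    Returns
    -------
    CascadeTrajectory
        Solution sampled at ``times``; negative under/overshoot from the
        integrator is clipped at 0 and flagged via ``floored``.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 2:
        raise ValueError("times must be a 1-D array with at least 2 points")
    if times[0] != 0:
        raise ValueError("times must start at 0")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    if steady_reactor1:
        def rhs(t, y):
            return [params.D * params.X1_0 + (params.mu2 - params.D) * y[0]]

        y0 = [params.X2_0]
    else:
        def rhs(t, y):
            return [
                y[0] * (params.mu1 - params.D),
                params.D * y[0] + (params.mu2 - params.D) * y[1],
            ]

        y0 = [params.X1_0, params.X2_0]

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        y0,
        t_eval=times,
        method="LSODA",
        rtol=_RTOL,
        atol=_ATOL,
    )
    if not sol.success:
        raise RuntimeError(
            f"cascade integration failed ({sol.message}); params={params!r}"
        )

    if steady_reactor1:
        X1 = np.full_like(times, params.X1_0)
        X2 = sol.y[0]
    else:
        X1, X2 = sol.y

    floored = bool(np.any(X1 < 0) or np.any(X2 < 0))
    return CascadeTrajectory(
        times=times,
        X1=np.clip(X1, 0.0, None),
        X2=np.clip(X2, 0.0, None),
        floored=floored,
    )
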