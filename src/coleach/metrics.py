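"""Batch-mode process indicators from reactor time series.

Bioleaching batch runs are summarised by a handful of threshold-crossing
times: the day the pulp reaches a reference pH (1.20) as biogenic acid
accumulates, the day the redox potential reaches a reference Eh (800 mV) as
ferrous iron is oxidised away, the day ferrous iron becomes undetectable,
and the duration of the microbial lag phase.  All are computed from sampled
series by linear interpolation between bracketing samples (with an optional
"snap to next sample" mode for integer-day reporting).

The lag phase has no universal operational definition; here it ends when the
cell count first exceeds ``k_fold`` times the initial count (default 2) and
stays above at the next sample.  Ferrous-iron depletion requires the
concentration to stay below the detection limit for the rest of the series
(a transient dip does not count).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReactorTimeSeries",
    "NOT_REACHED",
    "time_to_threshold",
    "fe2_depletion_time",
    "lag_phase_duration",
]

#: Sentinel for a threshold never reached within the series (NaN).
NOT_REACHED = math.nan

#: Tolerated |fe_total - (fe2 + fe3)| before a consistency warning (g/L).
FE_TOTAL_TOL = 0.2


@dataclass
class ReactorTimeSeries:
    """Measured chemistry and cell counts for one reactor over one run.

    times: days, strictly increasing.  pH dimensionless; Eh in mV; iron
    species in g/L; cells in 10^7 cells/mL; ``metals`` maps a metal name
    (e.g. ``"cu"``) to its dissolved concentration series (g/L).  Any field
    but ``times`` may be None (not measured).
    """

    times: np.ndarray
    pH: np.ndarray | None = None
    Eh: np.ndarray | None = None
    fe2: np.ndarray | None = None
    fe3: np.ndarray | None = None
    fe_total: np.ndarray | None = None
    cells: np.ndarray | None = None
    metals: dict[str, np.ndarray] = field(default_factory=dict)
    reactor_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        n = len(self.times)
        for name in ("pH", "Eh", "fe2", "fe3", "fe_total", "cells"):
            v = getattr(self, name)
            if v is None:
                continue
            v = np.asarray(v, dtype=float)
            if len(v) != n:
                raise ValueError(f"{name} length {len(v)} != times length {n}")
            if name not in ("pH", "Eh") and np.any(v < 0):
                raise ValueError(f"{name} must be non-negative")
            setattr(self, name, v)
        self.metals = {k: np.asarray(v, dtype=float) for k, v in self.metals.items()}
        for k, v in self.metals.items():
            if len(v) != n:
                raise ValueError(f"metal {k!r} length {len(v)} != times length {n}")
            if np.any(v < 0):
                raise ValueError(f"metal {k!r} must be non-negative")
        if self.fe2 is not None and self.fe3 is not None and self.fe_total is not None:
            gap = np.max(np.abs(self.fe_total - (self.fe2 + self.fe3)))
            if gap > FE_TOTAL_TOL:
                warnings.warn(
                    f"fe_total deviates from fe2 + fe3 by up to {gap:.3g} g/L "
                    f"(tolerance {FE_TOTAL_TOL} g/L)",
                    stacklevel=2,
                )

    def variable(self, name: str) -> np.ndarray:
        """Series for ``name`` (field name or metal key); error if absent."""
        if name in self.metals:
            return self.metals[name]
        v = getattr(self, name, None)
        if v is None:
            raise ValueError(f"variable {name!r} absent from series")
        return v


def _interp_crossing(t0, t1, v0, v1, threshold) -> float:
    if v1 == v0:
        return t0
    return t0 + (threshold - v0) * (t1 - t0) / (v1 - v0)


def time_to_threshold(
    series: ReactorTimeSeries,
    variable: str,
    threshold: float,
    direction: str,
    snap: bool = False,
) -> float:
    """First time ``variable`` crosses ``threshold`` in the given direction.

    ``direction`` is ``"rising"`` or ``"falling"``.  The crossing time is
    linearly interpolated between the bracketing samples (``snap=True``
    returns the first sample time at or past the threshold instead).  A
    series already at or past the threshold at its first sample returns 0
    days; a series that never crosses returns the ``NOT_REACHED`` sentinel
    (NaN).
    """
    if direction not in ("rising", "falling"):
        raise ValueError(f"direction must be 'rising' or 'falling', got {direction!r}")
    v = series.variable(variable)
    t = series.times
    sign = 1.0 if direction == "rising" else -1.0
    past = sign * (v - threshold) >= 0  # at or beyond threshold
    if past[0]:
        return 0.0
    idx = np.flatnonzero(past)
    if len(idx) == 0:
        return NOT_REACHED
    j = int(idx[0])
    if snap:
        return float(t[j])
    return float(_interp_crossing(t[j - 1], t[j], v[j - 1], v[j], threshold))


def fe2_depletion_time(series: ReactorTimeSeries, lod: float = 0.05) -> float:
    """Time of sustained ferrous-iron depletion.

    Returns the first sample time from which fe2 stays below the detection
    limit ``lod`` (g/L) for the rest of the series — a transient dip below
    the limit followed by a rebound does not count.  An all-depleted series
    returns the first sample time; never-depleted returns ``NOT_REACHED``.
    """
    fe2 = series.variable("fe2")
    below = fe2 < lod
    # last index where fe2 >= lod; sustained depletion starts just after
    above_idx = np.flatnonzero(~below)
    if len(above_idx) == 0:
        return float(series.times[0])
    start = int(above_idx[-1]) + 1
    if start >= len(fe2):
        return NOT_REACHED
    return float(series.times[start])


def lag_phase_duration(series: ReactorTimeSeries, k_fold: float = 2.0) -> float:
    """Lag-phase duration: interpolated time of a sustained k-fold count rise.

    The lag ends at the (interpolated) time the cell count first exceeds
    ``k_fold`` times the initial count, provided it is still above that
    level at the following sample.  Requires a positive initial count.
    Returns ``NOT_REACHED`` if the count never sustains the rise.
    """
    if k_fold <= 1:
        raise ValueError(f"k_fold must be > 1, got {k_fold}")
    cells = series.variable("cells")
    t = series.times
    if cells[0] <= 0:
        raise ValueError("initial cell count must be > 0")
    thr = k_fold * cells[0]
    n = len(cells)
    for j in range(1, n):
        if cells[j] > thr and (j + 1 >= n or cells[j + 1] > thr):
            return float(_interp_crossing(t[j - 1], t[j], cells[j - 1], cells[j], thr))
    return NOT_REACHED
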