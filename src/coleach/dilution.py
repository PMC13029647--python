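"""Material-balance model of solid PCB-dust concentration under stepwise feeding.

At each sampling step a volume ``v_added`` of fresh pulp with dust
concentration ``Yi`` displaces an equal volume of reactor pulp at the current
concentration ``Xi`` (total working volume constant), giving the mixing
recursion::

    X_{i+1} = (Xi * (v_total - v_added) + Yi * v_added) / v_total

The dust is treated as conserved between feed events.  With the reference
feed programme (5 g/L inlet through day 11, 12.5 g/L for steps ending days
14-22, 37.5 g/L from day 25; 400 mL replaced per step in a 1000 mL reactor)
the recursion tracks the in-reactor concentration through the three stages
of a continuous co-leaching run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "FeedStep",
    "DilutionSeries",
    "dilution_step",
    "run_schedule",
    "limit_concentration",
    "reference_schedule",
    "REFERENCE_X0",
    "read_schedule",
    "write_schedule",
]

#: Initial in-reactor dust concentration of the reference programme (g/L).
REFERENCE_X0 = 5.0


@dataclass(frozen=True)
class FeedStep:
    """One feed event: by ``end_day``, ``v_added`` mL of pulp at ``inlet_conc``
    g/L has displaced an equal volume of reactor pulp (``v_total`` mL)."""

    end_day: float
    inlet_conc: float  # Yi, g/L
    v_added: float     # mL
    v_total: float     # mL

    def __post_init__(self) -> None:
        if not 0 < self.v_added <= self.v_total:
            raise ValueError(
                f"need 0 < v_added <= v_total, got v_added={self.v_added}, v_total={self.v_total}"
            )
        if self.inlet_conc < 0:
            raise ValueError(f"inlet concentration must be >= 0, got {self.inlet_conc}")


@dataclass
class DilutionSeries:
    """In-reactor dust concentration (g/L) at the end of each step, with the
    day-0 initial value prepended."""

    days: list[float]
    conc: list[float]

    def at_day(self, day: float) -> float:
        """Concentration at ``day``: exact match, else the most recent step value.

        Raises
        ------
        KeyError
            If ``day`` precedes the first tabulated day.
        """
        if day < self.days[0]:
            raise KeyError(f"day {day} precedes the series start (day {self.days[0]})")
        value = self.conc[0]
        for d, c in zip(self.days, self.conc):
            if d > day:
                break
            value = c
        return value

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.days, "conc_gL": self.conc})


def dilution_step(Xi: float, Yi: float, v_added: float, v_total: float) -> float:
    """One application of the mixing recursion; returns the new concentration.

    Raises ``ValueError`` for v_added > v_total or negative inputs.
    """
    if not 0 < v_added <= v_total:
        raise ValueError(
            f"need 0 < v_added <= v_total, got v_added={v_added}, v_total={v_total}"
        )
    if Xi < 0 or Yi < 0:
        raise ValueError(f"concentrations must be >= 0, got Xi={Xi}, Yi={Yi}")
    return (Xi * (v_total - v_added) + Yi * v_added) / v_total


def run_schedule(X0: float, schedule: list[FeedStep], start_day: float = 0.0) -> DilutionSeries:
    """Iterate the recursion over a feed schedule, carrying full precision.

    The returned series includes the initial value at ``start_day`` followed
    by one entry per step (at its ``end_day``).  Rounding, if wanted, is the
    caller's reporting concern.
    """
    if not schedule:
        raise ValueError("schedule must be non-empty")
    if X0 < 0:
        raise ValueError(f"X0 must be >= 0, got {X0}")
    days = [d.end_day for d in schedule]
    if any(b <= a for a, b in zip(days, days[1:])) or days[0] <= start_day:
        raise ValueError("schedule end_days must be strictly increasing after start_day")

    out_days = [start_day]
    out_conc = [X0]
    x = X0
    for step in schedule:
        x = dilution_step(x, step.inlet_conc, step.v_added, step.v_total)
        out_days.append(step.end_day)
        out_conc.append(x)
    return DilutionSeries(days=out_days, conc=out_conc)


def limit_concentration(
    X0: float, Yi: float, f: float, epsilon: float = 0.1
) -> tuple[float, int]:
    """Limit of the recursion under a constant feed, and steps to get there.

    With a fixed replaced-volume fraction ``f = v_added / v_total`` the
    distance to the feed concentration shrinks geometrically,
    ``|X_n - Yi| = |X0 - Yi| * (1 - f)^n``, so the limit is ``Yi`` and the
    number of steps to come within ``epsilon`` of it is
    ``ceil(log(epsilon / |X0 - Yi|) / log(1 - f))``.

    Returns ``(limit, n_steps)``; ``f = 1`` reaches the limit in one step,
    and ``X0`` already within ``epsilon`` needs zero steps.
    """
    if not 0 < f <= 1:
        raise ValueError(f"replaced-volume fraction f must be in (0, 1], got {f}")
    if epsilon <= 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    gap = abs(X0 - Yi)
    if gap <= epsilon:
        return Yi, 0
    if f == 1:
        return Yi, 1
    n = math.ceil(math.log(epsilon / gap) / math.log(1 - f))
    return Yi, n


def reference_schedule(v_added: float = 400.0, v_total: float = 1000.0) -> list[FeedStep]:
    """The three-stage reference feed programme of a continuous run.

    Steps ending days 3-11 feed 5 g/L (concentration holds at the initial
    5 g/L), days 14-22 feed 12.5 g/L, days 25-34 feed 37.5 g/L; each step
    replaces 400 mL of a 1000 mL working volume.  The step *ending* on a
    feed-switch day still carries the previous inlet concentration.
    """
    steps: list[FeedStep] = []
    for day in (3, 5, 7, 9, 11):
        steps.append(FeedStep(day, 5.0, v_added, v_total))
    for day in (14, 16, 18, 20, 22):
        steps.append(FeedStep(day, 12.5, v_added, v_total))
    for day in (25, 27, 29, 31, 34):
        steps.append(FeedStep(day, 37.5, v_added, v_total))
    return steps


_SCHEDULE_COLS = ["end_day", "inlet_conc_g_per_L", "v_added_mL", "v_total_mL"]


def read_schedule(path: str | Path) -> list[FeedStep]:
    """Read a feed schedule from CSV (columns end_day, inlet_conc_g_per_L,
    v_added_mL, v_total_mL)."""
    df = pd.read_csv(path)
    missing = [c for c in _SCHEDULE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"schedule file {path} missing columns: {missing}")
    return [
        FeedStep(row.end_day, row.inlet_conc_g_per_L, row.v_added_mL, row.v_total_mL)
        for row in df.itertuples()
    ]


def write_schedule(schedule: list[FeedStep], path: str | Path) -> None:
    pd.DataFrame(
        [(s.end_day, s.inlet_conc, s.v_added, s.v_total) for s in schedule],
        columns=_SCHEDULE_COLS,
    ).to_csv(path, index=False)
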