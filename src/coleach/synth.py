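"""Seeded synthetic experiments with the statistical structure the analysis assumes.

Two study designs are emulated:

* **Continuous cascade** — a control chemostat at steady state feeding an
  experimental reactor whose specific growth rate depends on the in-reactor
  PCB dust concentration through a piecewise-linear toxicity response::

      mu2(x) = mu_base * max(0, 1 - x/X_tox) - delta * max(0, x - X_tox) / X_tox

  benign below the toxicity threshold ``X_tox``, increasingly negative (net
  cell death) above it.  The dust concentration follows the material-balance
  feed recursion; between feed events mu2 is constant, so the experimental
  cell trajectory is assembled exactly from the per-segment closed form.
  Cell counts carry multiplicative lognormal noise (mean-one), chemistry
  carries truncated Gaussian noise, and a genus abundance table responds
  logistically to exposure.

* **Batch run** — delayed-logistic cell growth with a programmed lag, pH
  declining after the lag, Eh rising sigmoidally through a programmed
  crossing day, ferrous iron declining to zero at a programmed depletion
  day, and total iron enforced as fe2 + fe3.  Shapes are phenomenological
  templates for testing the series metrics, not mechanistic chemistry.

Every generator draws from a single ``numpy`` Generator seeded from the
scenario, so a fixed seed gives byte-identical outputs.  Values below the
ferrous detection limit are recorded as zero, as a titrimetric assay would
report them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cascade import CascadeParams, analytic_X2, linear_growth_X2, REGIME_ATOL
from .community import AbundanceTable
from .dilution import DilutionSeries, FeedStep, reference_schedule, run_schedule
from .growth import CellCountSeries
from .metrics import ReactorTimeSeries

__all__ = [
    "GenusResponse",
    "SyntheticScenario",
    "CascadeBundle",
    "mu2_of_exposure",
    "generate_continuous_cascade",
    "generate_constant_mu2_pair",
    "generate_batch_run",
]


@dataclass(frozen=True)
class GenusResponse:
    """Logistic abundance response of one genus to dust exposure.

    ``weight`` is the unnormalised abundance weight at full response;
    ``direction`` is +1 (favoured by exposure) or -1 (suppressed);
    ``midpoint`` (g/L) and ``width`` (g/L) set where and how sharply the
    response turns.
    """

    weight: float
    direction: int
    midpoint: float = 15.0
    width: float = 5.0

    def raw_weight(self, exposure: float) -> float:
        z = self.direction * (exposure - self.midpoint) / self.width
        return self.weight / (1.0 + math.exp(-z))


def _default_community() -> dict[str, GenusResponse]:
    # Iron oxidisers tolerant of the dust grow in; mixotrophic detoxifiers
    # (Ferroplasma, Sulfobacillus) are suppressed by it.
    return {
        "Leptospirillum": GenusResponse(weight=55.0, direction=+1),
        "Acidithiobacillus": GenusResponse(weight=25.0, direction=+1),
        "Ferroplasma": GenusResponse(weight=30.0, direction=-1),
        "Sulfobacillus": GenusResponse(weight=8.0, direction=-1),
    }


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameter set of a synthetic experiment (defaults = study conditions).

    Continuous cascade: dilution rate D = 0.2 day^-1 (5-day retention),
    control reactor steady at 200e7 cells/mL, three-stage feed programme
    (5 -> 12.5 -> 37.5 g/L inlet, 400/1000 mL per step), sampling every
    2-3 days over 34 days, 10% CV lognormal count noise.  Toxicity:
    mu_base = 0.1 day^-1, threshold X_tox = 15 g/L, death slope delta = 0.8
    day^-1 per threshold unit (mu2 ~ -1.1 day^-1 at 35.5 g/L).

    Batch: inoculum 1.5e7 cells/mL growing logistically (rate 0.6 day^-1)
    to a 150e7 cells/mL plateau after a 12-day lag; pH 1.6 declining after
    the lag to cross 1.2 on day 20; Eh rising 620 -> 880 mV through 800 mV
    on day 15; ferrous iron 0.7 g/L depleting by day 12.
    """

    seed: int = 0
    # --- continuous cascade ---
    D: float = 0.2
    X1_steady: float = 200.0
    X2_0: float = 200.0
    mu_base: float = 0.1
    X_tox: float = 15.0
    delta: float = 0.8
    feed_X0: float = 5.0
    schedule: tuple[FeedStep, ...] = field(
        default_factory=lambda: tuple(reference_schedule())
    )
    sampling_days: tuple[float, ...] = (
        0, 3, 5, 7, 9, 11, 14, 16, 18, 20, 22, 25, 27, 29, 31, 34,
    )
    count_noise_cv: float = 0.10
    chem_noise_sd: tuple[tuple[str, float], ...] = (
        ("pH", 0.02), ("Eh", 5.0), ("fe", 0.02),
    )
    abundance_days: tuple[float, ...] = (11, 22, 34)
    abundance_noise_cv: float = 0.10
    community: tuple[tuple[str, GenusResponse], ...] = field(
        default_factory=lambda: tuple(_default_community().items())
    )
    other_weight: float = 5.0
    # --- batch run ---
    lag_days: float = 12.0
    growth_rate: float = 0.6
    carrying_capacity: float = 150.0
    initial_cells: float = 1.5
    ph_initial: float = 1.6
    ph_reference: float = 1.2
    ph_cross_day: float = 20.0
    ph_floor: float = 1.0
    eh_initial: float = 620.0
    eh_final: float = 880.0
    eh_reference: float = 800.0
    eh_cross_day: float = 15.0
    eh_steepness: float = 0.8
    fe2_initial: float = 0.7
    fe2_depletion_day: float = 12.0
    fe2_decline_days: float = 4.0
    fe3_initial: float = 5.0
    fe3_final: float = 10.0
    fe_lod: float = 0.05
    batch_horizon: float = 29.0
    batch_interval: float = 2.0

    def __post_init__(self) -> None:
        if self.count_noise_cv < 0 or self.abundance_noise_cv < 0:
            raise ValueError("noise CVs must be >= 0")
        if self.X_tox <= 0 or self.D <= 0:
            raise ValueError("X_tox and D must be > 0")
        for name in ("mu_base", "delta", "growth_rate", "lag_days"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.ph_cross_day <= self.lag_days:
            raise ValueError("ph_cross_day must exceed lag_days (acid onset)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    @property
    def chem_sd(self) -> dict[str, float]:
        return dict(self.chem_noise_sd)


def mu2_of_exposure(x: float, scenario: SyntheticScenario) -> float:
    """Piecewise-linear toxicity response mu2(x), day^-1."""
    growth = scenario.mu_base * max(0.0, 1.0 - x / scenario.X_tox)
    death = scenario.delta * max(0.0, x - scenario.X_tox) / scenario.X_tox
    return growth - death


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


def _x2_exact(scenario: SyntheticScenario, dilution: DilutionSeries) -> np.ndarray:
    """Noise-free X2 at the sampling days, assembled segment by segment.

    The dust concentration (hence mu2) is constant between feed events, so
    on each segment the closed-form solution applies with the segment's
    start value as initial condition.
    """
    days = np.asarray(scenario.sampling_days, dtype=float)
    knots = sorted(set(dilution.days) | set(days))
    x2_at = {knots[0]: scenario.X2_0}
    x2 = scenario.X2_0
    for t0, t1 in zip(knots, knots[1:]):
        mu2 = mu2_of_exposure(dilution.at_day(t0), scenario)
        p = CascadeParams(
            D=scenario.D, mu1=scenario.D, mu2=mu2,
            X1_0=scenario.X1_steady, X2_0=x2,
        )
        if abs(mu2 - scenario.D) <= REGIME_ATOL:
            x2 = linear_growth_X2(t1 - t0, p)
        else:
            x2 = analytic_X2(t1 - t0, p)
        x2_at[t1] = x2
    return np.array([x2_at[d] for d in days])


@dataclass
class CascadeBundle:
    """Everything one continuous-cascade run produces."""

    control_series: ReactorTimeSeries
    experimental_series: ReactorTimeSeries
    control_counts: CellCountSeries
    experimental_counts: CellCountSeries
    dilution: DilutionSeries
    abundance: AbundanceTable
    mu2_true: np.ndarray  # mu2 at each sampling day
    x2_true: np.ndarray   # noise-free X2 at each sampling day


def generate_continuous_cascade(scenario: SyntheticScenario) -> CascadeBundle:
    """Generate one seeded continuous-cascade experiment."""
    rng = scenario.rng()
    days = np.asarray(scenario.sampling_days, dtype=float)
    n = len(days)
    dilution = run_schedule(scenario.feed_X0, list(scenario.schedule))

    exposure = np.array([dilution.at_day(d) for d in days])
    mu2_true = np.array([mu2_of_exposure(x, scenario) for x in exposure])
    x2_true = _x2_exact(scenario, dilution)
    x1_true = np.full(n, scenario.X1_steady)

    cv = scenario.count_noise_cv
    x1_obs = x1_true * _lognormal_factor(rng, cv, n)
    x2_obs = x2_true * _lognormal_factor(rng, cv, n)

    control_counts = CellCountSeries(days, x1_obs, reactor_id="control")
    experimental_counts = CellCountSeries(days, x2_obs, reactor_id="experimental")

    sd = scenario.chem_sd
    stress = np.clip((exposure - scenario.X_tox) / scenario.X_tox, 0.0, None)

    def chem(base: np.ndarray, key: str, floor: float | None = None) -> np.ndarray:
        out = base + rng.normal(0.0, sd[key], n)
        if floor is not None:
            out = np.clip(out, floor, None)
        return out

    # Control reactor: quasi-stationary continuous-mode chemistry.
    ctrl_fe2 = np.zeros(n)
    ctrl_fe3 = chem(np.full(n, 10.0), "fe", floor=0.0)
    control_series = ReactorTimeSeries(
        times=days,
        pH=chem(np.full(n, 1.22), "pH"),
        Eh=chem(np.full(n, 850.0), "Eh"),
        fe2=ctrl_fe2,
        fe3=ctrl_fe3,
        fe_total=ctrl_fe2 + ctrl_fe3,
        cells=x1_obs,
        reactor_id="control",
    )

    # Experimental reactor: tracks the control until toxic stress sets in,
    # then pH rises, Eh falls and ferrous iron accumulates.
    exp_fe2_base = 4.0 * stress
    exp_fe2 = chem(exp_fe2_base, "fe", floor=0.0)
    exp_fe2[exp_fe2_base < scenario.fe_lod / 2] = 0.0  # below detection -> 0
    exp_fe3 = chem(np.clip(16.0 - 9.0 * stress, 0.0, None), "fe", floor=0.0)
    experimental_series = ReactorTimeSeries(
        times=days,
        pH=chem(1.16 + 0.35 * stress, "pH"),
        Eh=chem(870.0 - 160.0 * stress, "Eh"),
        fe2=exp_fe2,
        fe3=exp_fe3,
        fe_total=exp_fe2 + exp_fe3,
        cells=x2_obs,
        reactor_id="experimental",
    )

    abundance = _abundance_table(scenario, dilution, rng)

    return CascadeBundle(
        control_series=control_series,
        experimental_series=experimental_series,
        control_counts=control_counts,
        experimental_counts=experimental_counts,
        dilution=dilution,
        abundance=abundance,
        mu2_true=mu2_true,
        x2_true=x2_true,
    )


def _abundance_table(
    scenario: SyntheticScenario, dilution: DilutionSeries, rng: np.random.Generator
) -> AbundanceTable:
    community = dict(scenario.community)
    rows = []
    for reactor in ("control", "experimental"):
        for day in scenario.abundance_days:
            exposure = 0.0 if reactor == "control" else dilution.at_day(day)
            weights = {
                g: resp.raw_weight(exposure)
                * _lognormal_factor(rng, scenario.abundance_noise_cv, 1)[0]
                for g, resp in community.items()
            }
            weights["Other"] = scenario.other_weight
            total = sum(weights.values())
            row = {
                "sample_id": f"{reactor[:4]}_d{day:g}",
                "day": day,
                "reactor": reactor,
                "pcb_gL": exposure,
            }
            row.update({g: 100.0 * w / total for g, w in weights.items()})
            rows.append(row)
    return AbundanceTable(pd.DataFrame(rows))


def generate_constant_mu2_pair(
    mu2: float,
    scenario: SyntheticScenario | None = None,
    n_samples: int = 12,
    interval: float = 2.5,
    seed: int | None = None,
) -> tuple[CellCountSeries, CellCountSeries]:
    """Control/experimental count pair from a constant-mu2 cascade.

    The experimental trajectory follows the closed form (or the linear
    branch at mu2 = D) and both series carry the scenario's lognormal count
    noise.  Used by recovery studies where the generating mu2 is the known
    truth.
    """
    scenario = scenario or SyntheticScenario()
    if seed is not None:
        scenario = replace(scenario, seed=seed)
    rng = scenario.rng()
    times = np.arange(n_samples) * interval
    p = CascadeParams(
        D=scenario.D, mu1=scenario.D, mu2=mu2,
        X1_0=scenario.X1_steady, X2_0=scenario.X2_0,
    )
    if abs(mu2 - scenario.D) <= REGIME_ATOL:
        x2 = linear_growth_X2(times, p)
    else:
        x2 = analytic_X2(times, p)
    cv = scenario.count_noise_cv
    x1_obs = scenario.X1_steady * _lognormal_factor(rng, cv, n_samples)
    x2_obs = x2 * _lognormal_factor(rng, cv, n_samples)
    return (
        CellCountSeries(times, x1_obs, reactor_id="control"),
        CellCountSeries(times, x2_obs, reactor_id="experimental"),
    )


def generate_batch_run(scenario: SyntheticScenario, noise: bool = True) -> ReactorTimeSeries:
    """Generate one seeded batch run with programmed event times."""
    rng = scenario.rng()
    t = np.arange(0.0, scenario.batch_horizon + 1e-9, scenario.batch_interval)
    if t[-1] < scenario.batch_horizon:
        t = np.append(t, scenario.batch_horizon)
    n = len(t)
    sd = scenario.chem_sd if noise else {"pH": 0.0, "Eh": 0.0, "fe": 0.0}
    cv = scenario.count_noise_cv if noise else 0.0

    # Delayed-logistic cell growth: flat through the lag, then logistic to K.
    L, r, K, x0 = (
        scenario.lag_days, scenario.growth_rate,
        scenario.carrying_capacity, scenario.initial_cells,
    )
    grown = K * x0 / (x0 + (K - x0) * np.exp(-r * np.clip(t - L, 0.0, None)))
    cells = np.where(t < L, x0, grown) * _lognormal_factor(rng, cv, n)

    # pH: stable through the lag, then linear decline crossing the reference
    # value on the programmed day, floored.
    slope = (scenario.ph_initial - scenario.ph_reference) / (scenario.ph_cross_day - L)
    ph = np.clip(
        scenario.ph_initial - slope * np.clip(t - L, 0.0, None),
        scenario.ph_floor, None,
    ) + rng.normal(0.0, sd["pH"], n)

    # Eh: sigmoid rise positioned so the reference value is crossed on the
    # programmed day.
    frac = (scenario.eh_reference - scenario.eh_initial) / (
        scenario.eh_final - scenario.eh_initial
    )
    t0 = scenario.eh_cross_day - math.log(frac / (1 - frac)) / scenario.eh_steepness
    eh = (
        scenario.eh_initial
        + (scenario.eh_final - scenario.eh_initial)
        / (1.0 + np.exp(-scenario.eh_steepness * (t - t0)))
        + rng.normal(0.0, sd["Eh"], n)
    )

    # Ferrous iron: linear decline to zero at the programmed depletion day;
    # below-detection values are recorded as zero.
    dep, dur = scenario.fe2_depletion_day, scenario.fe2_decline_days
    fe2_base = np.where(
        t < dep - dur,
        scenario.fe2_initial,
        scenario.fe2_initial * np.clip((dep - t) / dur, 0.0, None),
    )
    fe2 = np.clip(fe2_base + rng.normal(0.0, sd["fe"], n), 0.0, None)
    fe2[fe2_base < scenario.fe_lod / 2] = 0.0

    # Ferric iron: linear mobilisation after the lag.
    horizon = max(scenario.batch_horizon - L, 1.0)
    fe3 = np.clip(
        scenario.fe3_initial
        + (scenario.fe3_final - scenario.fe3_initial)
        * np.clip((t - L) / horizon, 0.0, 1.0)
        + rng.normal(0.0, sd["fe"], n),
        0.0, None,
    )

    return ReactorTimeSeries(
        times=t,
        pH=ph,
        Eh=eh,
        fe2=fe2,
        fe3=fe3,
        fe_total=fe2 + fe3,
        cells=np.clip(cells, 0.0, None),
        reactor_id="experimental",
    )
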