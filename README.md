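# coleach

Quantitative analysis of **co-bioleaching experiments** in which pyrite
flotation tailings and ground printed-circuit-board (PCB) dust are leached
together by an acidophilic microbial community — either in batch runs or in
a two-reactor continuous cascade where a control chemostat (tailings only)
feeds an experimental reactor (tailings + PCB dust). It is written for
biohydrometallurgy researchers who monitor such reactors (pH, Eh, iron
speciation, cell counts, metal concentrations, 16S genus abundances) and
want the modelling and bookkeeping around those measurements to be
reproducible and testable.

## What it computes

**Cascade chemostat model** (`coleach.cascade`). Cell balances for the
cascade:

```
dX1/dt = X1 (μ1 − D)
dX2/dt = D X1 + μ2 X2 − D X2
```

with dilution rate `D` (day⁻¹), specific growth rates `μ1`, `μ2` (day⁻¹)
and cell concentrations `X1`, `X2` (10⁷ cells/mL). With reactor 1 at
chemostat steady state (`μ1 = D`, `X1` constant), `X2` has the closed form
`X2(t) = D·X1/(D−μ2) + C·e^{(μ2−D)t}`, and the long-run fate of `X2`
relative to `X1` classifies into regimes: exponential growth (`μ2 > D`),
stabilisation above `X1` (`0 < μ2 < D`), equality (`μ2 = 0`), a level below
`X1` (`μ2 < 0`, net cell death — the signature of dust toxicity), and
linear growth in the degenerate `μ2 = D` case.

**Feed material balance** (`coleach.dilution`). The in-reactor dust
concentration under stepwise feeding follows
`X_{i+1} = (X_i·(V_total−V_added) + Y_i·V_added)/V_total`; the packaged
reference programme (inlet 5 → 12.5 → 37.5 g/L, 400 mL replaced per step in
a 1 L reactor) tracks a three-stage continuous run.

**Growth-rate estimation** (`coleach.growth`). Pointwise estimators
`μ1 = D + X1′/X1` and `μ2 = (X2′ − D·X1 + D·X2)/X2` from count series, and
a least-squares fit of a constant `μ2` to the closed-form solution with a
seeded residual-bootstrap confidence half-width.

**Stoichiometry and yields** (`coleach.stoich`). Element/charge balance
checks for the canonical leaching reactions (pyrite oxidation by O₂ and by
Fe³⁺, microbial Fe²⁺ oxidation, ferric and acid dissolution of zero-valent
metals), mole budgets derived from them, and the control-corrected leach
yield `Ym = (m_LE − m_LC)/(Xi·V_total·ω) × 100 %`.

**Process metrics** (`coleach.metrics`). Batch-run indicators: time to a
reference pH or Eh, sustained ferrous-iron depletion time, and lag-phase
duration (k-fold sustained count rise).

**Community statistics** (`coleach.community`). Genus relative-abundance
tables with Pearson correlation against PCB exposure, encoded either as the
material-balance dust concentration at the sampling day or as binary
presence.

**Synthetic data** (`coleach.synth`). A seeded generator for both designs —
a cascade with a piecewise-linear toxicity response `μ2(x)` and a batch run
with programmed lag/crossing/depletion times — so every estimator can be
validated by round-trip recovery without any external data.

## Worked example

```python
import numpy as np
from coleach import (CascadeParams, analytic_X2, classify_regime,
                     steady_state_X2, reference_schedule, run_schedule,
                     LeachYieldInput, leach_yield, PCB_MASS_FRACTIONS)

# In-reactor dust concentration over the three-stage feed programme
series = run_schedule(5.0, reference_schedule())
print([round(c, 1) for c in series.conc])
# [5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 8.0, 9.8, 10.9, 11.5, 11.9,
#  22.2, 28.3, 32.0, 34.2, 35.5]

# A net-death cascade: mu2 = -1.07/day at D = 0.2/day, upstream X1 = 200e7/mL
p = CascadeParams(D=0.2, mu1=0.2, mu2=-1.07, X1_0=200, X2_0=200)
print(classify_regime(p).name, round(steady_state_X2(p), 2))
# BELOW_X1 31.5

# Copper leach yield: 0.091 g mobilised over 5 g/L dust, 1 L, 2.6% Cu
ym = leach_yield(LeachYieldInput(0.091, 0.0, 5.0, 1.0, PCB_MASS_FRACTIONS["Cu"]))
print(f"{ym.percent:.1f}%")
# 70.0%
```

The dust concentration climbs toward each stage's inlet value
geometrically (40 % of the volume replaced per step); the toxic-regime
cascade settles at 31.5×10⁷ cells/mL, well below the upstream 200 — a
sustained deficit only a negative growth rate can produce; and the yield is
the fraction of the copper fed with the dust that ended up in solution,
after subtracting the control reactor's contribution.

A CLI mirrors the library: `coleach simulate-cascade`, `dilution`,
`estimate-growth`, `yield`, `metrics`, `correlate`, `synth` (writes a full
synthetic fixture bundle) and `run` (full pipeline from a YAML config).

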