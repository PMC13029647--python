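# Methods

This note records the models, the parameter choices, and the numerical and
design decisions behind `coleach`, in the spirit of a model-documentation
page: what is assumed, what is tunable, and what the synthetic validation
does and does not show.

## Cascade chemostat model

The two-reactor cascade is modelled with constant specific growth rates and
perfect mixing:

```
dX1/dt = X1 (μ1 − D)
dX2/dt = D X1 + μ2 X2 − D X2
```

Assumptions: equal dilution rate `D` in both reactors, no substrate
limitation (no Monod term — μ is a constant of each operating window), no
feedback of pH/Eh on growth, and reactor 1 at chemostat steady state
(`μ1 = D`, `X1` constant) in the default analysis mode. `simulate_cascade`
can also integrate both balances for a transient reactor 1.

With steady `X1`, the downstream balance is linear with solution
`X2(t) = D·X1/(D−μ2) + (X2(0) − D·X1/(D−μ2))·e^{(μ2−D)t}` for `μ2 ≠ D`.
The degenerate `μ2 = D` case is singular in that expression and is solved
separately as `X2(t) = X2(0) + D·X1·t`; `analytic_X2` refuses it with an
error pointing at the linear branch rather than dividing by a vanishing
denominator. Regime boundaries (`μ2 = 0`, `μ2 = D`) are compared with an
absolute tolerance of 1e−12.

Numerics: LSODA (adaptive, stiffness-switching) with rtol 1e−8 and
atol 1e−10 — the system is stiff when `μ2 ≪ 0` and the exponential term
decays on a sub-day scale. Integrator output is clipped at zero and the
trajectory flagged if clipping occurred. Units are fixed throughout: days,
10⁷ cells/mL; conversion is the caller's job.

## Feed material balance

Each feed event replaces `V_added` of reactor pulp with fresh pulp at
concentration `Y_i` in a constant working volume `V_total`, giving
`X_{i+1} = (X_i(V_total − V_added) + Y_i V_added)/V_total`. The dust is
treated as conserved between events (no solid-phase consumption term). The
recursion is convex — each output lies between its inputs — and conserves
mass exactly, both enforced as tests.

The packaged reference programme uses `V_added = 400 mL`, `V_total =
1000 mL` for every step, including the three-day sampling intervals. That
fixed 0.4 replaced fraction is the only per-step choice consistent with the
published concentration table this programme reproduces (a strict `D·Δt`
accounting would replace more volume on three-day intervals and misses the
table); the step *ending* on a feed-switch day still carries the previous
inlet concentration, which is likewise the only reading consistent with the
printed values. Full precision is carried between steps; rounding is a
reporting concern (the suite also checks that carrying one-decimal-rounded
intermediates stays within ±0.1 g/L, guarding against either rounding
convention).

## Growth-rate estimation

Pointwise estimators rearrange the balances: `μ1 = D + X1′/X1` and
`μ2 = (X2′ − D·X1 + D·X2)/X2`. Derivatives come from second-order finite
differences on the native (possibly irregular, 2–3-day) grid — central in
the interior, second-order one-sided at the ends (`np.gradient`,
`edge_order=2`). The control series is linearly interpolated onto the
experimental sampling times; points outside the overlap are dropped, never
extrapolated. Zero experimental counts are floored at half the smallest
positive count in the pointwise estimator only (the balance divides by X2),
with a warning; the global fit uses raw values.

`fit_mu2_constant` minimises the squared error between the closed-form
`X2(t; μ2)` and the observations over a bounded interval (−10, 5) day⁻¹
(bounded scalar minimisation, xatol 1e−10), switching to the linear branch
within 1e−12 of `μ2 = D`. `X1` is fixed at the mean of the aligned control
counts and `X2(0)` at the first experimental observation. The confidence
half-width is 1.96 × the SD of a seeded residual bootstrap (default 200
refits); the point estimate never depends on the bootstrap.

## Stoichiometry and yields

Reactions are parsed from plain text (`"FeS2 + 14 Fe+3 + 8 H2O -> 15 Fe+2 +
2 SO4-2 + 16 H+1"`) into exact-rational coefficients; balance residuals
(reactant minus product totals, per element and for charge) are exact
`Fraction` arithmetic, so "balanced" means identically zero, not small.
The generic divalent metal `Me` is a first-class placeholder symbol so the
metal-dissolution equations can be balance-checked symbolically and then
instantiated with Cu, Ni or Zn. Mole budgets (protons, ferrous/ferric iron,
oxygen per mol pyrite or metal) are derived at run time from the parsed
canonical reactions rather than duplicated as literals.

The leach yield `Ym = (m_LE − m_LC)/(Xi·V_total·ω)·100 %` takes `m_LE` and
`m_LC` as **masses** of metal in the whole liquid phase (grams): a measured
concentration must be multiplied by the liquid volume first. Yields outside
[0, 100] are reported unclipped with an `in_range=False` flag — a negative
yield means the control mobilised more metal than the experiment and is
diagnostic, not an error.

## Process metrics

Threshold crossings are linearly interpolated between bracketing samples;
a series already at or past the threshold at its first sample reports 0
days (this convention is what makes "raising a falling threshold never
increases the time" hold exactly). A snap-to-next-sample mode is exposed
for integer-day reporting. Ferrous depletion requires the concentration to
stay below the detection limit (default 0.05 g/L, configurable — the
titrimetric floor is method-dependent) for the remainder of the series.
The lag phase ends at the interpolated time of the first `k_fold`-times
rise over the initial count (default k = 2) that is still sustained at the
next sample; the k-fold definition is this package's operational choice, as
no standard one exists, and k is a parameter for that reason.

## Synthetic-data generator

The generator emulates the two study designs so that every estimator can be
validated by generate-then-recover round trips.

*Continuous cascade*: dilution rate 0.2 day⁻¹ (5-day retention), control
reactor steady at 200×10⁷ cells/mL, the three-stage feed programme and its
2–3-day sampling grid over 34 days, and 10 % CV mean-one lognormal noise on
counts. Toxicity enters as a piecewise-linear response
`μ2(x) = μ_base·max(0, 1 − x/X_tox) − δ·max(0, x − X_tox)/X_tox` with
μ_base = 0.1 day⁻¹, X_tox = 15 g/L and δ = 0.8 day⁻¹: near-zero growth at
low dust loads and net death approaching −1.1 day⁻¹ at the final 35.5 g/L.
This is the simplest form reproducing the qualitative finding the cascade
model is used for (benign at ≤ 12 g/L, lethal near 35 g/L); it is a
modelling template, not a measured dose–response. Because μ2 is constant
between feed events, the noise-free trajectory is assembled exactly from
the per-segment closed form — no integrator error enters the truth.
Abundance tables use a per-genus logistic response to exposure
(Leptospirillum and Acidithiobacillus favoured; Ferroplasma and
Sulfobacillus suppressed, mirroring the mixotroph-suppression pattern such
systems show), renormalised to 100 % with an "Other" remainder.

*Batch run*: delayed-logistic counts (lag 12 days, rate 0.6 day⁻¹, plateau
150×10⁷ cells/mL), pH stable through the lag then declining linearly to
cross 1.2 on a programmed day, Eh rising sigmoidally through 800 mV on a
programmed day, ferrous iron declining linearly to zero at a programmed
depletion day, ferric iron mobilising after the lag, and `fe_total = fe2 +
fe3` enforced after noise. Chemistry noise is truncated Gaussian (pH 0.02,
Eh 5 mV, iron 0.02 g/L); values below half the ferrous detection limit are
recorded as zero, as a titrimetric assay would report them.

Each generator draws from a single `numpy` Generator seeded from the
scenario, so outputs are byte-identical for a fixed seed and independent of
platform. What passing the round-trip tests shows: the estimators are
consistent under the model's own assumptions and noise structure. What it
does not show: robustness to real-data pathologies the generator omits —
sampling-day irregularities beyond the fixed grid, non-lognormal count
error, drifting control reactors, pH/Eh feedback on growth, or solid-phase
dust consumption.

## Community statistics

Pearson correlations are computed per genus against the exposure vector;
genera with constant abundance (including all-zero) are flagged undefined
rather than assigned a number. Both exposure encodings (concentration at
the sampling day from the material-balance series, and binary presence) are
supported because published community–exposure correlations in this problem
area rarely state which convention was used; no multiple-testing correction
is applied and r is reported without p-values by default. Abundance tables
are validated on read: values in [0, 100], per-sample totals in (0, 100]
(±1 percentage point when an "Other" column should complete the sample to
100 %), with row-level diagnostics on rejection.

## Problem sizes

The validation studies use: 200 random parameter draws for the closed-form
vs ODE comparison (τ ∈ [0, 50] days); 100 seeded replicates (12 samples
each, 10 % count CV) for the μ2-fit bias study; a 0.1-day grid over 30 days
for the pointwise-estimator check; and a 3 × 5 scenario grid (three lag
settings, five seeds) for the batch-metric recovery study. These sizes give
stable estimates of the quantities reported while keeping the whole suite
in the seconds range.

## Known limitations

- Growth rates are window-constants; no substrate limitation, inhibition
  kinetics or mechanistic dose–response is modelled.
- The material balance conserves dust between feed events; leaching-driven
  solid consumption would bias the exposure series high late in a run.
- Eh and pH shapes in the generator are phenomenological templates; no
  Nernstian speciation is attempted, so the metrics are validated on shape,
  not chemistry.
- The leach-yield formula's mass convention must be honoured by the caller;
  passing concentrations directly produces silently scaled results.
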