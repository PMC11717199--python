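# Methods

## The model

The package models a treated tumor as two subpopulations sharing one
environment: sensitive cells `S(t)` and resistant cells `R(t)`, with
total `N = S + R`:

```
dS/dt = rho · ln(K/N) · (1 − lam·C(t)) · S
dR/dt = rho · ln(K/N) · R
```

Assumptions worth stating explicitly:

* **Shared carrying capacity `K` and growth rate `rho`.**  The two types
  compete only through the crowding term `ln(K/N)`; there is no
  competition matrix and no cost of resistance (off treatment the two
  types are dynamically indistinguishable, so the composition `S/N` is a
  constant of motion at `C = 0` — this is asserted as a property test).
* **Treatment acts multiplicatively on the sensitive type only.**
  `lam·C > 1` flips sensitive growth to decline while `N < K`; values of
  `lam` above 1 are therefore meaningful and allowed.
* **Dose is piecewise constant** and right-continuous: the in-vitro
  protocol is a step (0 before drug onset at 20 h, 1 after), the
  in-vivo protocol a constant `C = 1` (regular dosing at constant dose).

Under constant dose the two log-populations integrate the same shared
factor, giving the exact coupling `S/S0 = (R/R0)^(1−lam·C)`; this and
the monotypic closed form `N(t) = K·exp(ln(N0/K)·exp(−rho·t))` are the
independent oracles the integrator is tested against.

## Numerics

Simulation integrates in log-population coordinates (positivity is
structural; a type seeded at exactly 0 is dropped from the state and
reported as 0).  LSODA with `rtol = 1e-8`, `atol = 1e-10`; invariants
are asserted at 1e-6 or tighter.  Integration restarts at each dose
breakpoint so the 20 h drug switch is a hard segment boundary, never
smeared across an adaptive step.  Times carry native units — hours in
vitro, days in vivo — and are never converted implicitly.

## Fitting protocols

**In vitro** (per well): objective is the unweighted sum
`MSE_S + MSE_R`.  The fit starts at the third measured time point
(0-based index 2) and the initial state is pinned to the measured
values there, removing two free parameters (a free-initial-state mode
is available).  `lam` is a free parameter only in drug wells; in
no-drug wells the dose is identically zero and `lam` would be inert, so
it is fixed at 0.  In monotypic wells (seeding proportion 0 or 1) the
minor population's readout is fluorescent noise; it is zeroed before
fitting, its fitted trajectory is identically zero, and it contributes
exactly zero error.

**In vivo** (per patient): only the total volume is observed.  The
first measured volume fixes `N0`; its split is searched on a 21-point
grid of the initial sensitive fraction `p0 ∈ {0, 0.05, …, 1}`, fitting
`(rho, K, lam)` by least squares at each grid point and keeping the
best.  Near-ties (within `1e-9·mean(volume)²` of MSE, the scale of
optimizer noise) go to the smaller `p0`; this matters on the `lam → 0`
ridge where every split reproduces the same total.

**Bounds** (per time unit of the data): `rho ∈ [1e-4, 2]`,
`K ∈ [max observed N, 1e8 × max observed N]`, `lam ∈ [0, 10]`.  The
enormous `K` ceiling is deliberate: it admits the exponential limit
`K ≫ N`, where `ln(K/N)` is nearly constant and the fit degenerates to
exponential growth/decay — a regime that genuinely occurs for
sensitive-dominated drug wells and is flagged by the
`classify_fit_regime` diagnostic (threshold `K / max N > 1e3`).

**Multi-start**: each local trust-region least-squares fit starts from
one of 5 seeded Latin-hypercube points in the bounded box (`rho`, `K`
on a log10 scale, `lam` linear).  Starts are the first rows of a fixed
16-row LHS pool, so the best objective is non-increasing in the number
of starts and everything is deterministic given the config seed.
Optimizer `xtol = ftol = 1e-8`.

## Comparator growth laws

Two one-dimensional baselines, the best-performing classical laws for
sparse clinical series, are fitted with the same multi-start contract
and `V0` fixed to the first measurement:

* General Gompertz: `dV/dt = alpha·V·ln(K_c/V) − beta·C(t)·V`
* General von Bertalanffy: `dV/dt = alpha·V^gamma − beta·V`

These functional forms are **provisional defaults**; `ComparatorSpec`
keeps the law as data (rhs + named bounded parameters), so substituting
a different parameterization is a configuration change.  Note that
under constant dose the General Gompertz collapses to a plain Gompertz
with effective capacity `K_c·exp(−beta/alpha)` — `K_c` and `beta` are
then not separately identifiable, which is why the self-recovery test
uses a dose step.  Both laws are autonomous and one-dimensional under
constant dose, hence monotone: they cannot produce a decline followed
by regrowth.  That structural gap — not raw flexibility — is what the
U-shape comparison isolates.

## Trend classification

Five categories (Growth, Decline, DelayedResponse, UShape, Fluctuate)
are assigned by threshold rules on the measured series only.  All
comparisons are relative to the first volume `x1` through one threshold
`delta = 0.2` (a change is "significant" above 20% of baseline), which
buys scale and time-shift invariance.  Precedence: Fluctuate on ≥ 3
sign changes of significant successive differences; then Growth
(never significantly below baseline, ends significantly above);
Decline (mirror image); UShape (significant interior minimum with
significant regrowth); DelayedResponse (significant maximum before the
minimum, with a significant drop from it); else Fluctuate.  `delta` and
the sign-change count are configuration, not constants.

## Evaluation statistics

* **MAPE** (percent): zero-measurement points are excluded rather than
  epsilon-regularized, so an absent population predicted as absent has
  exactly zero error.
* **nMSE**: MSE divided by the squared mean measured volume.  A
  variance-normalized variant was considered and rejected as the
  default because near-constant series make it explode.
* **Welch's t-test** with Welch–Satterthwaite fractional degrees of
  freedom, two-sided; validated against an exhaustive permutation
  distribution on small samples.
* The per-category model comparison uses unpaired two-sided t-tests on
  nMSE by default; a paired option exists since the same series
  underlie all three models.  No multiple-testing correction is applied
  across the category × model-pair table.
* The CAF comparison tests fitted `lam` in drug wells grouped by CAF
  flag.  Monotypic wells can be excluded (`exclude_outliers`): in a
  fully resistant well `lam` never enters the dynamics, so its fitted
  value is an arbitrary point on a flat objective ridge and only adds
  variance.

## Synthetic data: what it emulates, what it does not

**Plate** (defaults): 8 seeding proportions (0, 0.1, 0.2, 0.4, 0.6,
0.8, 0.9, 1) × drug ± × CAF ± × 6 replicates = 192 wells; counts every
4 h for 120 h; seed total 1000 cells; drug at 20 h.  Per-well
parameters are lognormal around condition means: `rho` mean 0.04/h
(CV 10%), `K` mean 6000 cells (CV 15%), `lam` mean 1.2 without CAF and
0.6 with CAF (CV 15%) — the CAF condition is modeled *only* as this
halving of mean drug sensitivity, matching the implicit-comparison
design.  Measurement noise is mean-corrected multiplicative lognormal
(sigma 0.05) on counts, so the expected measured trajectory tracks the
latent one; the minor population of monotypic wells is exactly zero
(an optional fluorescent floor exists, off by default).  Absolute
scales (seed count, cadence) are order-of-magnitude choices exposed in
the design config.

**Cohort** (defaults): 100 patients cycling through the five intended
categories; baseline diameter 20–60 mm (volume = sphere from longest
diameter, `(pi/6)·d³`); visits at 42 ± 7 days; 4–12 visits per patient,
so roughly a fifth fall below the 6-measurement analysis filter by
design; `rho ∈ [0.003, 0.010]/day`, `K` 3–30× baseline volume,
`lam ∈ [1.5, 3]`.  Noise perturbs the implied *diameter* (sigma 0.02)
and is cubed back, giving right-skewed volume noise; lesions below a
5 mm detection floor are reported at the floor.  Category mechanisms:
Growth is resistant-dominated (`p0 ≤ 0.1`); Decline and DelayedResponse
are fully sensitive (`p0 = 1`) — under this model any resistant remnant
regrows on the study timescale, so a monotone decline that never
relapses implies a purely sensitive tumor; DelayedResponse additionally
starts treatment only after the first 1–2 visits, giving the classifier
true positives and the constant-dose fitter a known, documented failure
mode; UShape combines high `p0` (0.7–0.95) with `lam > 1` so sensitive
collapse precedes resistant regrowth; Fluctuate sits near carrying
capacity with larger diameter noise (sigma 0.08).  Each patient is
redrawn (≤ 40 attempts) until the noisy series classifies as intended;
the truth table records the intended category and realization flag.

Passing tests on these data show the pipeline recovers what the
generator encodes under the model's own assumptions.  They do not show
that real wells follow shared-`(rho, K)` dynamics, that real CAF action
is a pure `lam` shift, that clinical noise is lognormal in diameter, or
that real delayed responses come from late treatment starts — those are
modeling hypotheses the synthetic data inherits rather than tests.

**Canonical series**: 25 small archetypal shapes (5 per category,
scale- and stretch-varied) exercise the classifier directly, including
a zigzag Fluctuate shape that no noise-free trajectory of this model
can produce.

## Problem sizes

The test suite fits the full 192-well plate once (shared across
checks), 24-well recovery subsets, 50 small 12-well plates for the
null-calibration of the CAF test, and 20 U-shape series against all
three models; the acceptance script refits the full plate from scratch.
These sizes were chosen to match the emulated designs while keeping a
complete run in the minutes range on one CPU.

## Known limitations

* No uncertainty quantification beyond residuals (no bootstrap/profile
  intervals); no hierarchical sharing across wells or patients.
* The in-vivo fit assumes `C = 1` from the first measurement; delayed
  responses are therefore systematically misfit (by design, mirroring
  the data situation where treatment start predates baseline imaging).
* Comparator forms are provisional defaults pending an authoritative
  parameterization; conclusions drawn from them are structural
  (monotonicity) rather than parametric.
* The `p0` grid quantizes the initial sensitive fraction; off-grid
  truths propagate a few-percent bias into `lam`.
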