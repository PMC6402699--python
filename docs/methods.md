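# Methods

## Model

The community model couples two live populations and two exchanged
metabolites in four ODEs (README).  Its assumptions: birth rates depend
only on the instantaneous local concentration of the required metabolite
through Moser kinetics; death rates are constant; metabolite release is a
per-live-cell rate; consumption is proportional to births.  Units are
fixed package-wide (time h, densities cells/mL, concentrations µM,
per-cell amounts fmole), so a per-cell amount times a density converts to
concentration with the factor 10⁻⁶ — this is what makes the plausibility
check "0.12 fmole/cell × 10⁵ dead cells/mL = 0.012 µM" a one-liner.

The steady-state growth rate follows from requiring both strains to grow
at the community rate with stationary metabolites.  The exact root keeps
the death-asymmetry term `(d_A−d_L)²/4`; the working approximation drops
it (for the packaged phenotypes the difference is ~4×10⁻⁴/h).  Two lysine
release laws are supported, because the releasing strain's rate is
strongly environment-dependent: a piecewise-linear law in the local
hypoxanthine concentration (knots from the measured registry, clamped at
the ends), used in simulations, and a linear law in the releaser's net
growth rate, used analytically.  At steady state they describe the same
measurements from two sides and both simulated variants land on ≈0.10/h;
they differ slightly (0.102 vs 0.099/h) because the linear law is a
regression through measurements the piecewise law interpolates.

Error propagation uses the variance formula with analytic partials of the
approximate closed form, with the lysine release rate and SEM taken from
the 7-h-doubling chemostat row of the registry, whose doubling time
matches the community's.  SEMs derive from the registry's 95% bounds as
(upper−lower)/4.  The registry stores bounds exactly as measured and
rounded; for the two consumption parameters this rounding is visible in
the third significant figure of their (small) variance contributions,
which is why per-term tests allow a generous tolerance there while the
total error (0.004/h, 95% CI ±0.01/h) is insensitive.

## Chemostat estimators

The chemostat module simulates one strain under inflow at reservoir
concentration and symmetric outflow, in live-release or release-on-death
mode.  The two modes produce *identical* metabolite dynamics whenever
`r_live = r_death·d` — a structural non-identifiability verified by test —
so the release mode can only be decided from starvation assays, where the
dead-density and integrated-live-density curves decouple.  Estimators
implemented: steady-state inversions (consumption `(S₀−S)·dil/(b·N)`,
death `dil·dead/live`, release `dil·M/live`), and regressions of
`M·e^(dil·t)` (through the origin) and `dead·e^(dil·t)` (free intercept,
estimating the initial dead density) on the trapezoid-integrated
`live·e^(dil·t)`.  Steady state is detected as the final third of the
series after live-density changes fall below 5% per sampling interval
(configurable); the two estimator families agree within 3% on converged
noiseless runs.  Batch estimators enforce their validity conditions as
point filters with warnings: the exponential-consumption fit drops points
after the metabolite falls below 10 µM, and the release upper bound
documents its `N(T) ≫ N(0)` requirement.

The live-vs-dead comparison scores each model by R² of its prescribed fit
(computed about zero for the origin-constrained live model) and flags the
comparison indeterminate when the two R² values agree to 10⁻⁶, which is
exactly the collinear case (constant death rate, no dilution).

## Synthetic data

Generators wrap the package's own forward models and multiply latent
values by independent mean-one lognormal noise, CV 7.5% for densities
(flow-cytometry counting) and 10% for metabolite assays (bioassays); all
randomness flows from one recorded seed.  The chemostat generator samples
the exact ODE solution at the requested cadence (default every 4 h to
96 h).  The starvation generator uses closed-form latents with a
*two-phase* death rate — 0.005/h to 12 h, then 0.02/h — because starved
auxotrophs die slowly at first and faster later, and because with a
strictly constant death rate the dead density is exactly proportional to
the integrated live density, making live and dead release mathematically
indistinguishable; the two-phase default is the realistic feature that
gives the mode comparison its power (constant death remains available and
is used to test the indeterminate flag).  The community generator applies
fresh-medium dilutions when the total density crosses a threshold and
records cumulative factors so accumulative densities can be reconstructed.
What the generators do **not** emulate: assay standard curves,
flow-cytometry gating artifacts, cross-channel noise correlation (assumed
independent; unreported experimentally), or the time-varying starvation
release rate — so passing recovery tests demonstrates estimator
correctness under the stated noise model, not robustness to every
real-data pathology.

## Growth-rate fitting

The steady-state rate is the least-squares slope of ln(total accumulative
live density) vs time, with the slope's standard error.  Two window
policies are exposed because the experimental convention (fit beyond a
total-cell cutoff, default 9×10⁷, optionally excluding points above 10⁸)
and the simulation-friendly one (start where the instantaneous rate stops
drifting by more than 1% over one doubling) answer different needs;
neither is hard-coded as truth.  The fitted-rate ± 2·SEM interval covers
the true rate in ≥90% of noisy replicates by construction of the OLS
slope error, verified by Monte-Carlo.

## Evolutionary dynamics

"Mutants per cell per generation" is implemented as a per-birth conversion
probability µ — the only formulation consistent with continuous-time birth
processes and the chromosome-mis-segregation mechanism.  With equal birth
rates the mutant fraction follows `1 − e^(−µbt)`, the closed form the
batch test asserts.  A configurable lag freezes fractions before
exponential growth.  The chemostat competition extends the single-strain
equations with genotype-specific Moser laws sharing one metabolite.
Fitness arithmetic (log-ratio slope, founding-frequency back-extrapolation
`f₀ = f·e^(−s·t)`, and the 2·N·rate pre-existing-mutant count, where the
factor 2 is the birth-opportunity sum `(1+2+…+2ⁿ)/2ⁿ ≈ 2`) is exact.

## Spatial simulation

The spatial model is a continuum surrogate of an individual-based
simulation: since consumption and release scale linearly with biomass,
grid-level biomass densities are equivalent for community-level growth
rates (cell-scale patch structure is out of scope).  Cells occupy one
surface layer of a 3-D agar domain; metabolites diffuse with no-flux
boundaries (D = 360 µm²/s in agar, optionally 20 µm²/s inside the
community layer); each step is operator-split reaction-then-diffusion with
the explicit time step bounded by the 3-D stability limit
`dt ≤ 0.9/(2·D_max·(2/dx² + 1/dz²))`, checked before running.  Births are
capped by locally available metabolite so fields cannot go negative, and
the flux-form diffusion stencil conserves domain mass to machine
precision.  The default reduced-scale domain is 200 µm × 200 µm laterally
(dx = 50 µm) over a 5-mm column (dz = 500 µm) with a uniform inoculum of
3000 cells/mm²; the grid is deliberately anisotropic because the vertical
gradient through millimetres of agar is shallow, and the package's
refinement test shows halving dx and dz moves the growth rate by <2%.
This desk-scale default keeps a 40-h run under a minute; full-size
lateral domains (800–960 µm at 5 µm) are configurable but slow.  At late
times metabolite concentrations equalize between community and agar
(within ~1% at default settings), which is why the structured community
grows at the well-mixed rate — the simulation reproduces that mechanism,
not just the number.

## Numerical choices

ODEs integrate with LSODA at rtol 10⁻⁸ (atol 10⁻¹⁰–10⁻¹²), with
metabolite arguments clamped at zero when evaluating birth rates since the
balance equations can transiently undershoot numerically.  Community
simulations should not be pushed to astronomically large densities
(>10¹⁴ cells/mL) without dilutions: the metabolite derivative is a small
difference of two terms proportional to density, and double precision
eventually cannot resolve the balance — the dilution-aware generator is
the intended tool for long horizons.  Quadratic root selection takes the
larger root and rejects non-positive roots (no sustainable growth).
Trapezoid integration of the exponentially weighted live density follows
the standard composite rule; at coarse experimental cadence (4-h) it
biases the release regression by ~1% during the fast initial transient,
which disappears at 1-h sampling.

## Known limitations

Lag-phase dynamics are not quantitatively reproduced (starvation
phenotypes are time-dependent and differ from chemostat phenotypes); the
linear release-law coefficients are consumed as given, not re-derived from
the knot measurements, and no uncertainty is propagated through them; the
spatial model validates growth rate and metabolite uniformity only, not
spatial patterning; time-varying starvation release is fitted as a single
rate over the assay window.
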