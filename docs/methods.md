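# Methods

## Models

**Mean-field model.** The magnetization obeys the Euler-discretized
self-consistency dynamics

    M_{t+1} = M_t + (−M_t + tanh(c·M_t + H))·Δt + σ·N_t,

with Δt = 0.1 and i.i.d. standard-normal N_t. Noise is added with weight
σ *per step*, without a √Δt factor: σ is defined as the per-step noise
weight, which is the convention under which the calibrated value
σ = 0.01 is quoted. Deterministic equilibria are the roots of
M = tanh(c·M + H); a root is stable iff −1 + c·sech²(c·M* + H) < 0.
For c > 1 the model is bistable for |H| < w(c) with

    w(c) = c·√(1 − 1/c) − arccosh(√c),

the two folds sitting symmetrically at ∓w; at H = 0 the ordered pair
appears in a supercritical pitchfork at c = 1. Root finding brackets
sign changes of the self-consistency residual on a 10⁻³ grid over
[−1, 1] and refines by bisection to 10⁻¹³; every reported equilibrium
satisfies the defining equation to better than 10⁻⁹.

**Lattice model.** Spins ±1 on an L×L grid (default L = 100; a flag
restores the randomized choice from {50, 100}) with periodic boundaries
and von Neumann neighborhoods. Metropolis single-site dynamics: an
update attempt picks a site uniformly, computes Ediff = 2S(NB − H), and
flips if Ediff ≤ 0 (no random number consumed for the decision itself;
draws are pre-generated per sweep so the stream length is fixed) or with
probability exp(−Ediff/T). One sweep = L² attempts = one time step.
Note the sign convention of the energy rule: positive H favours spin
−1, i.e. the effective aligning field is −H, mirrored relative to the
mean-field model where +H favours +M. All experiment presets account
for this; reported estimates keep each model's own sign convention.
The "center patch" of an L×L lattice is mapped to index (L//2, L//2)
(0-based rows from the top); `simulate_lattice(..., track_site=...)`
records any site.

## Model matching (calibrations)

The two representations are deliberately *not* identical: at the shared
saddle-node temperature T = 2.12 the literal mean-field coupling c = T
puts the folds at ±0.619, while the lattice's metastable window,
measured from slow field ramps, is roughly ±0.09. Two calibration steps
align the equation-based model with the agent-based one before they are
compared:

* **Coupling** (`calibrate_coupling`): field ramps of 2000 sweeps over
  H ∈ [−0.3, 0.3] are run in both directions at T = 2.12 (four
  realizations each); the transition field is where the magnetization
  crosses zero, and the mean transition magnitude is taken as the
  half-width of the lattice's bistable window. The mean-field coupling
  is then solved from w(c) = width (c ≈ 1.28 for L = 100). The measured
  width shrinks slowly with ramp rate (nucleation needs time), so the
  ramp is the slowest that stays cheap; this rate dependence is a known
  limitation, not a bug.
* **Noise weight** (`calibrate_sigma`): lattice fluctuations are
  strongly field-dependent — the across-realization magnetization
  spread at L = 100, T = 2.12 grows from ≈ 0.007 deep on the metastable
  plateau to ≈ 0.03 adjacent to the transition — while the mean-field
  noise envelope is nearly flat (≈ 2.5σ). "Best resembling" the lattice
  std is therefore implemented as matching the *maximum* spread over the
  pre-transition plateau (default plateau: seven fields from the
  state-favouring side, H = +0.10, to a mildly opposing H = −0.02, with
  tipped realizations dropped), i.e. matching the envelopes where they
  are widest and most informative. A plain plateau-mean aggregation is
  available (`agg="mean"`); it weights the quiet far plateau and selects
  a smaller σ. With the default aggregation the grid
  {0.001, 0.005, 0.01, 0.05} selects σ = 0.01.

## Perturbation–recovery protocol

Per realization: a transient of 100 steps at fixed parameter; the
equilibrium reference y_eq is the mean over the last 20% of the
transient (the reference is otherwise undefined); a one-step
perturbation (mean-field: state set to the amplitude; lattice: every
spin redrawn toward the current equilibrium sign with alignment
probability r, so r = 0 flips the lattice, r = 0.5 unorders it, r = 1
is a null perturbation); then the recovery is recorded (default 400
steps). 100 realizations are averaged into one mean curve *before*
differencing; per-realization analysis is not offered. Divergent
realizations are dropped with a warning (at least half must survive);
an ensemble mean that never re-enters the 5% band around y_eq is
flagged "non-recovery" — a warning, not an error, so near-bifurcation
sweeps remain explorable.

The saddle worked example perturbs the lower branch to amplitude 1.5
(beyond the alternate equilibrium; this overshoot is only meaningful in
the mean-field model, where the state is not bounded by ±1) at four
evenly spaced fields from 2.5 to 1.5 fold-widths below the lower fold —
the same geometry, relative to the fold, as the reference experiments
this package reproduces. The pitchfork presets perturb to magnetization
1 when starting from the disordered state and to 0.01 when starting
from the ordered branch; on the lattice those targets are reached
through the alignment probability r = (1 + target)/2 relative to +1.

## Estimator numerics

First differences d(t) = y(t+1) − y(t) of the mean curve; segment = all
indices before the first entry into the 5% band around y_eq (fraction
configurable); least-squares polynomial fit of degree 4 (configurable
2–8; degree 4 captures the plateau-then-peak shape of difference curves
without ringing) using the numerically stable scaled-domain polynomial
class; the maximum is taken over the fitted polynomial on a 1000-point
grid across the segment — not over the raw differences — so single
noisy steps cannot masquerade as the slowest recovery rate. The final
regression of maxima against parameter values is unweighted ordinary
least squares; the bifurcation estimate is its zero crossing
ĉ = −intercept/slope. Exactly two perturbations suffice (the line then
interpolates both points). Degenerate inputs raise: fewer than two
distinct parameters, segments shorter than the degree, and slopes that
move the maxima by less than numerical noise ("zero slope"). A zero
crossing between the perturbation parameters while all maxima share one
sign is allowed but flagged.

The equilibrium-curve variant samples each fitted difference curve at
matched relative positions q ∈ {0.1, …, 0.9} of its segment ("matched
relative position" is our concrete realization of a correlated sample
across curves; the sampling rule is otherwise open), regresses the
fitted values against the parameter at fixed q, and pairs each zero
crossing with the mean state at q. Square-root (nonlinear) extrapolation
models are out of scope: the method assumes a locally linear approach to
the transition.

## Synthetic oracles

The saddle-node normal form x' = a − x², Euler-discretized with
dt = 0.01, is the end-to-end oracle: its fold sits exactly at a = 0 and
the maximal recovery rate from a within-basin perturbation is exactly
a·dt (attained at x = 0). The pipeline perturbation is placed at
x₀ = −0.6·√a: "just above" the unstable root −√a, but with enough
margin that additive noise of sd 0.002 does not eject realizations
across it (at −0.95·√a roughly a third of noisy realizations escape
and diverge). Because x₀ scales with √a, the recovery curves at
different a are rescalings of one shape and the extrapolated fold is
exactly 0 in the deterministic limit — the pipeline reproduces it to
±0.005 noise-free and ±0.02 at noise sd 0.002 with 100 realizations.
An AR(1) generator (stationary start) supplies series with known lag-1
correlation, variance and spectrum for the indicator suite.

What the generators do *not* emulate: observational error, unevenly
sampled or trending real-world series, multiplicative or correlated
noise, and spatial heterogeneity beyond nearest-neighbour coupling.
Passing tests demonstrate correctness of the machinery on systems with
known answers, not field-data performance.

## EWS indicator defaults

Rolling windows of half the series length (250 of 500), step 10,
within-window mean removal as detrending; all configurable. AR1 is the
lag-1 Pearson autocorrelation of the windowed series; STD the population
standard deviation; skewness and kurtosis the standardized third and
fourth moments, kurtosis in the Pearson convention (Gaussian → 3,
stated here because outputs depend on it). DFA: cumulative-sum profile
of the mean-removed series, non-overlapping boxes log-spaced in
[10, n/4] (12 sizes), order-1 detrending per box, exponent = slope of
the log–log RMS-fluctuation regression. Spectral reddening is defined
here as the ratio of mean periodogram power over the lowest 20% of
nonzero frequencies to the highest 20% (the name alone does not fix a
formula). Whether windows traverse time within one series or a
parameter sweep recorded as a series is up to the caller; both are
plain univariate series to `rolling_ews`. Indicator trends are
summarized externally (e.g. Kendall's tau); surrogate-based significance
testing is out of scope.

## Problem sizes and reproducibility

Default study conditions: 100 realizations per perturbation, 100-step
transients, 400-step recoveries, L = 100 lattices, 2000-sweep
calibration ramps; the full acceptance computation runs in about two
minutes on one CPU. All ensemble seeding derives from a single base
seed through `numpy.random.SeedSequence` spawning, so identical
configurations reproduce bit-identical results; the lattice inner loop
consumes pre-generated Generator draws, keeping the stream independent
of the jitted kernel.

## Known limitations

* Linear extrapolation from perturbations placed 1.5–2.5 fold-widths
  out systematically overshoots the fold by ≈ 10% of its magnitude
  (m(H) is mildly convex); the estimate lands beyond the innermost
  perturbation, on the far side of the true fold.
* The lattice transition fields used by the coupling calibration are
  ramp-rate dependent; the calibrated coupling inherits that bias.
* Within-bistable-region perturbations (amplitudes below the unstable
  equilibrium) give weak signals: reliable on the mean-field model,
  unreliable on the lattice, where the recovery deflections drown in
  endogenous noise — the warning path, not an accuracy promise, is the
  contract there.
* The per-step (non-√Δt) noise convention means σ is not comparable
  across different Δt choices.
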