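# Methods

## The model

Monotonically decaying kinetic curves of biological macromolecules — the
absorption recovery of photosynthetic reaction centers after switching off
excitation light, or chlorophyll fluorescence induction decays in
DCMU-blocked leaves — are modelled as a finite sum of decaying
exponentials with strictly positive amplitudes and rate constants,

    A(t) = sum_{i=1..n} a_i * exp(-k_i * t),      a_i > 0,  k_i > 0.

Each component is read as one quasi-stationary conformational state of the
macromolecular ensemble, so the positivity constraints are physical, not
merely numerical: a negative amplitude has no population interpretation and
is treated as evidence that a candidate component set is wrong. The rate
constants are called *decrements* here, following the kinetics usage.

The number of components `n` is not given in advance; selecting it is part
of the fit.

## The two reciprocal steps

**Weights by projection.** For a fixed set of decrements the basis
`phi_i(t) = exp(-k_i t)` is linearly independent but far from orthogonal.
With the inner product taken as the plain discrete dot product over the
sample grid, the optimal weights solve the normal equations `G a = beta`
with the Gram matrix `G_ij = (phi_i, phi_j)` and `beta_i = (x, phi_i)`;
equivalently they are inner products of the signal with the reciprocal
(biorthogonal) basis `theta_j = sum_k (G^-1)_jk phi_k`. Because this step
is a linear solve, the amplitudes never have to be searched — only the
decrements are free parameters. The solve is done by Cholesky
factorization, which is mathematically the same as applying `G^-1`.

Using the raw dot product rather than a quadrature rule makes the
projection exactly discrete least squares on the sample grid; on a uniform
grid the two differ by a constant factor that cancels in the normal
equations, so nothing is lost and the oracle equivalence with an
independent least-squares solve is exact.

**Decrements by discrete descent.** Decrements live on a logarithmic
candidate grid spanning `[0.1/T, 2/dt_min]` (slower rates are unresolvable
on a record of length `T`; faster ones decay within one sample), by default
50 candidates per decade. One component at a time, its decrement is swept
over all candidates, re-projecting *all* weights for each; candidates
producing any non-positive weight, or a Gram condition number above 1e12,
count as infinitely bad. Components are then revisited cyclically until
the dispersion stops changing. Components are added greedily: the new
component is optimized first with the others fixed, then everything is
refined.

**Dispersion.** The objective is the mean squared residual of the
peak-normalized signal (first-sample amplitude scaled to 1). With noise
quoted as a fraction of the initial amplitude, the dispersion of a correct
model estimates the squared noise level directly. Only the minimizer
matters for fitting; the normalization makes the number comparable across
signals.

## Escaping the pathologies of one-at-a-time descent

Two failure modes of the plain sweep were observed on synthetic data and
are handled explicitly:

* **Joint valley stalls.** The least-squares surface of multiexponential
  models has narrow curved valleys; one-decrement moves of a full grid step
  are uphill even when a correlated move of two decrements descends. After
  the cyclic sweeps converge, every *pair* of decrements is swept jointly
  over a window of ±4 grid steps around the incumbents, alternating with
  further cycles until nothing improves. On coarse grids this carries
  two-component fits to the exhaustive joint-grid minimum (verified against
  full enumeration of candidate pairs), which plain cyclic descent reaches
  in only ~70% of random problems.

* **Grid quantization.** A 50-per-decade grid has ~4.7% steps, so even the
  best on-grid decrement set misquotes a rate by up to ~2.3%, and a stall
  one step out doubles that. After the global stage converges, each
  decrement is re-swept on a local logarithmic grid spanning one global
  step around its incumbent, shrinking the local step fourfold per level;
  four levels bring the decrement resolution to ~0.02%. The decrement
  array remains discrete throughout — it is simply refined where the
  optimum lies. `local_refine_levels=0` restores the single-grid
  algorithm.

## Choosing the number of components

A stage with `n+1` components is accepted only if

1. some candidate admits an all-positive weight vector, and
2. its dispersion undercuts the accepted `n`-component dispersion by more
   than `improvement_tol` (relative), default **2%**.

The tolerance is the decisive constant. An added component fitted to pure
noise still lowers the mean squared residual by roughly (best-candidate
chi-squared)/N — a few parts in a thousand for records of a few thousand
samples — so any threshold well below that accepts noise components
forever. Conversely a component that carries percent-level amplitude,
the smallest the method claims to resolve, reduces the dispersion by tens
of percent at realistic noise. The default sits between the two regimes,
of the same order as the method's quoted ±2.5% decomposition accuracy.
It presumes records of roughly a thousand samples or more; for very short
records the noise-chasing gain (~10/N) approaches 2% and the threshold
should be raised.

Four further guards: the component cap (7; the method is meant for fewer
than 8 exponents); a dispersion floor (1e-10, i.e. normalized RMS 1e-5,
far below any physical amplitude precision) under which the fit counts as
exact; a minimum component weight (1% of the summed weights — the smallest
decomposition the method is claimed for carries ~3%, while ghost
components chasing residue enter at a fraction of a percent); and a
minimum separation ratio (1.2) between decrements — two
exponentials with nearly equal rates are not distinct kinetic states, and
on short or quantization-limited records such pairs slip past the
conditioning guard and soak up sub-noise residue (a pure single-exponential
record happily "improves" by splitting into rates 3.0006 and 2.9992 1/s
without the rule). Candidates closer than that factor to a fixed decrement
are skipped exactly like collisions.

Refinement revisits components in their stored order (decrement
descending) rather than order of addition; the fixed point of the cyclic
descent does not depend on the visiting order, only the path does.

## Synthetic data

The generator evaluates the model forward on a uniform grid and adds
i.i.d. Gaussian noise with standard deviation quoted as a fraction of the
initial amplitude — the simplest model of photometric detection noise.
Published three-component parameter sets for four winter-wheat genotypes
(Pdl, Per, Ods, Dos; weights 59/29/7 … 77/22/4 percent of initial
amplitude, rates 400/87/11 … 370/71/13 1/s) ship as fixtures; their
default grid, t ∈ [0, 0.5] s with dt = 0.25 ms (2001 samples), covers
more than five lifetimes of the slowest published rate and resolves the
fastest. The printed weight percentages are used verbatim as fractions
without renormalizing (they do not sum to 100 in the source because of
rounding).

What the generator does *not* emulate: correlated or signal-dependent
(Poisson) noise, baseline drift and offsets, instrument response, and the
full photophysics of fluorescence induction (OJIP transients) or
reaction-center photocycles. Passing recovery tests therefore demonstrate
the estimator's behaviour under ideal additive white noise, not robustness
to real-instrument artefacts; signals with a non-zero baseline must be
baseline-corrected before fitting, since the model contains no constant
term.

## Accuracy in context

At 0.5% additive noise on the Pdl parameter set, the recovered rate
constants match the generating values to within a couple of percent — and,
realization by realization, to within ~0.03 percentage points of an
independent continuous nonlinear least-squares fit started at the truth.
The residual scatter across noise realizations (roughly 0.4–6% maximum
rate error) is thus the statistical information limit of three-exponential
fitting at that noise level, not optimizer error. Any single quoted
accuracy figure for such a fit is therefore tied to a specific noise
realization; the acceptance script pins the realization it reports on.

## Numerical choices

* Gram matrices are symmetrized explicitly (`(M + M^T)/2`), so symmetry
  holds exactly as computed; condition numbers come from the SVD of the
  (at most 7×7) matrix.
* Candidate bases with condition above 1e12 are invalid rather than
  errors; the sweep simply skips them. `project_weights` raises on such
  bases when called directly.
* Sweep ties break toward the smallest decrement (ascending scan, strict
  improvement), making the whole fit deterministic; the only randomness in
  the package lives in the synthetic generator's seed.
* Candidates colliding with a fixed decrement (relative distance ≤ 1e-9)
  are skipped — equal decrements make the Gram matrix exactly singular.
* A sweep keeps the incumbent decrement when no candidate strictly beats
  it, so refinement cycles are non-increasing by construction.
* Fits require at least `2 * max_components + 1` samples and a strictly
  positive first amplitude; signals that do not decay overall produce a
  warning (lenient mode) or an error (strict reader mode).

## Problem sizes used in the test suite

Property suites run on 201–1001-point grids with candidate grids of 17–30
points per decade and up to 100 seeded random problems per invariant; the
published-fixture checks use the full 2001-point default grid. These sizes
keep every statistical check well-powered for the stated tolerances.

## Known limitations

* No uncertainty quantification on the recovered `(a_i, k_i)`; the stage
  trace is diagnostic, not inferential.
* No constant-offset term; baselines must be removed beforehand.
* Nearly equal rate constants (ratio below ~2) are fundamentally hard for
  any exponential decomposition; here they are usually absorbed into one
  component or rejected by the conditioning guard.
* The greedy order selection is calibrated for records of ≥ ~1000 samples
  at noise ≤ ~1% of the initial amplitude — the regime of the digitized
  kinetic curves the method targets.
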