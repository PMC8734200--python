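# Methods

## Model

Observations are `y_i = f(x1_i, x2_i) + ε_i`, `ε ~ N(0, σ²)`, with a
zero-mean GP prior on the latent surface `f` and the product logarithmic
squared-exponential kernel

```
k(x, x') = σ_f² exp( −½ Σ_{i=1,2} (log(1 + x_i/l_i) − log(1 + x'_i/l_i))² ).
```

The warp `u_i = log(1 + x_i/l_i)` handles dose 0 exactly; for doses far
below `l_i` the kernel is numerically indistinguishable from the linear SE
kernel (they agree to < 1e−8 for doses ≤ l/1000), and far above it depends
on log-dose ratios. Posterior mean and variance on the prediction grid are
exact Gaussian conditionals computed by Cholesky factorization with a
relative jitter of `1e−8·σ_f²` on the Gram diagonal (replicate wells make
the unjittered matrix exactly singular). Zero prior mean implies reversion
toward response 0 far outside the data — for inhibitory data this is "full
effect", which is also how monotherapy curves are extrapolated (below).
Surface plots and the default effect CIs use the latent (noise-free)
predictive `f*`; the observation-level variance `f* + σ²` is available via
`PosteriorSurface.predictive_variance(observation_noise=True)`.

## Priors and the constant c

Independent Gamma(shape, rate) priors, moment-matched:

| hyperparameter | mean | variance | notes |
|---|---|---|---|
| length scale `l_i` | `c·Dmax_i` | `0.1·(c·Dmax_i/2)` | `Dmax_i` = max design dose |
| amplitude `σ_f` | `E_obs/2` | `0.1·(E_obs/2)` | `E_obs` = observed response range |
| noise variance `σ²` | Gamma(2, 1) on percent scale; Gamma(0.14, 1.14) on fraction scale | | |

The amplitude prior is placed on the standard deviation σ_f (one of the
model's four hyperparameters), so that the GP can a priori swing across
about half the observed effect range; placing the same numbers on σ_f²
pins the amplitude to ~7 response units on percent data and the surface
grossly underfits (this was checked empirically: surface MSE ~267 vs ~18 on
the same benchmark data).

`c` rescales the length-scale prior relative to the dose range and encodes
how strongly the response changes over the design. The automatic rule used
by the pipeline sets `c = min/max` of the monotherapy responses, clipped to
[1e−3, 1]: flat data give `c ≈ 1` (length scale ≈ dose range, almost linear
warp), strongly responding data give small `c` (genuinely logarithmic warp).
The opposite ratio (max/min > 1) was rejected empirically — it lengthens the
length scales exactly when the response varies most, over-smoothing the fit
and biasing the synergy score positive. For the plain SE comparison kernel
(no warp) auto-`c` is 1: its length scale is the smoothness scale directly.

## Inference

The posterior over `φ = (log σ², log σ_f, log l1, log l2)` (Gamma priors
transformed with the Jacobian absorbed) is sampled with leapfrog HMC:
identity mass matrix, 5 leapfrog steps, default 1000 burn-in and 100,000
samples, target acceptance 75%. The step size is the largest value from the
log-spaced grid {0.01, 0.02, 0.03, 0.05, 0.08, 0.1, 0.2, 0.3, 0.6, 1.0}
whose 200-iteration pilot chain reaches the target acceptance (largest-first
search; smallest value with a recorded warning if none reaches it).
Trajectories with Hamiltonian error > 1000 count as divergences; a rate
above 5% is flagged. Gradients of the log marginal likelihood are the
standard trace identities; for complete checkerboards the Gram matrix
factorizes as a Kronecker product over the two dose axes, and all
determinants, traces and quadratic forms are computed from two per-axis
eigendecompositions (O(m³) per axis instead of O((m1·m2)³) overall), which
makes full-length chains on 11×11 designs take seconds. Summaries: 95% HPD
intervals (shortest sorted window), split-R̂ on the single chain, and the
posterior-mean hyperparameters, which are plugged into one exact GP predict
(plug-in rather than full predictive averaging; with 36–121 well-identified
observations the hyperparameter posterior is narrow and the difference is
far below the effect CIs). A deterministic MAP mode (multi-start L-BFGS-B on
the same log posterior) is the default for interactive use and screens.

## Hand null construction

Monotherapy curves `f1, f2` are the GP posterior-mean slices at the other
drug's dose 0, tabulated on the prediction grid and extended to twice the
warped dose range: at the high-dose corner the construction needs combined
equivalent doses beyond `Dmax`, and without the extension the null saturates
at `f(Dmax)` and acquires a systematic pro-synergy volume bias (≈ +400
response·dose² on noiseless additive 6×6 benchmarks; < 20 with it).

Because GP means can be mildly non-monotone (micro-wiggles, bumps near dose
0, upturns at the top of the range), the inversion table is the curve's
*monotone envelope*: the record extrema in its dominant direction. Wiggles
are bridged by interpolation between records; effects or doses beyond the
last record clamp there and the affected grid nodes are flagged. A curve
with no usable envelope (essentially constant) raises an error. Curves that
disagree at dose 0 by more than 1% of the effect range trigger a warning and
the average starting effect is used.

At grid node `(i, j)` the partition counts are `N1 = i`, `N2 = j` (grid
points in `(0, x_i]`; nearest-node ties break toward the lower index) and
`N = max(N1, N2)` alternating rounds are run, each applying a drug-1 step of
`x1/N` then a drug-2 step of `x2/N`, every step mapping
`E ← f_i(f_i⁻¹(E) + step)`. The returned value is the **average of the
drug-1-first and the drug-2-first pass**: a single alternating pass carries
an O(1/N) ordering bias (measured ≈ 0.06 response units at N = 200 on
asymmetric Hill pairs), whereas the symmetrized construction is exactly
commutative under drug swap (the swap just exchanges the two averaged terms)
and the leading splitting error cancels. Each pass is still the plain
alternating schedule, and both passes converge to the same Hand limit.
Associativity holds for the ideal (infinitesimal) model but is not asserted
numerically. Sham combinations (a drug against itself) reproduce `f(x1+x2)`
to < 0.5% of the effect range at N = 100; on additive (interaction-free)
surfaces the Hand null matches the implicit Loewe isobole solution to < 1%
of the effect range.

## Synergy scoring

Effect = `null − fit` for inhibitory data (`fit − null` for stimulatory), so
positive always means synergy. The per-node 95% CI is `effect ±
1.96·√(latent fitted variance)`: the null is treated as fixed because it is
built from the same posterior's monotherapy slices and double-counting would
inflate the bands. Volumes are computed by Delaunay triangulation of the
grid nodes in linear dose units (Σ triangle area × mean vertex value — exact
for piecewise-planar surfaces); the volume difference equals the volume
under the effect surface by linearity, and its CI comes from integrating the
effect bounds. A design-dose call is `additive` iff 0 lies inside the
node's effect CI, and the overall call applies the same rule to the volume
difference interval.

## Synthetic data generator

Ground truth follows the interaction-isobole family
`d1/D1(E) + d2/D2(E) + α·d1·d2/(D1·D2) = 1` with shared-asymptote Hill
monotherapies (`D_i` = inverse Hill dose), solved for E by bisection to
1e−10; `α = 0` is exact Loewe additivity, `α > 0` synergy, `α < 0`
antagonism. Defaults: 6×6 design [0, 2, 5, 10, 20, 50] × [0, 0.2, 0.5, 1,
2, 5], percent-scale inhibitory Hill curves (E0 = 100, Emax = 0, h = 1.2,
C = 10 and 1), α = 0.5, and i.i.d. Gaussian noise with sd 1.5 — the level
consistent with the Gamma(2, 1) percent-scale noise-variance prior
(variance ≈ 2). Note the family is asymmetric in α: on this design the true
volume-difference signal is +808 at α = +2 but −4078 at α = −0.5, because
positive interaction saturates where the response is already low.

What the generator does **not** emulate: plate/row effects, heteroscedastic
or proportional noise, non-Hill monotherapies, partial-agonist asymptote
mismatches, and replicate correlation. Passing the calibration suites
therefore shows correctness of the machinery under clean Loewe-type
conditions, not robustness to all real screen artifacts.

## Simulation study sizes

Chosen once for routine runs and reported with the suite:

- Null calibration and direction recovery: 50 seeded replicates per
  interaction level (α = 0, +2, −0.5), reduced HMC (500 burn-in, 5000
  samples), 51-node grid.
- Hyperparameter HPD coverage: 60 replicates of 11×11 GP-sampled surfaces
  with θ drawn from the prior each replicate (the self-consistent Bayesian
  coverage design), reduced HMC; ≥ 85% componentwise coverage required.
- Bootstrap coverage: 120 replicates × B = 300 refits (refits start from the
  point estimate), checking E0 and C interval coverage ∈ [0.90, 1].

## Numerical choices and edge cases

- Grid: 101 nodes per axis by default, uniform in the warped coordinate,
  with every design dose snapped onto the nearest node (so observed points
  always have exact prediction nodes and partition counts are well defined).
- Replicated wells are independent observations; they disable the Kronecker
  fast path but not the dense one.
- MuSyC responses are computed by solving the four-state balance equations
  directly (rows scaled by their max for conditioning), which reduces
  exactly to Hill curves on the monotherapy edges; fits run bounded
  least-squares in log-space for h, C, α, γ with Hill-fit-derived starts;
  the constrained null fixes α12 = α21 = γ12 = γ21 = 1 and β = 0
  (E3 = min(E1, E2)). β is derived from the state effects, and no CIs are
  produced for null-model-derived summaries.
- Hill fit bounds default to E0, Emax ∈ [0, 1.1·max response], h ∈ [0.1,
  10], C ∈ [min positive dose/10, 10·max dose]; constant data return a
  boundary fit with (bootstrap) intervals reflecting the non-identifiability.

## Known limitations

- The effect CI ignores null-surface and hyperparameter uncertainty; under
  strong model misspecification it can undercover.
- Corner regions whose combined equivalent dose exceeds the extended curve
  domain clamp at the envelope end (flagged per node).
- The score is conservative under very strong synergy with noisy small
  designs: interior wells pull the fitted monotherapy edges down, which
  lowers the null. 6×6 or denser designs are recommended; 4×4 designs are
  flagged as small by the screen command.
- Single-chain R̂ only; no mass-matrix adaptation (the log-space geometry of
  these 4-parameter posteriors has not required it).
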