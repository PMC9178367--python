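# Methods

## Model and assumptions

The package simulates a pool of N species on a connected graph of patches.
Within each patch p the community follows generalized Lotka–Volterra
dynamics with logistic self-regulation and a patch-specific random
interaction matrix A⁽ᵖ⁾; between adjacent patches species move by
diffusion through the graph Laplacian with spacing h (default 1). The
model is deterministic: there is no demographic or environmental noise,
and extinction is a bookkeeping threshold (density < 10⁻⁵), not a
dynamical removal — densities are never zeroed during integration beyond
clamping numerically negative excursions to zero.

A *habitat* is an interaction matrix; a *patch* is a node of the spatial
graph. Several patches may share one habitat. Habitat matrices have zero
diagonal (self-regulation lives in the logistic term), connectance c
(off-diagonal entries present independently with probability c), and
present entries drawn from N(μ, σ²). A_ij and A_ji are sampled
independently: no symmetry or trophic pairing is imposed, matching the
unstructured random-matrix setting in which σ√(cN) is the complexity
parameter.

## Correlated habitat ensembles

Three cross-habitat structures are generated, each the minimal Gaussian
construction realizing its correlation exactly:

- **independent** — masks and entries drawn afresh per habitat.
- **equicorrelated** — one shared mask; per present position, habitat g
  gets μ + σ(√ρ·z₀ + √(1−ρ)·z_g) with z₀ shared and z_g per-habitat
  standard normals, so every habitat pair has correlation exactly ρ.
- **nn_chain** — one shared mask; per present position a stationary AR(1)
  chain x_{g+1} = ρ_nn x_g + √(1−ρ_nn²) ε_g along the habitat index, so
  correlation decays as ρ_nn^lag.

Correlated ensembles share a single presence mask (an interaction present
anywhere is present everywhere); independent ensembles redraw the mask per
habitat, which is what produces the μ²(1−c) presence-mixture term in the
independent-case variance formula. Mask presence is i.i.d. Bernoulli(c)
per off-diagonal entry, not an exact count, for the same reason.

Randomness is organized as one root `SeedSequence` per ensemble with one
spawned child stream for shared structures (mask, latent factor) and one
per habitat, so enlarging G extends an ensemble without perturbing the
habitats already drawn. Changing N redraws all positions; per-position
streams were judged not worth N² generator objects.

## Numerical integration

The stacked system (patches × N equations) is stiff at high dispersal
(fast diffusive modes next to slow ecological ones), so it is integrated
with the implicit BDF method and an analytic sparse Jacobian: per-patch
dense N×N blocks plus the Kronecker coupling of the graph Laplacian with
diag(D). Integration proceeds in geometrically growing time chunks
(25, 50, 100, …, capped by t_max); after each chunk negative densities are
clamped to zero and stationarity is declared when max|dφ/dt| falls below
`residual_tol`. Defaults: rtol 10⁻⁶, atol 10⁻⁹, residual_tol 10⁻⁹,
t_max 10⁴. Reaching t_max first returns `converged=False` rather than
raising, because strongly interacting regimes genuinely oscillate or
wander chaotically.

**Runaway growth.** Below the coherent regime, zero-mean random
interactions at σ√N > 1 can form positive feedback loops that beat
logistic self-limitation, and single trajectories escape to infinity in
finite time. A density crossing 10⁶ is treated as divergence: by default
an error with diagnostics; inside the dispersal ladder and the experiment
drivers it is a flagged outcome (`diverged=True`, excluded from summary
statistics), since raising dispersal — which averages habitats and shrinks
the effective spread — is exactly the regime change that removes it.

**Dispersal policy.** The coherent regime is defined by its outcome (equal
densities across patches), not by a dispersal value, so
`integrate_adaptive_coherent` raises D from 1 in decade steps until the
maximum relative cross-patch spread of extant species drops below 10⁻³,
up to five decades (D = 10⁵; 32-patch landscapes need the fifth decade).
Because the spread scales like 1/D once coherent, the ladder jumps
directly to the decade predicted to meet the tolerance instead of visiting
every rung, warm-starting each integration from the previous equilibrium
(nudged off zero so extinct species can re-enter). A coherent but
non-stationary state ends the ladder immediately: more dispersal cannot
make an oscillating community stationary. The achieved D is reported with
every run.

Initial conditions, unless supplied, are i.i.d. uniform on [0.1, 1] per
species and patch from the run seed — strictly positive and unbiased
across species.

## Effective system and its moments

The effective matrix Ā is the *patch-multiplicity-weighted* mean of the
habitat matrices (a habitat on three patches counts three times); when
every patch has its own habitat this is the plain habitat average. μ̄ and
σ̄ are computed over all off-diagonal positions (structural zeros
included) for independent-mask ensembles and over the shared masked
positions for correlated ensembles, matching the position sets over which
the respective closed forms are derived. All closed-form functions return
variances; standard deviations are derived, never stored separately.

The printed independent-case formula equates Var(Ā_ij) to a quantity
labelled as a standard deviation; it is treated as a variance here, since
its c = 1 reduction must agree with the equicorrelated formula at ρ = 0,
which is unambiguous a variance.

## Experiments and the synthetic-data conditions

The experiment drivers fix the study conditions:

- **independent_sweep** — N = 50, c = 1, μ = 0, σ = 1.25/√N (May
  complexity 1.25: above the single-habitat full-coexistence limit, below
  collapse), one habitat per patch on the most-square grid with exactly G
  patches (chain when G is prime; topology is immaterial once coherent).
- **grid_heterogeneity** — 3×3 grid, H ∈ {1…9} equicorrelated habitats
  scattered by a uniformly random *surjective* patch assignment (every
  habitat occupies ≥ 1 patch, otherwise H would not be realized),
  ρ ∈ {0.2, 0.5, 0.8}, μ ∈ {0, −0.5}. The local σ again sets complexity
  1.25; the reference study states only N and μ for this design, so the
  same regime as the independent sweep is used. The acceptance checks run
  a scaled pool of N = 50 (from 100) with 10 realizations per cell
  (from 50) to fit a single-CPU budget.
- **nn_chain** — one habitat per patch of a 1-D chain, AR(1)-correlated.
- **coherence_scan** — one fixed heterogeneous 3×3 ensemble simulated at
  D ∈ {1, 10, 100, 1000} against its effective system.

Experiment drivers use residual_tol 10⁻⁷ and t_max 6000: richness at the
10⁻⁵ threshold is insensitive to residuals below ~10⁻⁷, and runs not
stationary by t = 6000 are overwhelmingly oscillatory, not slow. Flagged
(non-convergent or divergent) runs stay in the raw tables and are excluded
from summary means, which concern coherent stationary states; their count
is reported per sweep cell.

Every run's generator is keyed by the root seed plus its sweep coordinates
(G/H, ρ, μ, replicate index), so tables are bit-reproducible and extending
a sweep preserves existing rows.

"Significantly positive relationship" between habitat count and richness
is operationalized as a positive Spearman rank correlation across the
sweep's cell means — a repo convention; the reference analysis reports no
test statistic.

## What the generator does and does not emulate

The synthetic ensembles realize exactly the statistical conditions the
theory assumes: Gaussian entries, exact equicorrelation or AR(1) decay,
Bernoulli presence. Real interaction webs have structure the model
excludes by design — trophic sign pairing, modularity, non-Gaussian heavy
tails, connectance varying in space, and stochastic colonization/
extinction. Passing tests therefore validate the mathematics of the
averaging mechanism, not the claim that any particular field system sits
in its regime.

## Known limitations

- Equilibria found by forward integration depend, in multi-stable regimes,
  on the initial condition and on the dispersal ladder's path; only the
  statistical behavior over seeds is meaningful there.
- The coherent reduction is exact only as D → ∞; at the ladder's stopping
  spread (10⁻³) the density agreement with the effective system is of
  order 10⁻³–10⁻², not machine precision.
- Oscillatory and chaotic regimes are detected and flagged, never
  analyzed; richness in those regimes would need a time-averaged
  definition the package does not implement.
- One-dimensional analytic coherence proofs are out of scope; the
  reduction is verified numerically (identical-habitat identity, 1/D
  convergence of the discrepancy).
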