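# metaglv

**Generalized Lotka–Volterra metacommunities with diffusive dispersal:
how spatial heterogeneity in species interactions sets global richness.**

Large contiguous landscapes (a tropical forest basin, a long environmental
gradient) are rarely homogeneous: the strength of competition between any
two species varies from place to place with temperature, soil, and other
abiotic conditions. When dispersal between patches is high, each species'
density becomes nearly equal everywhere (*spatial coherence*), and the
whole heterogeneous landscape behaves like a single well-mixed community
whose interaction matrix is the **spatial average** of the local ones.
Averaging cancels interaction differences, so heterogeneity *lowers* the
effective complexity of the metacommunity and *raises* the number of
species that coexist. This package implements that model end to end, for
theoretical ecologists studying diversity maintenance in random-matrix
(May-type) communities.

## Model

Species densities φ_{i,p} on a patch graph follow GLV dynamics with
discrete-Laplacian dispersal (zero-flux boundaries, spacing h = 1):

    dφ_{i,p}/dt = r_i φ_{i,p} (1 − φ_{i,p}/K_i)
                  + φ_{i,p} Σ_j A⁽ᵖ⁾_{ij} φ_{j,p}
                  + D_i Σ_{q∼p} (φ_{i,q} − φ_{i,p}) / h²

Each habitat's A is a random matrix: zero diagonal, connectance c, nonzero
entries ~ N(μ, σ²); σ√(cN) is the May complexity. r_i = K_i = 1 by
default, and a species is extinct when its density falls below 10⁻⁵.

In the high-dispersal (coherent) limit the system reduces to a single GLV
community with the patch-averaged matrix Ā. The entry variance of Ā has
closed forms by correlation structure across G habitats:

- independent habitats: Var(Ā_ij) = (c/G)(σ² + μ²(1−c)) → 0 as G → ∞
- equicorrelated (pairwise ρ): Var(Ā_ij) = (σ²/G)(1 + (G−1)ρ) → ρσ²
- nearest-neighbor chain (ρ_nn^|g−g′|):
  Var(Ā_ij) = σ²(G + 2 Σ_η ρ_nn^η (G−η))/G² → 0

Since richness of a random GLV community is set by the spread of its
interaction matrix, these formulas predict when adding habitats keeps
buying species and when richness hits a correlation-imposed ceiling.

## Worked example

```python
import numpy as np
from metaglv import (CommunityParams, CorrelationSpec, sample_ensemble,
                     build_landscape, grid2d, integrate_adaptive_coherent,
                     effective_matrix, global_richness, moments_independent)

N = 50
params = CommunityParams(N=N, c=1.0, mu=0.0, sigma=1.25 / np.sqrt(N))
ensemble = sample_ensemble(9, CorrelationSpec("independent"), params, seed=42)
landscape = build_landscape(grid2d(3, 3), np.arange(9))  # one habitat/patch

eq, D = integrate_adaptive_coherent(landscape, ensemble, params, seed=7)
n, rel = global_richness(eq, params)
eff = effective_matrix(ensemble, landscape)
print(f"richness {n}/{N} at D={D:g}, spread {eq.max_coherence_spread:.1e}")
print(f"sigma_bar: measured {eff.sigma_bar:.4f}, "
      f"theory {moments_independent(1.0, 0.0, params.sigma, 9).sigma_bar:.4f}")
```

prints

```
richness 50/50 at D=10000, spread 4.2e-04
sigma_bar: measured 0.0584, theory 0.0589
```

A single habitat at this complexity (σ√N = 1.25) typically keeps only
28–40 of the 50 species; nine independent habitats under coherent
dispersal shrink the effective interaction spread by 1/√9 and here carry
all 50 — heterogeneity rescued the rest of the pool. The analysis scripts sweep this systematically:

```
python analysis/01_theory_moments.py           # closed forms vs Monte Carlo
python analysis/02_coherence_scan.py           # coherence & reduction vs D
python analysis/03_independent_habitat_sweep.py  # richness vs G, saturation at 1
python analysis/04_grid_heterogeneity.py       # 9 patches, H habitats, rho sweep
python analysis/05_nn_chain.py                 # AR(1)-correlated habitat chain
```

Each writes tidy CSV tables under `results/`. A thin CLI (`metaglv
generate|simulate|theory|experiment`) wraps the same library calls.

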