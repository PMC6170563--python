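# econetres

Does the resilience of mutualistic plant–animal networks track environmental
change?  `econetres` implements the full analysis chain used to ask that
question at macroecological scale: it scores each bipartite pollination or
seed-dispersal web with the macroscopic resilience parameter β_eff, computes
historical climate-change velocities from paired current / Last-Glacial-
Maximum climate grids, and regresses resilience on climate, human footprint
and network size with the spatially explicit protocol standard in the field
— exact Moran tests on OLS residuals, Moran-eigenvector (SEVM) spatial
filtering, all-subsets AICc selection and 95%-confidence-set model
averaging.  It is aimed at ecologists who want a tested, scriptable version
of that pipeline, plus a synthetic-data generator that makes every stage
verifiable without any external downloads.

## The quantities at the core

For a binary incidence matrix `M` (n plants × m animals), each side is
projected onto a weighted one-mode network by summing inverse degrees of
shared partners (plant side shown):

    A_ij = Σ_k M_ik M_jk / Σ_s M_sk

and resilience is the single macroscopic parameter

    β_eff = Σ_ij A_ij A_ji / Σ_ij A_ij

Climate-change velocity at a site is the temporal climate gradient
(|current − LGM|) divided by the local Horn slope of the current climate
surface, in km.  The regression step fits standardized log β_eff on nine
candidate terms (richness, elevation, T_mean, T_seasonality, P_ann,
P_seasonality, human footprint, T_velocity, P_velocity); when the exact
Moran test finds residual spatial autocorrelation (p < 0.05), a Moran-
eigenvector filter is selected, held fixed, and the selection/averaging is
repeated under SEVM.  See `docs/methods.md` for all conventions.

## Worked example

```python
import numpy as np
from econetres import IncidenceMatrix, project, beta_eff

web = IncidenceMatrix(("p1", "p2"), ("a1", "a2", "a3"),
                      np.array([[1., 1., 0.], [0., 1., 1.]]))
plants = project(web, "plant")
print(plants.A)                      # [[1.5 0.5]
                                     #  [0.5 1.5]]
print(beta_eff(plants).beta_eff)     # 1.25
```

Animal `a2` is shared by both plants and has degree 2, so it contributes
1/2 to the off-diagonal coupling; β_eff = (2·1.5² + 2·0.5²)/(2·1.5 + 2·0.5) = 5/4.

The full study runs as four scripts from the repository root:

```bash
python analysis/01_simulate_studies.py --seed 1   # 62- and 30-site synthetic studies
python analysis/02_network_resilience.py          # beta_eff per site network
python analysis/03_climate_velocity.py --seed 1   # velocities from synthetic rasters
python analysis/04_fit_models.py                  # OLS/SEVM model tables
```

which prints, for seed 1:

```
pollination: 62 sites, richness 19-65, mean connectance 0.32 -> results/synthetic/pollination
...
62 sites; temporal gradient 40.0 everywhere; velocity median 1195 km (range 866-2306)
pollination/beta_eff_plant: OLS only; OLS Moran I=0.03 (p=0.10); best model ('richness', 't_mean', 't_velocity') R2=0.87
seed_dispersal/beta_eff_plant: SEVM triggered; OLS Moran I=0.09 (p=0.02); best model ('richness', 't_velocity') R2=0.74
```

The simulated studies link animal richness to T_velocity, so the best models
recover richness and T_velocity as predictors of plant-side β_eff; in the
30-site study the residuals are spatially autocorrelated (Moran's I = 0.09,
p = 0.02), triggering the SEVM branch, whose post-filter Moran test is
non-significant.  Coefficient tables in the published layout (estimate with
bracketed p for full/best/averaged models, plus Moran's I and R² rows) land
under `results/synthetic/<study>/models/`.

## Layout

    src/econetres/      library: bipartite_io, resilience, climate_velocity,
                        spatial, model_selection, synthetic_data, pipeline
    analysis/           numbered study drivers (thin wrappers over the library)
    tests/              pytest suite, including end-to-end checks
    scripts/            acceptance.py
    docs/methods.md     models, conventions, numerical choices, limitations
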