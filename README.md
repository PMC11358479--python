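# paleodisp

Climate-forced population dispersal modelling for palaeodemography: a
niche-model-driven simulator that reconstructs dispersal chronologies,
population sizes, mobility and flux networks for a prehistoric
techno-complex from archaeological site records and gridded palaeoclimate
predictors.

## Who this is for

Researchers combining archaeological site catalogues with palaeoclimate
reconstructions to ask *where and when* a human population could have
spread: the package estimates a habitat-suitability surface from
presence/absence data, turns it into a time-varying demographic forcing,
and integrates a population continuity equation over millennia on a
longitude–latitude grid.

## The model

**Human existence potential (HEP)** has three layers:

1. *Environment HEP* Φ_E ∈ (0,1): a quadratic logistic regression on four
   standardized bioclim predictors P = (T_m, T_δ, R_m, R_δ) — annual mean
   temperature, temperature seasonality, wettest-month precipitation,
   precipitation seasonality:

       q(P) = ½ PᵀA P + B·P + C,   Φ_E = 1 / (1 + e^(−q))

   fitted to presence cells (grid cells holding ≥1 site; stacked sites
   collapse to one record), a-priori absence cells (site-free cells whose
   climate is outside the habitability envelope: T_m ∉ [−2, 16] °C or
   R_m ∉ [30, 250] mm) and probabilistically labelled pseudo-absence cells.
   An ensemble of refits on random 80% subsamples carries the uncertainty;
   validation uses the Brier Skill Score against the intercept-only model
   and the ROC AUC on held-out 20% splits.

2. *Accessible HEP* Φ_Ac = Φ_E · g_ele · g_std · g_wat · … · g_x, with
   unit-interval modifiers for terrain elevation, sub-grid roughness and
   water bodies, and sets the local carrying capacity ρ_c = ρ_c,max Φ_Ac.

3. *Available HEP* Φ_Av = ρ_c · w(ρ/ρ_c)/w_max, a Weibull-density transform
   of the density-to-capacity ratio (scale ε, shape η) expressing mutual
   support at low density and population pressure at high density. With
   ε = 0.4, η = 1.6 it peaks at ρ ≈ 0.2 ρ_c.

**Population dynamics.** Density ρ (persons / 100 km²) obeys

    ∂ρ/∂t + v·∇ρ − D∇²ρ = r ρ (1 − ρ/ρ_c),   dv/dt = α∇Φ_Av − γ v

with velocity-scaled diffusivity D = κ·l·σ_v clipped to [10, 100] km²/yr
and growth rate r = r_max Φ_Av / ρ_c,max. Stadial/interstadial (GS/GI)
climate end members are blended in time by a normalised δ¹⁸O proxy series
(20-yr steps). The solver is a conservative finite-volume scheme (upwind
advection, centered diffusion, no-flux coasts) split with an exact
per-cell logistic growth step; it conserves transported population to
rounding and preserves positivity.

Diagnostics include the total population Λ = Σ ρ·s, the mobility index
M = Σ|f| with population flux f = vρ − D∇ρ, first-arrival maps at
0.4 P / 100 km², occupation contours at 1 P / 100 km², and chronology
tables against dated sites. Perturbed-parameter ensembles (ρ_c,max, α, D;
5×5×5 full factorial by default) quantify arrival-time uncertainty.

A synthetic-data module generates all inputs (paired GS/GI bioclim
rasters, site catalogues sampled from a known truth niche model, periodic
isotope series, topography and land mask), so the whole pipeline runs and
is tested without any download.

## Worked example

```python
from paleodisp import run_synthetic_reconstruction, arrival_time_map

art = run_synthetic_reconstruction(n_members=20, duration_yr=1000.0, seed=42)
print(art.niche_ensemble.summary())
print(art.result.summary())
amap = arrival_time_map(art.result, threshold=0.4)
print(f"cells reached: {int(amap.reached().sum())} of {int(art.mask.land.sum())} land cells")
```

prints

```
Niche ensemble: 20 members, BSS=-0.017, held-out AUC=0.508 (member s.d. 0.041)
Dispersal run 45.00 -> 44.00 ka: 101 snapshots, Lambda 5000 -> 658 persons (max 5305)
cells reached: 353 of 1200 land cells
```

Reading the output: the ensemble's held-out skill is near chance *by
construction of this demo scenario* — under the stringent pseudo-absence
option, site-free cells of a broadly habitable synthetic domain are
labelled presence/absence at the catalogue base rate, so the labels carry
little climatic signal and the fitted Φ_E shrinks toward that base rate
(the behaviour expected of the most conservative labelling choice).  The
dispersal run starts from 5 000 people seeded near (6°E, 44°N); the
population grows to ≈5 300 during the opening interstadial, then the
square-wave stadial (a −12 °C excursion) pushes the northern half of the
domain outside the habitability envelope and the total collapses toward
the southern refugium — 353 cells saw a density of at least
0.4 P / 100 km² at some point.  `NicheLogistic(...).fit()` exposes the
statsmodels-style coefficient table via `summary()`, and
`DispersalModel(...).run(...)` returns the `RunResult` used above.

A command-line interface mirrors the pipeline
(`paleodisp synth | hep-train | simulate | ensemble | diagnose`, each
driven by one validated YAML config).

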