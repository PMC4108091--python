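# endemicity

Analysis toolkit for continental-scale biogeographic pattern in species ×
ecoregion occurrence data, built around three linked questions:

1. **Which areas share a faunal history?** Parsimony Analysis of Endemicity
   (PAE) treats areas (e.g. freshwater ecoregions) as taxa and each species'
   presence/absence as a binary character. A hypothetical area in which every
   species is absent roots the trees and polarises presence as the derived
   state, so the most-parsimonious "area cladogram" groups areas that share
   restricted-range species — candidate areas of endemism.
2. **Does climate cap richness?** A constraint-envelope (Boundary Sum of
   Squares) test: the observed ranges of richness *S* and an environmental
   variable *x* delimit a rectangle; a right triangle spanning it (lower-right
   when the ceiling rises with *x*, lower-left for variables like altitude)
   defines a candidate boundary. The statistic is the mean distance of points
   outside the triangle from its hypotenuse; an unusually *small* value —
   judged against a permutation null with `p = (1 + #{null ≤ obs})/(1 + N)` —
   means the cloud presses against an upper limit rather than following a
   line.
3. **What predicts richness?** OLS multiple regression
   `S = β₀ + β₁·log(area) + β₂·altitude + … + ε` over eight standard
   correlates (log area, altitude, six bioclimatic summaries), reported as a
   coefficient table with the model F, p, and adjusted R².

A synthetic-data module plants known area cladograms (species as clade
synapomorphies plus occurrence noise), triangular constraint envelopes, and
species–area power laws (`S ≈ c + z·ln A`), so each stage is
recovery-testable without any external dataset.

## Worked example

```python
import endemicity as e

# plant an 8-area cladogram; 60 species mark its clades, with noise
truth = e.synthetic_truth(n_areas=8, seed=11, false_presence_rate=0.01,
                          false_absence_rate=0.05, widespread_fraction=0.1)
matrix = e.simulate_incidence(truth, 60)
res = e.ParsimonyEndemicity(matrix).fit(replicates=20, keep=50, seed=3)
print(res.summary())
```

```
Parsimony Analysis of Endemicity
========================================
areas:                8
species (characters): 60
replicates run:       20
best tree length:     83
trees retained:       1 (1 at best score)
consensus over:       best-only

majority-rule clades (support %):
   100.0  area01; area02; area03; area04; area05; area06; area07
   100.0  area01; area02; area03; area04; area05; area06
   100.0  area01; area03; area04; area05; area06
   100.0  area01; area03; area04
   100.0  area01; area04
   100.0  area05; area06
```

The best tree length (83) is the minimum total number of 0↔1 changes over
all 60 characters; every one of the six nontrivial clades of the planted
cladogram is recovered at 100% majority-rule support despite the noise.

```python
pts = e.simulate_envelope(60, noise_sd=0.05, seed=1)     # planted ceiling
bss = e.BoundaryTest(pts.x, pts.y).fit(n_randomizations=1000, seed=2)
print(bss.summary())
```

```
Boundary (constraint-envelope) test
========================================
n points:        60
orientation:     lower_right
distance power:  1
null model:      permute_y (1000 draws)
points outside:  12
observed stat:   0.0366563
null mean stat:  0.170295
p (one-sided):   0.000999
```

The twelve points above the hypotenuse sit, on average, ~5× closer to it
than permuted data would (0.037 vs 0.170 on the unit square), and no
permutation produced a smaller statistic — p = 1/1001, a clear ceiling.

```python
cov, rich = e.simulate_species_area(n_areas=72, seed=3)  # planted z = 0.45
print(e.RichnessRegression(cov, rich).fit().summary())
```

```
                         estimate  std_error  t_value   p_value
log_area                   0.4822    0.05453    8.844 1.208e-12
altitude               -9.128e-05  0.0001137  -0.8025    0.4253
...
n = 72, residual df = 63
F = 10.82, p = 1.92e-09, R^2 = 0.579, adjusted R^2 = 0.525
```

Only log(area) is significant, and its estimate (0.48 ± 0.055) covers the
planted species–area slope z = 0.45.

## Command line

```bash
endemicity simulate incidence --n-areas 12 --n-species 150 --seed 1 --out sim/
endemicity pae --matrix sim/incidence.csv --replicates 1000 --keep 100 --seed 2
endemicity bss --covariates cov.csv --richness rich.csv --reps 1000 --seed 3
endemicity regress --covariates cov.csv --matrix sim/incidence.csv
endemicity full --config run.yaml     # whole chain + reproducibility manifest
```

`endemicity full` writes `consensus.nwk`, `richness.csv`, `bss_report.csv`,
`regression.csv`, and `manifest.json` (package/library versions, seeds and
SHA-256 hashes of inputs and artifacts); rerunning a manifest's configuration
reproduces every artifact bit for bit.

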