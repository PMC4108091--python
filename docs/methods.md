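# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the package, in the order an analysis runs.

## Data model

The raw input is a binary species × area incidence matrix (strict
presence/absence; missing cells are rejected by default because imputing
occurrence records silently is worse than failing — `treat_missing_as_absent`
relaxes this explicitly) together with a per-area covariate table: surface
area (km²), mean altitude (m), annual mean temperature, maximum temperature
of the warmest month, minimum temperature of the coldest month (°C), annual
precipitation, and precipitation of the driest and wettest months (mm).
Physically impossible tables (non-positive areas, warmest-month maximum below
coldest-month minimum, negative precipitation) are rejected at load time.

## Parsimony Analysis of Endemicity

**Model.** Areas are treated as taxa; each species is one unordered binary
character. Tree length is the Fitch (1971) minimum number of 0↔1 changes
summed over characters. A hypothetical area scored absent for every species
is included as an outgroup leaf: without it presence/absence has no polarity
and nested area groups are uninterpretable. The reserved outgroup label is
`ROOT_ALL_ABSENT`.

**Scoring.** Fitch state sets are packed into Python integers, one bit per
character and state, so one post-order pass scores all characters
simultaneously with a handful of integer operations per node. This makes
exhaustive enumeration of the 10,395 topologies on 8 leaves take a fraction
of a second, which in turn lets the heuristic be validated against exact
minima rather than against itself.

**Search.** The heuristic protocol is random-addition-sequence +
tree-bisection-reconnection (TBR):

- *Stepwise addition*: the best-scoring of the three starting quartets
  (first three areas + outgroup), then each remaining area at the insertion
  edge minimising length; ties are broken by the replicate's seeded RNG.
- *TBR*: every edge (pendant edges included — bisecting only internal edges
  would leave a 4-leaf tree with no neighbourhood at all and make single-leaf
  moves unreachable) is bisected and the fragments reconnected across every
  edge pair, in a fixed deterministic order. Strict improvements are accepted
  immediately; at a plateau, swapping continues on every equally parsimonious
  tree found, retaining up to `keep` distinct best-scoring topologies per
  replicate (a tree-buffer in the style of standard parsimony software). No
  randomness is needed at this stage, so a run is reproducible bit for bit
  from its seed.
- Replicates are pooled with topological deduplication (trees are identified
  by their set of outgroup-rooted clade bitmasks).

Retaining *equally best* trees rather than a ranked top-`keep` is a
deliberate choice: padding the buffer with strictly worse trees would make
consensus support frequencies uninterpretable. For the same reason the
consensus is computed over the trees at the global best score by default
(`consensus_over="best-only"`); `"pooled"` additionally admits replicate-best
trees that are globally suboptimal.

**Consensus.** Majority rule with strict cutoff (> 50%), support reported as
the clade's percentage frequency rounded to one decimal. Majority clades are
always pairwise compatible at this cutoff, so they assemble into a unique,
possibly polytomous, outgroup-rooted tree.

**Uninformative characters.** Species present in fewer than two areas cannot
group areas (given the all-absent root they are constant or autapomorphic);
`drop_uninformative` removes them. They are *retained* by default since they
only shift every tree's length by a constant, which the tests verify
directly. Species present in *all* areas are likewise topology-neutral but
are kept, matching the "fewer than two areas" rule exactly.

**Exhaustive search** enumerates all unrooted topologies by recursive edge
insertion and is refused above 9 ingroup areas (10 leaves ⇒ 2,027,025
topologies); it exists to provide exact optima for validating the heuristic
and for small empirical subsets.

## Constraint-envelope (BSS) test

**Construction.** Both axes are affinely mapped to [0, 1] by default
(environmental units and species counts are incommensurate, so unscaled
distances are meaningless; with standardisation the decision is invariant to
positive affine transforms of either axis). The observed ranges define the
bounding rectangle; the triangle is lower-right — vertices (min x, min y),
(max x, max y), (max x, min y), hypotenuse rising from (min x, min y) to
(max x, max y) — for variables whose richness ceiling rises with x, and
lower-left (hypotenuse falling from (min x, max y) to (max x, min y)) for
variables such as altitude whose ceiling falls. The published description of
the lower-left variant lists, as a set, the same three vertices as the
lower-right one — geometrically a typo; the mirrored triangle implemented
here is the only reading under which the variant differs from the original.

**Statistic.** Mean of (distance to the hypotenuse *segment*)^p over points
strictly outside the triangle; 0 when none are outside. Points exactly on
the hypotenuse count as inside. Distances go to the segment rather than the
full perimeter because points outside these triangles always lie on the
hypotenuse side; the segment distance is the continuous extension at the
corner shadows. `p = 1` (mean absolute distance, the default, matching the
procedure's "average distance" wording) or `p = 2` (the sum-of-squares
reading of the test's name).

**Null and p-value.** Default null permutes the richness values over areas
(both marginals preserved; the triangle need not be recomputed because
ranges are permutation-invariant); `uniform_rectangle` draws points
uniformly in the observed rectangle for comparability with classical
null-model software. One-sided, small statistic = boundary-concentrated,
with the add-one rule `p = (1 + #{null ≤ obs}) / (1 + N)`, so p lives on the
grid k/(N+1) and never reaches 0. Default N = 1000.

## Richness regression

OLS of per-area richness on eight predictors in fixed reporting order:
log(area) first, then altitude and the six bioclimatic variables. Area
enters logged (natural log by default; base 10 available, which rescales the
area coefficient by ln 10) because the species–area relationship is
conventionally log-linear. The response is raw counts by default, with
`log`/`log1p` options for power-law fits. The fit itself is delegated to
statsmodels OLS; the package adds the design construction, join semantics
(areas missing either table are dropped with a warning), an explicit
rank-deficiency error naming collinear columns, and the Table-style report
(coefficients, SEs, t, p; model F, p, R², adjusted R², n). Zero-richness
areas are included by default (a flag drops them).

## Synthetic data

The generators define the study conditions the package is validated under:

- **Area cladogram**: uniform random unrooted binary tree over n areas
  (sequential random-edge insertion), outgroup attached. A binary tree over
  n areas has exactly n − 2 nontrivial ingroup clades.
- **Incidence**: each species is a synapomorphy of a uniformly chosen
  nontrivial clade (uniform over clades, not size-weighted, so every clade
  has equal expected support and recovery tests are sharp); a fraction w of
  species are instead widespread-random (independent coin flips per area).
  Cells then flip 0→1 with rate ε₀₁ and 1→0 with rate ε₁₀, i.i.d. — no
  spatial autocorrelation, keeping the noise analytically checkable.
  Defaults, chosen once as plausible for an occurrence compilation:
  ε₀₁ = 0.01 (false records), ε₁₀ = 0.05 (under-sampling dominates),
  w = 0.10.
- **Envelope**: x ~ U(0,1); constrained data fill the space below a planted
  ceiling y ≤ slope·x + intercept (then Gaussian noise, clipped at 0);
  the unconstrained variant is the exact independence null. Defaults
  slope = 1, intercept = 0 (the hypotenuse itself), noise sd 0.05.
- **Species–area**: areas log-uniform over 1e2–1e6 km² (four orders of
  magnitude, the spread real ecoregions span); counts
  round(max(0, 3.0 + 0.45·ln A + N(0, 1))). The planted slope 0.45 is the
  magnitude reported for freshwater zooplankton-type data; the other
  covariates are drawn independently of richness so a correct analysis
  attributes signal to log(area) alone.

What the generators do *not* emulate: spatial autocorrelation of occurrence
noise, heterogeneous sampling effort across areas, correlated climate
covariates, and range evolution along the tree (species are perfect clade
markers up to i.i.d. noise). Passing recovery tests therefore demonstrates
algorithmic correctness under the stated conditions, not robustness to
every failure mode of real occurrence compilations.

## Validation conditions and problem sizes

The acceptance suite (and `scripts/acceptance.py`) runs, as the package's
own choice of validation scale: 100 random 7-area × 30-species matrices for
heuristic-vs-exhaustive agreement (10 addition replicates each; agreement
required in ≥ 95, undercutting never); 50 random trees of ≤ 8 leaves for
exact Fitch-vs-brute-force equality; one noise-free 150-species matrix from
a 12-area cladogram for 100%-support recovery of all 10 true clades; 500
null datasets (n = 60, 1000 permutations) for type-I calibration within
[0.03, 0.07] at α = 0.05; 200 planted-envelope replicates (noise sd 0.05)
for ≥ 80% power; and 200 species–area simulations for ≥ 93% two-SE coverage
of the planted slope. The boundary geometry is checked analytically
(distance of (0,1) to the unit lower-right hypotenuse = √2⁄2 to 1e-12).

## Numerical notes and limitations

- All randomness flows through numpy Generators seeded from one run-level
  seed (per-replicate streams `[seed, r]`), so every result is reproducible.
- Tie-breaks: stepwise addition draws uniformly among tied insertion edges;
  TBR enumerates deterministically and keeps all ties, so it needs none.
- Consensus supports are stored rounded to one decimal; p-values exactly on
  the α boundary count as rejections (`p ≤ α`) in calibration code.
- Permutation-null p-values are discrete (grid 1/(N+1)); with N = 1000 the
  smallest attainable p is ≈ 0.001.
- No Bremer or bootstrap supports, no weighted/ordered characters, no
  quantile-regression alternative to the envelope test, no spatial
  autocorrelation correction in the regression, and no multiple-testing
  correction across envelope variables (one test per variable is reported
  as-is).
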