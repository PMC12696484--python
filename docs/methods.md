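# Methods

## Scope and model

`nanoqstr` implements a quantitative structure–toxicity (QSTR) workflow
for spherical iron carbide nanoparticles (ICNPs; phases Fe₂C, Fe₃C,
Fe₅C₂).  The modelled endpoint is in vitro cell viability — the fraction
of surviving cells relative to an untreated control after a 24 h exposure
— regressed on a mixture of exposure/experimental attributes and
atom-level structural descriptors computed from the crystal structure of
the core material.  Treatments with viability below 70 % of control are
regarded as cytotoxic (the standard ISO indicator); this binary label is
used for stratification and reporting only, the regression target stays
continuous.

Two configurations are supported: an *evidence* approach using the nine
experimental attributes alone, and an *atomistic* approach that augments
five pre-synthesis exposure features (core diameter, coating group, shell
material, shell thickness, concentration) with selected atomistic
descriptors.

## Nanoparticle construction

A particle is built by parsing a CIF unit cell (gemmi handles CIF syntax
and symmetry-operator algebra; symmetry images closer than 0.01 Å are
merged), replicating it into a supercell whose perpendicular extent
covers the requested diameter plus a 2 Å margin, and keeping atoms within
`diameter/2` (inclusive, 1e-8 Å tolerance) of the centre.  Two centre
policies exist: the geometric centre of the supercell box (library
default) and the atom nearest that centre ("atom", the pipeline default —
it guarantees a non-empty core for the smallest particles).  Atoms within
4 Å of the nominal surface (`‖r−c‖ ≥ R − 4 Å`, inclusive toward the
surface) form the *shell*; the rest the *core*.  No relaxation is applied:
particles are ideal lattice fragments.  No coating atoms are constructed;
coatings enter only as tabular features.

### Proxy-particle scale

Descriptors for the pipeline are computed on geometrically scaled proxy
particles at **2 Å per nominal nm** (a 44.3 nm core becomes an 88.6 Å
particle of ~26 000 atoms).  Full scale (10 Å/nm) would require millions
of atoms per particle; the 2 Å/nm proxies preserve the monotone
dependence of every size-sensitive descriptor on the nominal diameter and
the distinction between phases, which is what the downstream regression
consumes.  The scale is configurable (`scale_ang_per_nm`).

## Energy model

Descriptor energetics go through a minimal `EnergyModel` contract
(per-atom energies of a cluster; periodic bulk energy per atom), so
production interatomic potentials (EAM/MEAM engines) can be plugged in.
The built-in reference models are Lennard-Jones (default) and Morse pair
potentials with per-species-pair parameters, cutoff 8 Å, and pair
energies half-assigned to each partner so region-restricted averages are
well defined.  Default parameters (Fe–Fe ε=0.40 eV σ=2.30 Å, Fe–C
0.20/1.90, C–C 0.10/3.00) are generic literature-style magnitudes chosen
for a plausible cohesion ordering; they are *not* a fitted force field,
and absolute energies should be read comparatively (across sizes and
phases), not thermochemically.  Bulk energies use explicit image sums
over all periodic neighbours within the cutoff.

## The 57-descriptor registry

Descriptors are evaluated for three regions (whole particle, core,
shell) plus core-shell differences and ratios.  Eight ids are anchored by
convention and used verbatim downstream:

| id  | quantity |
|-----|----------|
| D5  | average potential energy of the core atoms (eV) |
| D7  | core − shell average potential energy difference (eV) |
| D15 | average coordination parameter (3 Å), core |
| D21 | average coordination parameter (4 Å), shell |
| D32 | lattice energy of the particle (eV/atom) |
| D33 | bulk lattice energy − particle lattice energy (eV/atom) |
| D46 | average second hexatic order parameter (q6), all atoms |
| D48 | average second hexatic order parameter (q6), shell |

The full layout (configuration, not hard-code; see
`descriptors.default_registry()`):

- D1–D3: atom counts (all/core/shell)
- D4–D8: average potential energy family
- D9–D13: unlike-species "bonded" coordination at a cutoff of 1.2× the
  covalent-radii sum — the rule whose cutoff can undershoot actual Fe–C
  bond lengths and return structurally zero values
- D14–D28: coordination families at 3/4/5 Å cutoffs
- D29–D31: total potential energy, surface and volume atom densities
- D32–D35: lattice-energy family (particle, bulk, difference, ratio)
- D36–D40: first bond-orientational invariant (Steinhardt q4) family
- D41–D45: planar ψ6 family
- D46–D50: second bond-orientational invariant (q6) family
- D51–D57: sphere geometry (volume, area, ratios, fractions, diameter)

"Second hexatic order parameter" is interpreted as the l=6 Steinhardt
invariant `q_l(i) = sqrt(4π/(2l+1) Σ_m |⟨Y_lm⟩_neigh|²)` with a 4 Å
neighbour cutoff (q4 as the "first"); a planar ψ_l = |⟨e^{ilθ}⟩| variant
is carried alongside.  Atoms without neighbours contribute 0.  Neighbour
counting is inclusive at the cutoff and self-excluding.  Sphere volume
and area use the nominal diameter.  Descriptors whose region is empty or
whose denominator vanishes are flagged *missing* (never silently zeroed);
the pipeline excludes any descriptor column with missing values from the
modelling pool.

## Dataset curation

Viability is stored as a fraction; CSV input in percent (values > 2) is
divided by 100.  Zeta potential and hydrodynamic size columns are
accepted and dropped.  Categorical encodings: coating free text is mapped
by a keyword table to functional groups with fixed ordinals (bare=0,
polymer-based=1, protein-based=2, other=3); shell material and cell line
are ordinal by descending training frequency; health status and organism
are binary.  Unseen categories at prediction time fall back to the most
frequent training code with a logged warning and an `*_unseen` flag
column for the applicability domain.

The 70:30 split first places one uniformly chosen row of every multi-row
experiment in the hold-out set (single-row experiments stay in training,
with a warning), then fills the remaining quota greedily toward the full
table's cytotoxic/non-cytotoxic proportions — the greedy one-slot-at-a-
time allocation minimises the final deviation, keeping both subsets
within 5 percentage points of the full-table label balance whenever the
hold-out size makes that arithmetically possible.  z-scaling uses
training-set statistics only; the population (ddof=0) standard deviation
convention is used (switchable); constant columns pass through with a
warning.  Descriptor rows join on (phase, nearest diameter within
0.1 nm); unmatched or ambiguous particles are hard errors.

## Feature selection

Zero-variance columns are dropped, then feature pairs are scanned in
registry order and the later member of any pair with |Pearson r| > 0.99
against a surviving earlier member is dropped (greedy, order-stable; the
tie policy is documented because the surviving set depends on it).  A
Random Forest surrogate (40 trees, depth 10, unscaled features) is
trained on the filtered pool and per-instance Shapley attributions are
computed; atomistic descriptors are ranked by mean |SHAP| (ties break by
registry order) and the top 8 are united with the five fixed experimental
features, giving 13 by default.  Selection uses training rows only.

## Shapley attributions

The `shap` package is not a dependency; attribution is computed in-house
(`nanoqstr.shapley`):

- sklearn tree ensembles: **exact interventional Shapley values** against
  a background sample.  For each leaf, path features split into those
  whose constraints only the explained row satisfies (U) and those only a
  background row satisfies (V); the leaf is reached by coalition S iff
  U ⊆ S and S ∩ V = ∅, giving closed-form weights (u−1)!v!/(u+v)! and
  −u!(v−1)!/(u+v)!.  This is verified against brute-force subset
  enumeration to 1e-10 in the tests.
- xgboost / lightgbm: the libraries' native contribution predictions.
- other regressors: a seeded permutation-sampling estimator
  (256 permutations by default).

All routes are additive: per-row attributions plus the base value equal
the model prediction (tested at 1e-6).  The sign convention follows the
endpoint: positive attributions push predicted viability up (toward
non-cytotoxicity).

## Model pool and tuning

Six algorithms: Random Forest, kNN, linear SGD regression, one-hidden-
layer MLP (64 units), LightGBM and XGBoost.  Only kNN and linear SGD are
z-scaled (refit inside every fold; the MLP is deliberately unscaled to
match the pool's documented normalisation requirements).  Hyperparameters
are drawn at random from per-algorithm grids (trees 50–500, depth 3–20,
impurity decrease 0–0.01; k 2–15 with uniform/distance weights; learning
rate 1e-4–1e-1 log-uniform with 200–2000 iterations; relu/tanh with
initial rate 1e-4–1e-2; LightGBM trees 50–500 with rate 0.01–0.3; XGBoost
rate 0.01–0.3 with depth 2–10) and scored by mean absolute error over a
shared shuffled 5-fold partition; the winner is the algorithm/draw with
the lowest MAE_cv and is refit on the full training set.  Fold
construction is plain (unstratified) k-fold; all randomness derives from
one master seed.

## Validation

- **LOO Q²** = 1 − PRESS/SS_tot, with each held-out prediction from a
  refit at the *same* hyperparameters (not re-tuned per point).
- **Golbraikh–Tropsha**: k = Σyŷ/Σŷ², k′ = Σyŷ/Σy²,
  r0² = 1 − Σ(y−kŷ)²/Σ(y−ȳ)², r0′² = 1 − Σ(ŷ−k′y)²/Σ(ŷ−ŷ̄)².  Pass
  requires r² > 0.6, Q²loo > 0.5, at least one of (r²−r0²)/r² and
  (r²−r0′²)/r² below 0.1 (both directions are reported), and at least one
  slope within (0.85, 1.15).
- **Y-scrambling**: five refits on a permuted training response, scored
  on the untouched test set; verdict "separated" iff the true test R²
  beats every round.
- **Bootstrap**: percentile (not BCa) intervals from out-of-bag scoring
  of refits on resamples of the *training* set (the test set stays
  blind); resamples with an empty out-of-bag set are skipped and counted.

## Applicability domain

All pairwise training distances are computed; those strictly below their
mean are retained, and the threshold is `⟨d⟩ + Z·σ` with ⟨d⟩, σ the mean
and sample (n−1) standard deviation of the retained subset.  Z is not
fixed by the thresholding scheme itself; the default is 0.5
(config-exposed).  A query is reliable iff its nearest-training-neighbour
distance does not exceed the threshold (inclusive).  Euclidean mode drops
encoded categorical columns and z-scales the numeric block on training
statistics; Gower mode keeps all columns, range-normalising numeric
differences (clipped at 1, zero-range features skipped) and scoring
categorical mismatch 0/1, with per-feature weights defaulting to the
final model's normalised mean-|SHAP| importances (equal weights
otherwise) — the weighting scheme is this package's documented choice.

## Synthetic study generator

`synthdata` emulates the statistical structure of a curated ICNP
dose-response collection: 186 rows from experiments cycling over twelve
(phase, diameter) particles spanning 4.9–44.3 nm, a seven-step two-fold
concentration ladder (3.125–200 µg/mL), shell materials, free-text
coatings and seven cell lines.  Noise-free viability follows a Hill
curve `1/(1+(C/IC50_eff)^h)` with `IC50_eff = IC50_base × coating
multiplier × (d/20 nm)^γ` (defaults: IC50_base 200 µg/mL, h 1.3, γ 0.2,
multipliers bare 0.55 / polymer 1.8 / protein 1.25 / other 1.0), plus
N(0, 0.05) noise, clipped at zero.  The defaults were calibrated once so
the sub-70 % fraction sits near the ~18 % class balance the analysis
assumes (achieved ≈19 % at the default seed; a warning fires beyond ±5
points).  The Hill form matches the sigmoidal dose effect the workflow is
designed to recover; the parameters are this package's own.  The
generator is deterministic per seed, and the manifest records every
generating parameter so feature-importance recovery is checkable.

What the generator does **not** emulate: inter-laboratory heterogeneity,
correlated measurement errors within a study, reporting gaps, real
crystal chemistry (toy cells stand in for database structures) and any
coupling between cell line and response.  Passing tests therefore show
the machinery is correct and the workflow recovers planted structure
under its own assumptions — not that the biological conclusions transfer
to real ICNP data.

## Numerical choices and degenerate inputs

Inclusive boundaries everywhere a rule names a region (carve radius,
shell membership, neighbour cutoff, APD threshold).  Merge tolerance for
symmetry images 0.01 Å; carve tolerance 1e-8 Å.  Correlation-filter and
SHAP ties break by registry order.  Adjusted R² is undefined (None) when
n − p − 1 ≤ 0; R² is undefined for a constant response; the APD fit
refuses tables whose pairwise distances are all equal (nothing retained
below the mean).  Empty regions propagate as missing-value flags.

## Problem sizes of the shipped runs

The test suite and the acceptance script run the full atomistic pipeline
on the default 186-row scenario with 6–10 randomised draws per algorithm,
a 200-resample bootstrap, five scrambling rounds and 2 Å/nm proxy
particles (23–26 000 atoms); a complete run takes on the order of a
minute on one CPU.  Draw counts, bootstrap size and particle scale are
all config knobs for larger studies.

## Known limitations

- The pair-potential energetics are reference-grade; MEAM-class accuracy
  requires plugging an external potential into the `EnergyModel` contract.
- Only 8 of the 57 descriptor ids are externally anchored; the remaining
  layout is a documented convention of this package.
- The correlation-filter survivor set depends on the documented greedy
  tie policy and on the data, so survivor counts are reproducible only
  under that policy.
- Particles are monodisperse ideal spheres; no polydispersity, faceting,
  relaxation or explicit coating atoms.
- The evidence-approach feature set accepts a superset of the canonical
  nine attributes; the modelling feature lists are explicit configs.
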