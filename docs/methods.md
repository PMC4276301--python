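# Methods

## Scope and data

The package re-implements a complete small-series QSAR workflow for
thiophenyl C-aryl glucoside SGLT2 inhibitors: 33 compounds with nanomolar
IC50 values, 2D descriptor models selected by stochastic search, and
lattice-field kNN models on aligned 3D structures. The original study's
descriptor values came from proprietary software and its train/test
membership is reported inconsistently (9 compounds are flagged as test
members while every model states N_test = 7; the printed unicolumn sums
imply a 26/7 split for the 2D models but 24/9 for the 3D ones). The printed
headline statistics are therefore not regeneration targets. What is
reproduced exactly is the tables' own arithmetic (activity conversion,
extrema, residuals); everything else is validated on synthetic data with
planted, known structure.

Two transcription defects in the printed tables are handled explicitly:
the activity table truncates pIC50 at 4 decimals rather than rounding
(verified on all 33 rows), and one LOO prediction (compound 26, SW-3D
model) carries a digit slip of exactly 1.0 relative to its own observed and
residual cells; `reference_data.KNOWN_MISPRINTS` records the correction.
The published model-1 F statistic (45.8975) is inconsistent with the
standard overall-regression F at its own r², n and k (≈ 29.73); the
standard formula is implemented and the printed value is not imitated.

## Activity scales and splitting

pIC50 = 9 − log10(IC50 nM) is the modeling target; the published unicolumn
tables use log10(IC50 nM) = 9 − pIC50. The split-validity conditions (test
max ≤ train max and test min ≥ train min) are a conjunction that is
invariant under this mirror, so they may be checked on either scale.

Sphere exclusion operates in z-scored descriptor space with Euclidean
distances. Training compounds are sphere centers collected along a random
ordering; compounds inside a center's radius go to the test pool. The
radius defaults to the value (found by bisection per ordering) that yields
the requested test fraction, with a deterministic post-adjustment to hit
the exact size: oversized test pools return their most distant members to
training, undersized ones demote the least-distant center. Orderings are
retried (default cap 200) until the containment conditions hold; failure
reports the best attempt. Sample standard deviation uses the n−1
denominator throughout.

## 2D descriptors

E-state values follow the Kier–Hall definitions: intrinsic state
I = ((2/N)²·δv + 1)/δ on the heavy-atom graph (δ heavy degree, δv = valence
electrons − attached H, N principal quantum number), perturbation
ΔI_i = Σ_j (I_i − I_j)/(d_ij + 1)² over all heavy-atom pairs, S = I + ΔI.
Σ ΔI = 0 identically, asserted at 1e−9 and tested against an independent
double-loop oracle and against RDKit's reference implementation. Type sums
(sCH3 = carbon with three hydrogens and one single bond; aaS = sulfur with
two aromatic bonds) are the modeling descriptors; a literal sCH3 atom count
is exposed under a separate name, since the original "count" columns carry
non-integer (E-state-sum) values.

Alignment-independent descriptors count unordered atom pairs with
attributes from {double-bonded, triple-bonded, C, N, O, S, H, F, Cl, Br, I}
at topological distances 0–7 on the explicit-hydrogen graph (distance 0 =
atoms matching both attributes), named `T_<a>_<b>_<d>`. The assembled
matrix adds element counts, H-donor/acceptor counts and E-state columns
(total 542 before pruning, by a documented formula); constant columns are
removed at sample variance < 1e−12 (idempotent). External columns such as
LUMO energies are appended with `external` provenance — no quantum
chemistry is computed in-package, since no method for it is specified and
any estimate would be untestable. Aromaticity follows the input file's
flags when present, otherwise the chemistry backend's ring perception.

## Linear models and selection

The estimator is ordinary least squares with intercept (the published
model is a 4-term linear equation on raw descriptor scales; "GA-PLS" with
all components retained is OLS, and predictors are not standardized by
default). Leave-one-out predictions use the PRESS identity
e_(i) = e_i/(1 − h_ii) from a single fit — algebraically exact, tested to
1e−12 against the naive n-refit loop; a leverage-1 fold falls back to the
training mean with a warning.

Three engines search column subsets with fitness = LOO q², all reproducible
bit-for-bit per seed and sharing a subset-keyed fitness cache; subsets
larger than `max_terms` (or empty) score −∞:

* **Stepwise** — deterministic forward/backward with enter/remove
  thresholds (default 1e−4), ties broken on column index.
* **GA** — bitmask chromosomes, tournament-2 selection, uniform crossover
  (p = 0.8), bit-flip mutation, elitism of 1 (best-ever fitness is
  non-decreasing), population 60, 150 generations.
* **SA** — single-bit-flip neighborhood with Metropolis acceptance
  exp(Δ/T), T0 calibrated so initial acceptance ≈ 0.8, geometric cooling
  0.95, 60 flips per level, 80 levels.

Three engineering choices were required to make the stochastic engines
actually optimize under the hard −∞ size penalty, and are config-exposed:
(1) mutation splits the expected number of flips (default 2) evenly
between set and unset bits — a uniform per-bit rate almost always pushes a
near-cap chromosome past the cap, voiding the child; (2) 20% of each GA
generation are fresh random immigrants, keeping novel columns in
circulation after convergence; (3) the best-ever subset is polished by a
deterministic best-improvement hill-climb over single flips and pair swaps
(monotone, so the non-decreasing trace is preserved). Without the polish
the GA demonstrably sat one move from the optimum for ~100 generations
without sampling it; with these choices both GA and SA recover the planted
4-of-50 support in 10/10 seeds and attain the enumeration optimum on
exhaustively checkable instances.

y-randomization refits (optionally re-selects) on permuted activities
(identity permutations redrawn) and reports the fraction of permuted r²
below the true r² as a confidence percentage.

## Validation statistics

q² and pred_r² follow the standard PRESS forms; pred_r² uses the TRAINING
mean as baseline. Standard errors: r²_se is the residual standard error
with df = n − k − 1; q²_se and pred_r²_se are root-mean-squares of the
corresponding prediction residuals with denominator n (the published
values name no formulas; these conventions are config-switchable via the
explicit denominator argument). F = (r²/k)/((1−r²)/(n−k−1)).
Golbraikh–Tropsha reports Q² > 0.5 and test r² > 0.6 flags plus both
through-origin slopes; the extended battery (r0², rm²) is out of scope.

## 3D fields and kNN-MFA

Alignment is the closed-form least-squares rigid superposition (SVD with
determinant correction, no reflections) of mapped template atoms onto the
reference — the most active compound by default — requiring ≥ 3
non-collinear atoms; tested against an independent rotation optimizer.

The lattice covers the aligned set's bounding box plus a 4.0 Å margin at
2.0 Å spacing; points are numbered 1-based in x-fastest raster order, and
field columns are labeled `S_<i>`, `E_<i>`, `H_<i>` (the original study's
numbering scheme is undefined, so this one is declared). Fields, evaluated
per compound with a united-atom CH3 probe (charge +1, σ = 3.775 Å,
ε = 0.207 kcal/mol):

* electrostatic: 332.0·q_i·q_p/(ε(r)·r) with distance-dependent ε(r) = r by
  default (constant-ε switch available; the source is silent), clipped to
  ±10 kcal/mol;
* steric: 6-12 potential with Lorentz–Berthelot combination against a
  built-in per-element parameter table, clipped to ±30;
* hydrophobic: atomic increments attenuated as h/(1+r) from a built-in
  table, clipped to ±30 (the hydrophobic cutoff is grouped with the steric
  one in the source).

Distances are clamped at 0.1 Å against on-atom singularities. Partial
charges are taken from the input or computed Gasteiger-style for RDKit
molecules — a documented reproducibility boundary. All fields depend on
interatomic distances only, hence are invariant (to FP rounding) under a
common rigid motion of molecule and lattice.

kNN-MFA predicts the inverse-distance-weighted mean activity of the k
nearest training compounds (exact match returns that activity) on the
selected columns; k defaults to 2 (selectable 1–5; the source never states
k). Column selection reuses the same three engines with kNN LOO q² as
fitness after pruning constant columns.

## Synthetic worlds

The 2D generator emits 33 compounds × 216 non-constant columns by default,
matching the original pool size, with four planted columns mimicking the
published model's descriptor types and scales (an E-state-like sum
~N(13, 0.9), a halogen indicator Bernoulli(0.7), an orbital-energy column
~N(−1.2, 0.4), a second E-state sum ~N(1.8, 0.5)) and the published
coefficient magnitudes (0.6451, 0.4287, −0.2574, 0.2789). Activity noise is
Gaussian on the pIC50 scale (standard QSAR assumption), sd 0.25 by default —
chosen a priori so the recoverable fit sits in the published r² ≈ 0.85
regime; decoys mix Poisson counts, normal sums and sparse indicators.
IC50 values are emitted as 10^(9−pIC50), giving an nM-range table.

The 3D generator builds point-atom molecules sharing an identical rigid
5-atom thiophene-like core, plus substituents: one shared site carries a
compound-specific charge in [−0.5, 0.5] that linearly determines activity
(slope 1.5 pIC50 per unit charge), the rest jitter in position with small
background charges. Each molecule is emitted in its own random rigid pose,
so template alignment is genuinely exercised. What these worlds do *not*
emulate: chemical realism of structures, conformational flexibility,
correlated descriptor blocks, activity cliffs — a green recovery test
establishes that the machinery finds planted linear structure at the
stated noise, not that it would resolve the real series' chemistry.

## Known limitations

* Proprietary descriptor values (and hence the published headline r²/q²)
  are not reproducible by construction; the published selected-descriptor
  table is treated as a loose format fixture only.
* MMFF minimization and conformer generation are out of scope; 3D input is
  taken as provided.
* At the default synthetic noise (sd 0.25, n_train 26) the weakest planted
  term is at the edge of identifiability and selection may swap it for a
  decoy — visible in the worked example and intentional.
* The stepwise engine is deterministic and can stop at a local optimum;
  its contract is only to never exceed the enumeration optimum.
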