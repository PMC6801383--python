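# Methods

This note documents the models, conventions and numerical choices behind
`molsnap`, and what its synthetic benchmarks do and do not demonstrate.

## Activity normalisation and labeling

Raw screening signals normalise as
%Activity = (V_compound − V_DMSO) / (V_pos − V_DMSO) × 100,
with V_DMSO and V_pos the vehicle-only and positive-control medians. The
value is deliberately unclamped: super-maximal (>100) and inverse (<0)
responses are information, not errors. Coincident controls raise a
`DegenerateControlError`.

Scores class into three groups — 0 inactive, 1–39 inconclusive, 40–100
active — and binary modelling (the default everywhere downstream) folds
inconclusive into inactive. The boundary is inclusive: a score of exactly
40 is active.

## Curation

Structure equality is defined on the canonical SMILES of the **largest
organic fragment** (RDKit `LargestFragmentChooser`, organic preferred), so
a free base and its salt collapse to one compound. Rules, in order:

* unparseable structures: dropped, reported (`unparseable`), never fatal;
* records without a score: dropped (`no score`);
* structures with zero carbon atoms: dropped (`nonorganic`) — the working
  definition of "organic" here is simply "contains carbon";
* same-structure duplicates with agreeing binary labels merge into one
  record keeping all source ids (score = member mean, which cannot change
  the binary label since all members sit on one side of the cutoff);
* duplicates with conflicting binary labels are removed **entirely**: an
  ambiguous training label is worse than a missing one.

Curation is idempotent and every dropped record appears in the removal
report with exactly one reason.

## Wash (structure standardisation)

Protonation modes:

* `none` — structure unchanged.
* `neutralize` — RDKit Uncharger: protonate anions, deprotonate cations
  wherever valence rules permit; zwitterions neutralise where possible.
* `dominant` — an explicit rule table, **not** a pKa predictor:
  carboxylic acids (pKa ≈ 4.8) and sulfonic acids deprotonate when the
  wash pH is above those values; aliphatic amines (conjugate acid
  pKa ≈ 10; amides, anilines and aromatic N excluded) protonate below
  pH 9.5. At the default pH 7 both rule families fire. This approximates
  commercial "dominant protomer at pH" functionality and is documented as
  an approximation.

Coordinate modes:

* `depict2d` — RDKit 2D depiction layout, z = 0.
* `rebuild3d` — hydrogens added, seeded ETKDG distance-geometry embedding.
* `corina_like` — the same embedding followed by MMFF (UFF fallback)
  refinement, giving exactly **one** low-energy conformer per molecule.

A chained spec (e.g. `neutralize:rebuild3d+neutralize:corina_like`)
re-derives stage two from the stage-one molecular graph; intermediate
coordinates do not influence the final conformer (an explicit assumption —
the alternative, seeding stage two from stage-one geometry, is not
implemented).

Determinism: the per-molecule embedding seed is
`seed XOR crc32(mol_id)` (masked to 31 bits), so coordinates are
bit-for-bit reproducible under a fixed seed *and* independent of library
order.

## Rendering

Rotation grids enumerate per axis as {i·step : i ≥ 0, i·step < 360} and
take the Cartesian product in lexicographic (rx, ry, rz) order, giving
ceil(360/step)³ views — 1, 8, 216, 27 and 1000 views at steps of 360°,
280°, 60°, 176° and 38°. Rotation composes as x-axis, then y, then z,
right-handed, about the molecule centroid.

Bond perception is purely geometric: atoms i < j bond iff
mbd ≤ d(i,j) ≤ r_cov(i) + r_cov(j) + bt, with covalent radii from a
shipped table (Cordero values; carbon pinned at the classic 0.77 Å so a
1.54 Å C–C bond sits exactly at twice the radius). Pairs closer than
`mbd` log a steric-clash warning. Defaults mbd = 0.4 Å, bt = 0.8 Å.

Depiction: orthographic projection; atom spheres at `at`% of the Bondi
van der Waals radius (default 23%), CPK colors from a shipped table,
Lambert-shaded with one fixed directional light over a 0.35 ambient floor;
bonds as flat-shaded thick segments of radius `br` milli-Ångström (default
14.5 mÅ) with a 1-pixel minimum half-width so they stay visible, colored
in split halves by their end atoms; hidden-surface removal by z-buffer.
The projection scale is set from the rotation-invariant bounding sphere
(max centroid distance + draw radius) so the molecule fills `zf`% of the
image edge (default 100%) in *every* view of that molecule — rotated
snapshots of one molecule are therefore mutually comparable, and the
molecule cannot clip the frame at zf ≤ 100. Output is an exact
`pixel`×`pixel` (default 256) RGB PNG; rendering is a pure function, so
images are byte-identical across runs and molecule orderings. `mps`
(default 100) chunks structure files for IO only and never affects pixels.

## Splits

For a Train:Val:Test ratio the library is shuffled and dealt into
train+val+test near-equal groups; the first n mod groups receive one extra
molecule, and the hold-out (test) groups are drawn first, then validation,
then training. Hence 9 molecules at 1:1:1 give 3/3/3, 53 at 26:26:1 give
26/26/1, and 10 at 4:4:1 give 4/4/2 — the rounding surplus goes to the
hold-out. With labels (the default) each class is apportioned across the
split sizes by largest remainder under the constraint that split totals
are met exactly, keeping every split's class mix within one molecule of
the global mix.

Splitting is **molecule-level**: all rotated images of a molecule inherit
its split. Image-level ("leaky") splitting is available only as an
explicit comparison mode, because rotated views of one molecule are
near-duplicates and splitting them across Train/Test would inflate test
AUC. The permutation control reassigns the (score, label) pairs uniformly
at random among molecules, conserving the label multiset while destroying
the structure–activity relationship.

## Reference CNN

The snapshot classifier is a compact convolutional network implemented in
numpy and exposed as a scikit-learn estimator:

* **Input transform.** RGB converts to chromaticity + brightness
  (r/s − ⅓, g/s − ⅓, b/s − ⅓, s/765 − ½ with s = R+G+B) at native
  resolution. The renderer's lighting is multiplicative, so chromaticity
  is shading-invariant and identifies an element's CPK color exactly; the
  white background maps to zero signal. Downsampling to 64×64 keeps each
  block's per-channel maximum *and* minimum (8 channels) — mean pooling
  would dilute a lone colored atom sphere into the background.
* **Architecture.** conv 1×1×8→16 (a learned bank of per-pixel color
  detectors) → ReLU → two 2×2 max-pools → conv 3×3×16→16 → ReLU → global
  max+average pooling → dense 32 → dense 1, sigmoid. The global-pooling
  head makes the decision translation-invariant: a diagnostic color blob
  counts wherever the rotation placed it. ~5k parameters.
* **Training.** Adam (β₁ 0.9, β₂ 0.999) on binary cross-entropy, peak
  learning rate 0.003 cosine-decayed to zero, batch size 32, 120 epochs;
  per-epoch monitors record training loss, validation loss and validation
  accuracy. Three independent seeded restarts are trained and the weights
  with the best validation ROC AUC are kept — the monitor-and-select
  practice of interactive deep-learning front-ends. Everything is
  deterministic under the seed (up to floating-point reduction order).
* **Persistence** is a plain `.npz` of weight arrays — no pickled code.

The `external` architecture hook accepts any object with
`fit(X, y)`/`predict_proba(X)`, which is where a full-scale GoogLeNet- or
AlexNet-class model would plug in; the package's claims are about the
pipeline, not about those weights.

## Descriptor baseline

`compute_descriptors` builds a fixed-schema numeric table per molecule:
the RDKit 2D physicochemical descriptor set, the 167 MACCS keys and a
256-bit Morgan count fingerprint (radius 2) — 633 columns for the
synthetic library. Columns with any non-finite value are median-imputed;
all-missing columns are dropped and logged; per-molecule failures drop the
row and are reported. `train_tree_baseline` evaluates one
(max_depth, n_estimators, max_features) grid point by repeated seeded 1:1
hold-out splits (default five, reported as per-repeat AUCs with mean ± sd).
`max_features` means features-per-split for random forests and the
per-tree column subsample count (colsample_bytree × n_features) for
XGBoost; the mapping is recorded in the result metadata because the two
libraries have no parameter in common with identical semantics.

## Evaluation

Per-image probabilities aggregate to one score per molecule by the median
(even counts: mean of the two central values). All metrics are computed at
molecule level, after aggregation. The ROC curve comes from the score
thresholds; AUC is the trapezoidal integral, which equals the
active-vs-inactive pair statistic with ties counted one half (a property
the test suite checks against a brute-force oracle to 1e-12). The
classification cutoff maximises Youden J = sensitivity + specificity − 1
over midpoints of adjacent distinct scores (ties break toward the higher
threshold, i.e. higher specificity) and is selected on **validation**
scores, then frozen for the test set, to avoid optimistic bias. The
decision rule at the boundary is score ≥ threshold ⇒ active.

Metric conventions: MCC uses the standard square-root four-factor
denominator; any zero denominator (precision with no predicted positives,
MCC with an empty margin) returns 0 and flags the bundle as degenerate
rather than raising, so batch evaluations stay total.

## Synthetic benchmark

The toy generator emits unique, parseable, all-organic structures built
from ~20 scaffold cores with halogenated and plain substituents; the
binary label is a deterministic function of a structural rule
(`halogen_present` by default; ring-count and heavy-atom-count rules are
available), with scores drawn 40–100 for rule-satisfying and 0–39
otherwise and optional label noise that re-draws a seeded subset from the
opposite band. Actives under the halogen rule are drawn round-robin over
F/Cl/Br/I so each variant of the cue is uniformly represented — standard
diverse-library design; with uniform draws a 60-molecule library can
leave a halogen with a single training example, which tests nothing about
the pipeline. The default study conditions for the end-to-end check are
n = 60, active fraction 0.5, 280° angle step (8 views/molecule, 480
images), molecule-level stratified 1:1:1 split; an imbalanced regime
(active fraction 0.108, the screening library's class balance) is
exercised separately. The plate generator inverts the %Activity formula
with optional Gaussian well noise, recovering true percentages exactly at
zero noise and unbiasedly otherwise.

**What passing shows — and does not.** The synthetic label is encoded in
a visually explicit, chromatic cue (halogen CPK colors), so the end-to-end
benchmark demonstrates that curation, washing, rendering, leakage-free
splitting, training, aggregation and evaluation compose correctly and
that the permutation null lands at chance (AUC ≈ 0.5). It does **not**
demonstrate that real activity endpoints — where the signal lives in
subtle 3D shape and substitution patterns, under ~10:1 class imbalance and
label noise — are learnable at this scale; that claim requires the real
screening data and a full-scale CNN through the `external` hook.

## Problem sizes and determinism

The shipped checks use desk-scale sizes chosen to keep the whole suite in
CPU minutes: 60-molecule libraries, 8 views per molecule, a 5k-parameter
CNN, five baseline repeats, 1000-case metric oracles and 200-case AUC
oracles. Every stochastic component (library draw, embedding, split,
weight init, batch order, baseline splits) derives from one user seed;
reported numbers are reproducible bit-for-bit under that seed.

## Known limitations

* `dominant` protonation is a small rule table; tautomers are not
  enumerated.
* The renderer is a minimal z-buffer rasteriser: flat/Lambert shading, no
  anti-aliasing or perspective; only geometry and color semantics are
  contractual.
* ZF and AT are defined by this package's contracts (bounding-sphere fill
  fraction; % of van der Waals radius); other depiction software may
  interpret similarly named parameters differently.
* AUC confidence intervals and multi-class endpoints are out of scope.
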