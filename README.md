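# molsnap

Image-based QSAR from omnidirectional 3D molecular snapshots.

Quantitative structure–activity relationship (QSAR) models usually start
from hand-engineered molecular descriptors. An alternative is to let an
image classifier learn its own features: embed each compound as a single
low-energy 3D conformer, photograph its ball-and-stick model from a grid of
rotations, train a convolutional network on the snapshot images, and score
each molecule by the **median** of its per-view predicted probabilities.
`molsnap` implements that pipeline end to end for binary activity data —
the motivating application is nuclear-receptor (CAR) agonism screened in
the Tox21 program — together with the descriptor-table random-forest /
gradient-boosting baseline it is compared against. It is aimed at
cheminformaticians who want a transparent, fully scriptable desk-scale
version of the snapshot approach.

## Pipeline

1. **Ingest & curate** (`molsnap.chem_io`). Input is a table of
   (id, SMILES, activity score) rows, where the score comes from the assay
   normalisation %Activity = (V_compound − V_DMSO)/(V_pos − V_DMSO) × 100.
   Scores class as inactive (0), inconclusive (1–39, folded into inactive
   for binary modelling) and active (40–100). Curation canonicalises the
   largest organic fragment, merges duplicates with consistent labels,
   drops conflicting duplicates entirely, and removes carbon-free
   (nonorganic) entries — every removal is reported with a reason.
2. **Wash** (`chem_io.wash`). Protonation handling (`none`, `neutralize`,
   or a documented `dominant`-at-pH rule table) plus coordinate
   generation: 2D depiction layout, seeded distance-geometry 3D embedding,
   or `corina_like` — exactly one force-field-refined conformer per
   molecule, bit-for-bit reproducible under a fixed seed.
3. **Render** (`molsnap.render`). Rotations are enumerated per axis as
   {i·step : i·step < 360}, so a 360° step gives 1 view, 280° gives 8,
   60° gives 216 and 38° gives 1000. Bonds are perceived from interatomic
   distances (mbd ≤ d ≤ r_cov(i)+r_cov(j)+bt); atoms draw as CPK-colored
   spheres at AT% of the van der Waals radius; output is a byte-stable
   256×256 RGB PNG per view plus a manifest CSV.
4. **Split** (`molsnap.datasets`). Molecules (never individual images) are
   dealt into Train:Val:Test groups at integer ratios such as 1:1:1 or
   26:26:1, stratified by label, with a label-permutation control for
   null-model comparisons.
5. **Classify** (`molsnap.classify`, `molsnap.cnn`). A compact numpy CNN
   (scikit-learn estimator API) scores each snapshot; any estimator with
   `fit`/`predict_proba` plugs in through the same contract. The baseline
   route computes >500 RDKit descriptors/fingerprint bits per molecule and
   evaluates RF/XGBoost grids over repeated 1:1 hold-out splits.
6. **Evaluate** (`molsnap.evaluate`). Per-image probabilities reduce to
   per-molecule medians; the module builds the ROC curve, selects a
   Youden-J cutoff on validation scores, and reports sensitivity,
   specificity, balanced accuracy (BAC), accuracy, precision, recall, F
   value and Matthews correlation coefficient (MCC, square-root
   denominator), plus AUC.

## Worked example

```python
from molsnap import (ToyLibrarySpec, make_toy_library, curate, wash, WashSpec,
                     RenderParams, Rotation, render_snapshot, enumerate_rotations)

lib = make_toy_library(ToyLibrarySpec(n=12, active_fraction=0.5, seed=7))
records, report = curate(lib)
print(f"curated {len(records)} molecules ({sum(r.label=='active' for r in records)} active), "
      f"{len(report)} removed")

mol = wash(records[0], WashSpec("neutralize", "corina_like"), seed=7)
print(f"{mol.mol_id}: {records[0].structure_key} -> {mol.n_atoms} atoms, "
      f"{len(mol.bonds)} bonds, net charge {mol.net_charge}")

rots = enumerate_rotations((280.0, 280.0, 280.0))
print(f"{len(rots)} views per molecule at a 280-degree step")

img = render_snapshot(mol, Rotation(0, 0, 0), RenderParams())
print(f"snapshot: {img.shape[0]}x{img.shape[1]} RGB, "
      f"{(img != 255).any(axis=2).sum()} foreground pixels")
```

prints

```
curated 12 molecules (6 active), 0 removed
toy0000: NCC1CCC2CCCCC2C1CN -> 38 atoms, 39 bonds, net charge 0
8 views per molecule at a 280-degree step
snapshot: 256x256 RGB, 9485 foreground pixels
```

i.e. a 12-record synthetic library survives curation intact with a
balanced label split; the first record embeds (hydrogens included) into a
neutral single conformer; the 280° angle step yields the expected 8
rotated views; and the zero-rotation snapshot is a 256×256 RGB image whose
molecule occupies ~9500 pixels.

The same flow is available from the shell:

```sh
molsnap fixtures --n 60 --active-fraction 0.5 --seed 7 --out toy.csv
molsnap prepare  --input toy.csv --wash neutralize:corina_like --seed 7 --out toy.sdf
molsnap snap     --sdf toy.sdf --angle 280 --out snaps/
molsnap split    --manifest snaps/manifest.csv --ratio 1:1:1 --seed 7 --out split.csv
molsnap train    --manifest split.csv --model-out model.npz
molsnap baseline --input toy.csv --model xgb --max-depth 3 --n-estimators 5000 --max-features 60
```

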