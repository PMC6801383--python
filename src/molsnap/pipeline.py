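"""End-to-end convenience pipeline: library -> wash -> snapshots -> split ->
classifier -> median-aggregated molecule-level evaluation.

This wires the individual modules together the way the CLI does, and is what
the learnability checks run: a synthetic library with a known structure-label
rule should be nearly perfectly classifiable from its snapshots, while the
same run with permuted labels should collapse to chance.
"""

from __future__ import annotations

import logging
import tempfile
from pathlib import Path
from typing import Optional

import numpy as np

from . import chem_io, classify, datasets, evaluate, render, synthetic

logger = logging.getLogger(__name__)


def prepare_library(
    spec: synthetic.ToyLibrarySpec,
    wash_spec: chem_io.WashSpec,
    seed: int,
    permute: bool = False,
) -> tuple[list[chem_io.Molecule3D], dict[str, str]]:
    """Generate, curate, (optionally) permute and wash a toy library.

    Returns the prepared 3D molecules and a mol_id -> binary label map.
    """
    records = synthetic.make_toy_library(spec)
    curated, report = chem_io.curate(records)
    if report:
        logger.info("curation dropped %d records", len(report))
    if permute:
        curated = datasets.permute_labels(curated, seed=seed + 1)
    mols, labels = [], {}
    for rec in curated:
        try:
            mol = chem_io.wash(rec, wash_spec, seed=seed)
        except chem_io.EmbeddingError as exc:
            logger.warning("skipping %s: %s", rec.mol_id, exc)
            continue
        mols.append(mol)
        labels[mol.mol_id] = rec.label
    return mols, labels


def run_image_pipeline(
    n: int = 60,
    active_fraction: float = 0.5,
    rule: str = "halogen_present",
    angle: float = 280.0,
    ratio: str = "1:1:1",
    seed: int = 0,
    epochs: int = 120,
    permute: bool = False,
    workdir: Optional[str | Path] = None,
    params: Optional[render.RenderParams] = None,
) -> dict:
    """Run the full snapshot pipeline on a synthetic library.

    Returns a dict with the test-set MetricsBundle, the training history and
    bookkeeping counts. Deterministic under a fixed seed.
    """
    spec = synthetic.ToyLibrarySpec(n=n, active_fraction=active_fraction, rule=rule, seed=seed)
    wash_spec = chem_io.WashSpec(protonation="neutralize", coordinates="corina_like")
    mols, labels = prepare_library(spec, wash_spec, seed=seed, permute=permute)

    if params is None:
        params = render.RenderParams(angle_step=(angle, angle, angle))
    with tempfile.TemporaryDirectory() as tmp:
        outdir = Path(workdir) if workdir is not None else Path(tmp)
        manifest = render.snap_dataset(mols, [labels[m.mol_id] for m in mols], params, outdir)

        assignment = datasets.split_molecules(
            [m.mol_id for m in mols],
            datasets.SplitRatio.parse(ratio),
            seed=seed,
            labels=[labels[m.mol_id] for m in mols],
        )
        manifest = datasets.attach_images(assignment, manifest)
        parts = {s: manifest[manifest["split"] == s].reset_index(drop=True) for s in ("train", "val", "test")}
        images = {s: classify.load_images(parts[s]) for s in parts}

    config = classify.TrainingConfig(epochs=epochs, seed=seed)
    model, history = classify.train_image_classifier(images["train"], images["val"], config)

    val_preds = classify.predict_images(model, parts["val"], images["val"][0])
    test_preds = classify.predict_images(model, parts["test"], images["test"][0])
    metrics = evaluate.evaluate_predictions(
        test_preds, labels, val_preds=val_preds, val_labels=labels
    )
    return {
        "metrics": metrics,
        "history": history,
        "n_molecules": len(mols),
        "n_images": int(sum(len(p) for p in parts.values())),
        "split_sizes": {s: int(parts[s]["mol_id"].nunique()) for s in parts},
        "permuted": permute,
    }


def run_baseline_pipeline(
    n: int = 60,
    active_fraction: float = 0.5,
    rule: str = "halogen_present",
    seed: int = 0,
    config: Optional[classify.BaselineConfig] = None,
    n_repeats: int = 5,
    permute: bool = False,
) -> dict:
    """Descriptor-table RF/XGB baseline on the same synthetic library."""
    spec = synthetic.ToyLibrarySpec(n=n, active_fraction=active_fraction, rule=rule, seed=seed)
    records = synthetic.make_toy_library(spec)
    curated, _ = chem_io.curate(records)
    if permute:
        curated = datasets.permute_labels(curated, seed=seed + 1)
    table, failures = classify.compute_descriptors(
        [(r.mol_id, r.structure_key) for r in curated]
    )
    kept = [r for r in curated if r.mol_id in set(table.index)]
    y = np.array([1 if r.label == "active" else 0 for r in kept])
    if config is None:
        config = classify.BaselineConfig(seed=seed)
    result = classify.train_tree_baseline(table, y, config, n_repeats=n_repeats)
    result["n_molecules"] = len(kept)
    result["n_descriptors"] = int(table.shape[1])
    result["n_failures"] = len(failures)
    return result
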