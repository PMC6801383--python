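"""Shared fixtures: all test data is generated programmatically at run time."""

from __future__ import annotations

import numpy as np
import pytest

from molsnap import chem_io, render, synthetic


@pytest.fixture(scope="session")
def toy_library():
    """A deterministic 20-molecule library (halogen rule, balanced classes)."""
    spec = synthetic.ToyLibrarySpec(n=20, active_fraction=0.5, seed=11)
    return synthetic.make_toy_library(spec)


@pytest.fixture(scope="session")
def curated_records(toy_library):
    curated, report = chem_io.curate(toy_library)
    assert not report
    return curated


@pytest.fixture(scope="session")
def washed_molecules(curated_records):
    """Six single-conformer 3D molecules plus their binary labels."""
    spec = chem_io.WashSpec(protonation="neutralize", coordinates="corina_like")
    mols, labels = [], []
    for rec in curated_records[:6]:
        mols.append(chem_io.wash(rec, spec, seed=5))
        labels.append(rec.label)
    return mols, labels


@pytest.fixture(scope="session")
def small_render_params():
    """Default depiction parameters with the single-view rotation grid."""
    return render.RenderParams(angle_step=(360.0, 360.0, 360.0))


def make_color_blob_images(n: int, seed: int, size: int = 64):
    """Tiny synthetic classification task: images with (label 1) or without
    (label 0) a small saturated green square at a random position."""
    rng = np.random.RandomState(seed)
    X = np.full((n, size, size, 3), 255, dtype=np.uint8)
    y = rng.randint(0, 2, n)
    for i in range(n):
        # gray distractor blob
        r, c = rng.randint(0, size - 8, 2)
        X[i, r : r + 8, c : c + 8] = 128
        if y[i]:
            r, c = rng.randint(0, size - 4, 2)
            X[i, r : r + 4, c : c + 4] = (40, 220, 40)
    return X, y
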