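"""Train/validation/test assembly at integer ratios, and label-permutation controls.

Splitting follows the hold-out-group procedure: the shuffled library is dealt
into train+val+test near-equal groups, the hold-out (test) groups are drawn
first and absorb the rounding surplus, and each molecule carries all of its
snapshot images into its split so no structure leaks across splits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem_io import MoleculeRecord

Split = str  # "train" | "val" | "test"
_SPLITS: tuple[Split, ...] = ("test", "val", "train")  # allocation order


@dataclass(frozen=True)
class SplitRatio:
    train: int
    val: int
    test: int

    def __post_init__(self):
        if min(self.train, self.val, self.test) < 1:
            raise ValueError("all ratio parts must be >= 1")

    @classmethod
    def parse(cls, text: str) -> "SplitRatio":
        parts = text.split(":")
        if len(parts) != 3:
            raise ValueError(f"ratio {text!r} is not of the form train:val:test")
        t, v, s = (int(p) for p in parts)
        return cls(t, v, s)

    @property
    def n_groups(self) -> int:
        return self.train + self.val + self.test


def split_sizes(n: int, ratio: SplitRatio) -> dict[Split, int]:
    """Target split sizes for n molecules.

    The library is dealt into train+val+test near-equal groups; the first
    n mod groups receive one extra molecule, and the hold-out test groups are
    drawn first (so e.g. 10 molecules at 4:4:1 give sizes 4/4/2).
    """
    groups = ratio.n_groups
    if n < groups:
        raise ValueError(f"need at least {groups} molecules for ratio "
                         f"{ratio.train}:{ratio.val}:{ratio.test}, got {n}")
    base, extra = divmod(n, groups)
    sizes = [base + 1] * extra + [base] * (groups - extra)
    counts = {"test": ratio.test, "val": ratio.val, "train": ratio.train}
    out: dict[Split, int] = {}
    pos = 0
    for split in _SPLITS:
        k = counts[split]
        out[split] = sum(sizes[pos : pos + k])
        pos += k
    return out


def _deal(ids: list, sizes: dict[Split, int]) -> dict:
    assignment = {}
    pos = 0
    for split in _SPLITS:
        for mid in ids[pos : pos + sizes[split]]:
            assignment[mid] = split
        pos += sizes[split]
    return assignment


def split_molecules(
    mol_ids: Sequence[str],
    ratio: SplitRatio,
    seed: int = 0,
    labels: Optional[Sequence[str]] = None,
) -> dict[str, Split]:
    """Assign each molecule to train/val/test, optionally label-stratified.

    Deterministic under a fixed seed. With labels, each class is apportioned
    across splits by largest remainder so every split's class mix matches the
    global mix to within one molecule of rounding.
    """
    mol_ids = list(mol_ids)
    if len(set(mol_ids)) != len(mol_ids):
        raise ValueError("mol_ids must be unique")
    sizes = split_sizes(len(mol_ids), ratio)
    rng = np.random.RandomState(seed & 0x7FFFFFFF)

    if labels is None:
        order = rng.permutation(len(mol_ids))
        return _deal([mol_ids[i] for i in order], sizes)

    if len(labels) != len(mol_ids):
        raise ValueError("labels must align with mol_ids")
    labels = list(labels)
    n = len(mol_ids)
    classes: list[str] = list(dict.fromkeys(labels))
    by_class = {c: [m for m, l in zip(mol_ids, labels) if l == c] for c in classes}

    # largest-remainder apportionment of each class over the split sizes,
    # constrained so split totals are met exactly
    alloc = {c: {s: 0 for s in _SPLITS} for c in classes}
    fractions = []
    for c in classes:
        n_c = len(by_class[c])
        for s in _SPLITS:
            quota = n_c * sizes[s] / n
            alloc[c][s] = int(quota)
            fractions.append((quota - int(quota), c, s))
    rem_class = {c: len(by_class[c]) - sum(alloc[c].values()) for c in classes}
    rem_split = {s: sizes[s] - sum(alloc[c][s] for c in classes) for s in _SPLITS}
    for _, c, s in sorted(fractions, key=lambda t: (-t[0], t[1], t[2])):
        if rem_class[c] > 0 and rem_split[s] > 0:
            alloc[c][s] += 1
            rem_class[c] -= 1
            rem_split[s] -= 1
    for c in classes:  # fixup for degenerate greedy leftovers
        for s in _SPLITS:
            while rem_class[c] > 0 and rem_split[s] > 0:
                alloc[c][s] += 1
                rem_class[c] -= 1
                rem_split[s] -= 1

    assignment: dict[str, Split] = {}
    for c in classes:
        members = list(by_class[c])
        order = rng.permutation(len(members))
        members = [members[i] for i in order]
        pos = 0
        for s in _SPLITS:
            for mid in members[pos : pos + alloc[c][s]]:
                assignment[mid] = s
            pos += alloc[c][s]
    return assignment


def attach_images(assignment: dict[str, Split], manifest: pd.DataFrame) -> pd.DataFrame:
    """Propagate molecule split assignments onto the image manifest.

    Every image inherits its molecule's split; a manifest molecule missing
    from the assignment is an error (it would silently leak otherwise).
    """
    out = manifest.copy()
    orphans = sorted(set(out["mol_id"].astype(str)) - set(assignment))
    if orphans:
        raise ValueError(f"manifest molecules missing from split assignment: {orphans}")
    out["split"] = out["mol_id"].astype(str).map(assignment)
    return out


def split_images_leaky(manifest: pd.DataFrame, ratio: SplitRatio, seed: int = 0) -> pd.DataFrame:
    """Image-level splitting (rotated views of one molecule may straddle
    splits). Provided for leakage comparison only; molecule-level splitting
    is the supported default."""
    idx = list(range(len(manifest)))
    sizes = split_sizes(len(idx), ratio)
    rng = np.random.RandomState(seed & 0x7FFFFFFF)
    order = rng.permutation(len(idx))
    assignment = _deal([idx[i] for i in order], sizes)
    out = manifest.copy()
    out["split"] = [assignment[i] for i in range(len(out))]
    return out


def permute_labels(records: Sequence[MoleculeRecord], seed: int = 0) -> list[MoleculeRecord]:
    """Permutation-control labelling: activity scores (and hence labels) are
    randomly reassigned among the molecules, conserving the label multiset
    while destroying any structure-activity relationship."""
    records = list(records)
    if not records:
        raise ValueError("cannot permute an empty record list")
    rng = np.random.RandomState(seed & 0x7FFFFFFF)
    perm = rng.permutation(len(records))
    return [
        replace(records[i], label=records[j].label, activity_score=records[j].activity_score)
        for i, j in enumerate(perm)
    ]
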