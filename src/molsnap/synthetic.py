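"""Synthetic labeled molecule libraries and assay-plate signals.

The toy library emulates a screened small-molecule collection whose binary
activity is a deterministic function of a structural feature (halogen
presence, ring count, or heavy-atom count), with optional label noise and a
tunable class imbalance — the real screening data it stands in for is highly
imbalanced (roughly one active per nine inactives). Every stage of the
pipeline, from curation through rendering to end-to-end learnability, is
testable on these libraries with no download.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .chem_io import RawRecord

# Shipped scaffold list: neutral organic cores for library generation plus
# charged species (protonation-rule tests) and one carbon-free structure
# (nonorganic-filter test).
SCAFFOLDS: tuple[str, ...] = (
    "c1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1", "c1ccc2ccccc2c1",
    "c1ccc(C)cc1", "c1ccc(O)cc1", "c1ccc(N)cc1", "c1cnccn1",
    "C1CCCCC1", "C1CCNCC1", "C1CCOC1", "C1CC1", "C1CCC1",
    "CCCCC", "CCCCCC", "CC(C)C", "CCOCC", "CCNCC", "CC(C)CC",
    "C1CCC2CCCCC2C1", "c1ccc2[nH]ccc2c1",
    # charged species for wash tests
    "CC(=O)[O-]", "C[NH3+]", "CC(=O)O", "CCN", "[O-]C(=O)c1ccccc1",
    # carbon-free structures for the nonorganic filter
    "OS(=O)(=O)O", "[Na+].[Cl-]",
)

_CORES = SCAFFOLDS[:21]
_HALO_PREFIX = ("F", "Cl", "Br", "I", "FC", "ClC", "BrC", "IC", "ClCC", "FCC", "BrCC")
_PLAIN_PREFIX = ("", "C", "CC", "CCC", "O", "OC", "OCC", "N", "NC", "NCC", "OCCC")
_SUFFIX = ("", "C", "CC", "O", "N", "CO", "CN", "CCO")

_RULE_RE = re.compile(r"^heavy_atoms_ge_(\d+)$")


def _rule_predicate(rule: str):
    if rule == "halogen_present":
        halo = {9, 17, 35, 53}
        return lambda m: any(a.GetAtomicNum() in halo for a in m.GetAtoms())
    if rule == "ring_count_ge_2":
        return lambda m: Chem.rdMolDescriptors.CalcNumRings(m) >= 2
    m = _RULE_RE.match(rule)
    if rule == "heavy_atoms_ge_k":
        rule = "heavy_atoms_ge_10"
        m = _RULE_RE.match(rule)
    if m:
        k = int(m.group(1))
        return lambda mol: mol.GetNumHeavyAtoms() >= k
    raise ValueError(f"unknown rule {rule!r}")


@dataclass(frozen=True)
class ToyLibrarySpec:
    """Generation recipe for a synthetic labeled library."""

    n: int = 60
    active_fraction: float = 0.5
    rule: str = "halogen_present"
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 4:
            raise ValueError("n must be >= 4")
        if not (0.0 < self.active_fraction < 1.0):
            raise ValueError("active_fraction must lie in (0, 1)")
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must lie in [0, 0.5)")
        _rule_predicate(self.rule)


def _candidate_pools(rule: str) -> tuple[list[str], list[str]]:
    """Unique canonical candidate structures partitioned by the rule."""
    pred = _rule_predicate(rule)
    seen: set[str] = set()
    satisfy: list[str] = []
    fail: list[str] = []
    for prefix in _HALO_PREFIX + _PLAIN_PREFIX:
        for core in _CORES:
            for suffix in _SUFFIX:
                smi = f"{prefix}{core}{suffix}"
                mol = Chem.MolFromSmiles(smi)
                if mol is None:
                    continue
                can = Chem.MolToSmiles(mol)
                if can in seen:
                    continue
                seen.add(can)
                (satisfy if pred(mol) else fail).append(can)
    return satisfy, fail


def _draw_balanced(pool: list[str], k: int, rule: str, rng: np.random.RandomState) -> list[str]:
    """Draw k rule-satisfying structures, balanced over the rule's variants.

    For the halogen rule the actives are drawn round-robin over F/Cl/Br/I so
    each variant of the structural cue is uniformly represented in the
    library — the usual diverse-design practice, and it keeps every variant
    learnable in any random split. Other rules draw uniformly.
    """
    if rule != "halogen_present":
        return [pool[i] for i in rng.choice(len(pool), k, replace=False)]
    halo_of = {9: "F", 17: "Cl", 35: "Br", 53: "I"}
    groups: dict[str, list[str]] = {h: [] for h in halo_of.values()}
    for smi in pool:
        mol = Chem.MolFromSmiles(smi)
        present = sorted({halo_of[a.GetAtomicNum()] for a in mol.GetAtoms()
                          if a.GetAtomicNum() in halo_of})
        groups[present[0]].append(smi)
    for h in groups:
        groups[h] = [groups[h][i] for i in rng.permutation(len(groups[h]))]
    order = ["F", "Cl", "Br", "I"]
    out: list[str] = []
    i = 0
    while len(out) < k:
        g = groups[order[i % 4]]
        if g:
            out.append(g.pop())
        elif not any(groups.values()):
            raise ValueError("halogen pools exhausted")
        i += 1
    return out


def make_toy_library(spec: ToyLibrarySpec) -> list[RawRecord]:
    """Emit n unique, parseable, all-organic records with scores tied to the rule.

    Exactly round(n * active_fraction) structures satisfy the structural
    rule and receive scores in 40-100; the rest score 0-39. ``label_noise``
    re-draws the score of a seeded random subset from the opposite band,
    decoupling those labels from the structure. Deterministic under seed.
    """
    rng = np.random.RandomState(spec.seed & 0x7FFFFFFF)
    n_active = int(round(spec.n * spec.active_fraction))
    n_inactive = spec.n - n_active
    satisfy, fail = _candidate_pools(spec.rule)
    if n_active > len(satisfy) or n_inactive > len(fail):
        raise ValueError(
            f"spec unsatisfiable: need {n_active} rule-satisfying / {n_inactive} other "
            f"structures but pools hold {len(satisfy)} / {len(fail)}"
        )
    actives = _draw_balanced(satisfy, n_active, spec.rule, rng)
    inactives = [fail[i] for i in rng.choice(len(fail), n_inactive, replace=False)]

    smiles = actives + inactives
    is_active = np.array([True] * n_active + [False] * n_inactive)
    n_flip = int(round(spec.label_noise * spec.n))
    if n_flip:
        flip = rng.choice(spec.n, n_flip, replace=False)
        is_active[flip] = ~is_active[flip]

    scores = np.where(
        is_active,
        rng.randint(40, 101, size=spec.n),
        rng.randint(0, 40, size=spec.n),
    )
    order = rng.permutation(spec.n)
    return [
        RawRecord(
            record_id=f"toy{k:04d}",
            smiles=smiles[i],
            activity_score=float(scores[i]),
        )
        for k, i in enumerate(order)
    ]


def make_plate(
    v_dmso: float,
    v_pos: float,
    true_percents,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Generate compound-well signals whose percent activity recovers
    ``true_percents`` — exactly at zero noise, unbiasedly in expectation
    otherwise (additive Gaussian well noise)."""
    if v_pos == v_dmso:
        raise ValueError("degenerate controls: v_pos must differ from v_dmso")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    p = np.asarray(true_percents, dtype=float)
    v = v_dmso + p / 100.0 * (v_pos - v_dmso)
    if noise_sd > 0:
        rng = np.random.RandomState(seed & 0x7FFFFFFF)
        v = v + rng.normal(0.0, noise_sd, size=p.shape)
    return v
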