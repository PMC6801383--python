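"""Ingestion, curation and structure preparation ("wash") for activity-scored libraries.

The input is a table of (id, SMILES, activity score 0-100) rows as produced by
a quantitative high-throughput reporter-gene screen. Curation deduplicates on
canonical structure, drops conflicting duplicates and non-organic entries, and
assigns the activity-score class (0 inactive / 1-39 inconclusive / 40-100
active; inconclusive folds into inactive for binary modelling). The wash step
standardises protonation (none / dominant-at-pH / neutralize) and generates
coordinates (2D depiction layout, seeded distance-geometry 3D embedding, or a
single force-field-optimised low-energy conformer).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, rdDepictor
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

Label = Literal["active", "inactive", "inconclusive"]

ACTIVE_MIN = 40.0  # activity score at and above which a compound is active


class MolsnapError(Exception):
    """Base class for package errors."""


class DegenerateControlError(MolsnapError):
    """Positive and vehicle control signals coincide; % activity undefined."""


class EmbeddingError(MolsnapError):
    """3D embedding failed for a molecule."""


@dataclass(frozen=True)
class RawRecord:
    """One row of a raw activity table."""

    record_id: str
    smiles: str
    activity_score: Optional[float] = None

    def __post_init__(self):
        if self.activity_score is not None and not (0.0 <= self.activity_score <= 100.0):
            raise ValueError(
                f"activity_score {self.activity_score} outside [0, 100] for {self.record_id!r}"
            )


@dataclass(frozen=True)
class MoleculeRecord:
    """A curated, deduplicated compound keyed by canonical structure."""

    structure_key: str
    label: Label
    activity_score: float
    source_ids: tuple[str, ...] = ()

    @property
    def mol_id(self) -> str:
        return self.source_ids[0] if self.source_ids else self.structure_key


_PROTONATIONS = ("none", "dominant", "neutralize")
_COORDINATES = ("depict2d", "rebuild3d", "corina_like")


@dataclass(frozen=True)
class WashSpec:
    """Structure-standardisation recipe: a protonation rule plus a coordinate generator.

    ``chained`` applies a second (protonation, coordinates) pair to the result
    of the first, mirroring two-stage preparation recipes; the second stage
    regenerates coordinates from the stage-one molecular graph.
    """

    protonation: str = "none"
    coordinates: str = "corina_like"
    chained: Optional[tuple[str, str]] = None
    ph: float = 7.0

    def __post_init__(self):
        if self.protonation not in _PROTONATIONS:
            raise ValueError(f"unknown protonation {self.protonation!r}; expected one of {_PROTONATIONS}")
        if self.coordinates not in _COORDINATES:
            raise ValueError(f"unknown coordinates {self.coordinates!r}; expected one of {_COORDINATES}")
        if self.chained is not None:
            p2, c2 = self.chained
            if p2 not in _PROTONATIONS or c2 not in _COORDINATES:
                raise ValueError(f"unknown chained stage {self.chained!r}")
        if not self.ph > 0:
            raise ValueError("ph must be positive")

    @classmethod
    def parse(cls, text: str, ph: float = 7.0) -> "WashSpec":
        """Parse ``prot:coords`` or ``prot:coords+prot:coords``."""
        stages = []
        for part in text.split("+"):
            prot, _, coords = part.partition(":")
            stages.append((prot.strip(), coords.strip()))
        if len(stages) == 1:
            return cls(*stages[0], ph=ph)
        if len(stages) == 2:
            return cls(*stages[0], chained=stages[1], ph=ph)
        raise ValueError("at most two chained wash stages are supported")


@dataclass(frozen=True)
class Molecule3D:
    """A prepared molecule: elements, coordinates (Å), charges and bonds."""

    mol_id: str
    elements: tuple[str, ...]
    coords: tuple[tuple[float, float, float], ...]
    formal_charges: tuple[int, ...]
    bonds: tuple[tuple[int, int], ...]

    def __post_init__(self):
        n = len(self.elements)
        if not (len(self.coords) == len(self.formal_charges) == n):
            raise ValueError("elements, coords and formal_charges must have equal length")
        seen = set()
        for i, j in self.bonds:
            if not (0 <= i < j < n):
                raise ValueError(f"bond ({i},{j}) out of range or not i<j for {n} atoms")
            if (i, j) in seen:
                raise ValueError(f"duplicate bond ({i},{j})")
            seen.add((i, j))

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def net_charge(self) -> int:
        return sum(self.formal_charges)


# ---------------------------------------------------------------------------
# Assay arithmetic and labeling
# ---------------------------------------------------------------------------

def percent_activity(v_compound: float, v_dmso: float, v_pos: float) -> float:
    """Normalise a raw well signal to percent activity.

    %Activity = (Vcompound - Vdmso) / (Vpos - Vdmso) * 100, where Vdmso and
    Vpos are the vehicle-only and positive-control medians. No clamping:
    super-maximal or inverse responses fall outside [0, 100].
    """
    if v_pos == v_dmso:
        raise DegenerateControlError(
            f"positive control equals vehicle control ({v_pos}); percent activity undefined"
        )
    return (v_compound - v_dmso) / (v_pos - v_dmso) * 100.0


def assign_label(activity_score: float, binary: bool = True) -> Label:
    """Class an activity score: 0 inactive, 1-39 inconclusive, 40-100 active.

    In binary mode (the default downstream) inconclusive maps to inactive.
    """
    if not (0.0 <= activity_score <= 100.0):
        raise ValueError(f"activity score {activity_score} outside [0, 100]")
    if activity_score >= ACTIVE_MIN:
        return "active"
    if activity_score == 0.0:
        return "inactive"
    return "inactive" if binary else "inconclusive"


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

_fragment_chooser = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)


def structure_key(smiles: str) -> Optional[str]:
    """Canonical SMILES of the largest organic fragment, or None if unparseable.

    Salt/solvent components are stripped before canonicalisation so that a
    free base and its salt form compare equal.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    if mol.GetNumAtoms() == 0:
        return None
    mol = _fragment_chooser.choose(mol)
    return Chem.MolToSmiles(mol)


def _has_carbon(smiles: str) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    return mol is not None and any(a.GetAtomicNum() == 6 for a in mol.GetAtoms())


def curate(
    records: Sequence[RawRecord],
) -> tuple[list[MoleculeRecord], list[tuple[str, str]]]:
    """Deduplicate and filter raw records into curated molecule records.

    Rules:
      * unparseable structures are dropped and reported, not fatal;
      * records without an activity score are dropped ("no score");
      * structures with no carbon atom are dropped ("nonorganic");
      * same-structure records with consistent binary labels collapse into one
        record keeping every source id (score = mean of member scores);
      * same-structure records with conflicting binary labels are removed
        entirely ("conflicting label") — a safe default for label integrity.

    Returns (curated records, removal report) where the report holds one
    (record_id, reason) row per dropped input record.
    """
    report: list[tuple[str, str]] = []
    groups: dict[str, list[RawRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.activity_score is None:
            report.append((rec.record_id, "no score"))
            continue
        key = structure_key(rec.smiles)
        if key is None:
            report.append((rec.record_id, "unparseable"))
            continue
        if not _has_carbon(key):
            report.append((rec.record_id, "nonorganic"))
            continue
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(rec)

    curated: list[MoleculeRecord] = []
    for key in order:
        members = groups[key]
        labels = {assign_label(m.activity_score) for m in members}
        if len(labels) > 1:
            report.extend((m.record_id, "conflicting label") for m in members)
            continue
        score = float(sum(m.activity_score for m in members) / len(members))
        curated.append(
            MoleculeRecord(
                structure_key=key,
                label=labels.pop(),
                activity_score=score,
                source_ids=tuple(m.record_id for m in members),
            )
        )
    return curated, report


# ---------------------------------------------------------------------------
# Wash: protonation + coordinate generation
# ---------------------------------------------------------------------------

_uncharger = rdMolStandardize.Uncharger()

# Dominant-protomer rule table at pH 7 (an explicit approximation, not a pKa
# predictor): acids well below pH 7 deprotonated, basic aliphatic amines
# protonated. Each rule is (SMARTS for the titratable atom, charge delta,
# fires-when predicate over pH).
_DOMINANT_RULES: list[tuple[str, int, object]] = [
    # carboxylic acid O-H -> carboxylate (pKa ~4.8)
    ("[OX2H1][CX3](=O)", -1, lambda ph: ph > 4.8),
    # sulfonic acid O-H -> sulfonate (pKa ~ -1)
    ("[OX2H1][SX4](=O)(=O)", -1, lambda ph: ph > 0.0),
    # aliphatic amine N -> ammonium (conjugate-acid pKa ~10); excludes
    # amides, anilines/aryl-N and aromatic nitrogen
    ("[NX3;H2,H1,H0;+0;!$(N~[#6X3]=[O,S,N]);!$(N-a);!$(n)]", +1, lambda ph: ph < 9.5),
]


def _apply_dominant(mol: Chem.Mol, ph: float) -> Chem.Mol:
    rw = Chem.RWMol(mol)
    for smarts, delta, fires in _DOMINANT_RULES:
        if not fires(ph):
            continue
        patt = Chem.MolFromSmarts(smarts)
        for match in rw.GetSubstructMatches(patt):
            atom = rw.GetAtomWithIdx(match[0])
            if atom.GetFormalCharge() != 0:
                continue
            if delta < 0 and atom.GetTotalNumHs() >= 1:
                atom.SetFormalCharge(-1)
                atom.SetNumExplicitHs(max(0, atom.GetNumExplicitHs() - 1))
                atom.SetNoImplicit(True)
            elif delta > 0:
                atom.SetFormalCharge(+1)
                atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
                atom.SetNoImplicit(True)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def _derive_seed(seed: int, mol_id: str) -> int:
    """Per-molecule seed stable under library reordering: seed XOR crc32(id)."""
    return (int(seed) ^ zlib.crc32(mol_id.encode("utf8"))) & 0x7FFFFFFF


def _protonate(mol: Chem.Mol, protonation: str, ph: float) -> Chem.Mol:
    if protonation == "none":
        return mol
    if protonation == "neutralize":
        return _uncharger.uncharge(mol)
    return _apply_dominant(mol, ph)


def _embed(mol: Chem.Mol, seed: int, optimize: bool) -> Chem.Mol:
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise EmbeddingError(f"3D embedding failed for {Chem.MolToSmiles(mol)}")
    if optimize:
        try:
            if AllChem.MMFFHasAllMoleculeParams(mol):
                AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
            else:
                AllChem.UFFOptimizeMolecule(mol, maxIters=500)
        except Exception as exc:  # pragma: no cover - force-field edge cases
            raise EmbeddingError(f"force-field optimisation failed: {exc}") from exc
    return mol


def _coordinates(mol: Chem.Mol, mode: str, seed: int) -> Chem.Mol:
    if mode == "depict2d":
        mol = Chem.Mol(mol)
        rdDepictor.Compute2DCoords(mol)
        return mol
    # rebuild3d: seeded distance-geometry embedding; corina_like: the same
    # embedding followed by force-field refinement, yielding exactly one
    # low-energy conformer per molecule.
    return _embed(mol, seed, optimize=(mode == "corina_like"))


def wash(record: MoleculeRecord | str, spec: WashSpec, seed: int = 0, mol_id: Optional[str] = None) -> Molecule3D:
    """Standardise protonation and generate coordinates for one molecule.

    Deterministic: the same (record, spec, seed) triple always yields
    identical coordinates. The per-molecule RNG seed mixes the molecule id so
    results do not depend on library order.
    """
    if isinstance(record, MoleculeRecord):
        smiles = record.structure_key
        mid = mol_id or record.mol_id
    else:
        smiles = record
        mid = mol_id or smiles
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable structure {smiles!r}")

    dseed = _derive_seed(seed, mid)
    mol = _protonate(mol, spec.protonation, spec.ph)
    mol = _coordinates(mol, spec.coordinates, dseed)
    if spec.chained is not None:
        prot2, coords2 = spec.chained
        # stage two re-derives from the stage-one graph; intermediate
        # coordinates do not influence the final conformer
        graph = Chem.RemoveHs(mol)
        graph = _protonate(graph, prot2, spec.ph)
        mol = _coordinates(graph, coords2, dseed)

    conf = mol.GetConformer()
    elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
    coords = tuple(
        (float(conf.GetAtomPosition(i).x), float(conf.GetAtomPosition(i).y), float(conf.GetAtomPosition(i).z))
        for i in range(mol.GetNumAtoms())
    )
    charges = tuple(a.GetFormalCharge() for a in mol.GetAtoms())
    bonds = tuple(
        sorted((min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()), max(b.GetBeginAtomIdx(), b.GetEndAtomIdx())) for b in mol.GetBonds())
    )
    return Molecule3D(mol_id=mid, elements=elements, coords=coords, formal_charges=charges, bonds=bonds)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_smiles_table(path: str | Path) -> list[RawRecord]:
    """Read a CSV/TSV with (id, smiles, score) header columns (case-insensitive)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        id_col, smi_col, score_col = cols["id"], cols["smiles"], cols["score"]
    except KeyError as exc:
        raise ValueError(f"table {path} must have id, smiles, score columns; found {list(df.columns)}") from exc
    records = []
    for _, row in df.iterrows():
        score = row[score_col]
        records.append(
            RawRecord(
                record_id=str(row[id_col]),
                smiles=str(row[smi_col]),
                activity_score=None if pd.isna(score) else float(score),
            )
        )
    return records


def write_smiles_table(records: Iterable[RawRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.record_id, r.smiles, r.activity_score) for r in records],
        columns=["id", "smiles", "score"],
    )
    df.to_csv(path, index=False)


def read_sdf(path: str | Path, score_field: str = "score") -> list[RawRecord]:
    """Read an SDF; the activity score comes from a named data field."""
    records = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path), removeHs=False)):
        if mol is None:
            records.append(RawRecord(record_id=f"sdf_{i}", smiles="*invalid*", activity_score=None))
            continue
        rid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf_{i}"
        score = float(mol.GetProp(score_field)) if mol.HasProp(score_field) else None
        records.append(RawRecord(record_id=rid, smiles=Chem.MolToSmiles(Chem.RemoveHs(mol)), activity_score=score))
    return records


def write_molecules_sdf(
    mols: Sequence[Molecule3D],
    labels: Sequence[str],
    path: str | Path,
    scores: Optional[Sequence[float]] = None,
) -> None:
    """Write prepared molecules as V2000 SDF with label/score data fields."""
    writer = Chem.SDWriter(str(path))
    writer.SetForceV3000(False)
    for k, m in enumerate(mols):
        rw = Chem.RWMol()
        for sym, q in zip(m.elements, m.formal_charges):
            a = Chem.Atom(sym)
            a.SetFormalCharge(q)
            a.SetNoImplicit(True)
            rw.AddAtom(a)
        for i, j in m.bonds:
            rw.AddBond(i, j, Chem.BondType.SINGLE)
        conf = Chem.Conformer(m.n_atoms)
        for i, (x, y, z) in enumerate(m.coords):
            conf.SetAtomPosition(i, (x, y, z))
        mol = rw.GetMol()
        mol.AddConformer(conf)
        Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS)
        mol.SetProp("_Name", m.mol_id)
        mol.SetProp("label", str(labels[k]))
        if scores is not None:
            mol.SetProp("score", repr(float(scores[k])))
        writer.write(mol)
    writer.close()


def read_molecules_sdf(path: str | Path) -> tuple[list[Molecule3D], list[str]]:
    """Read prepared molecules (with stored bonds/coordinates) and labels back."""
    mols, labels = [], []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)):
        if mol is None:
            continue
        conf = mol.GetConformer()
        m3d = Molecule3D(
            mol_id=mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf_{i}",
            elements=tuple(a.GetSymbol() for a in mol.GetAtoms()),
            coords=tuple(
                (float(conf.GetAtomPosition(k).x), float(conf.GetAtomPosition(k).y), float(conf.GetAtomPosition(k).z))
                for k in range(mol.GetNumAtoms())
            ),
            formal_charges=tuple(a.GetFormalCharge() for a in mol.GetAtoms()),
            bonds=tuple(
                sorted((min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()), max(b.GetBeginAtomIdx(), b.GetEndAtomIdx())) for b in mol.GetBonds())
            ),
        )
        mols.append(m3d)
        labels.append(mol.GetProp("label") if mol.HasProp("label") else "")
    return mols, labels


def write_removal_report(report: Sequence[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(report, columns=["record_id", "reason"]).to_csv(path, index=False)
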