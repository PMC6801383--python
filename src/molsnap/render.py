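"""Deterministic ball-and-stick snapshot rendering over a rotation grid.

Each prepared 3D molecule is photographed from every rotation in the
Cartesian product of per-axis angle grids ({i*step : i*step < 360} per axis)
and written as a fixed-size RGB PNG. Depiction follows the conventional
ball-and-stick recipe: CPK-colored atom spheres scaled to a percentage of the
van der Waals radius (AT), bond cylinders of fixed radius (BR), with bonds
perceived from interatomic distances between a minimum bond distance (MBD)
and the covalent-radii sum plus a tolerance (BT). Rendering is a pure
function of its inputs: identical molecules, rotations and parameters yield
byte-identical images.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from ._elements import covalent_radius, cpk_color, vdw_radius
from .chem_io import Molecule3D, write_molecules_sdf

logger = logging.getLogger(__name__)

_LIGHT = np.array([-0.45, 0.45, 0.77])
_LIGHT = _LIGHT / np.linalg.norm(_LIGHT)
_AMBIENT = 0.35


@dataclass(frozen=True)
class Rotation:
    """Rotation triple in degrees, one value per axis, each in [0, 360)."""

    rx: float
    ry: float
    rz: float

    def __post_init__(self):
        for v in (self.rx, self.ry, self.rz):
            if not (0 <= v < 360):
                raise ValueError(f"rotation component {v} outside [0, 360)")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.rx, self.ry, self.rz)


@dataclass(frozen=True)
class RenderParams:
    """All depiction parameters.

    angle_step : per-axis capture increment in degrees (0 < step <= 360)
    mps        : molecules per intermediate structure-file chunk (IO only)
    zf         : zoom factor, % of the image edge filled by the bounding sphere
    at         : atom sphere radius as % of the van der Waals radius
    br         : bond cylinder radius in milli-Ångström
    mbd        : minimum bond distance in Å (closer pairs are clashes)
    bt         : bond tolerance in Å added to the covalent-radii sum
    pixel      : image edge length in pixels
    """

    angle_step: tuple[float, float, float] = (280.0, 280.0, 280.0)
    mps: int = 100
    zf: float = 100.0
    at: float = 23.0
    br: float = 14.5
    mbd: float = 0.4
    bt: float = 0.8
    pixel: int = 256
    format: str = "png"
    background: tuple[int, int, int] = (255, 255, 255)

    def __post_init__(self):
        for step in self.angle_step:
            if not (0 < step <= 360):
                raise ValueError(f"angle step {step} outside (0, 360]")
        if self.pixel <= 0 or self.mps <= 0:
            raise ValueError("pixel and mps must be positive")
        for name in ("zf", "at", "br", "mbd", "bt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.format != "png":
            raise ValueError("only png output is supported")


def enumerate_rotations(angle_step: tuple[float, float, float]) -> list[Rotation]:
    """Enumerate the rotation grid for a per-axis angle increment.

    Per axis the angles are {i*step : i >= 0, i*step < 360}; the result is
    the Cartesian product in lexicographic (rx, ry, rz) order, so the grid
    has prod(ceil(360/step)) rotations: 1 at 360°, 8 at 280°, 216 at 60°,
    1000 at 38°.
    """
    axes = []
    for step in angle_step:
        if not (0 < step <= 360):
            raise ValueError(f"angle step {step} outside (0, 360]")
        axes.append([i * step for i in range(math.ceil(360.0 / step))])
    return [Rotation(x, y, z) for x in axes[0] for y in axes[1] for z in axes[2]]


def perceive_bonds(
    elements: Sequence[str],
    coords: Sequence[tuple[float, float, float]] | np.ndarray,
    mbd: float = 0.4,
    bt: float = 0.8,
) -> list[tuple[int, int]]:
    """Distance-based bond perception.

    Atoms i < j are bonded iff mbd <= d(i,j) <= r_cov(i) + r_cov(j) + bt,
    with covalent radii from the shipped element table. Pairs closer than
    mbd that would otherwise bond are logged as steric clashes.
    """
    pts = np.asarray(coords, dtype=float)
    if len(elements) != len(pts):
        raise ValueError("elements and coords length mismatch")
    radii = np.array([covalent_radius(sym) for sym in elements])
    n = len(elements)
    if n < 2:
        return []
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    cutoff = radii[:, None] + radii[None, :] + bt
    iu, ju = np.triu_indices(n, k=1)
    bonded = (d[iu, ju] >= mbd) & (d[iu, ju] <= cutoff[iu, ju])
    clashes = (d[iu, ju] < mbd) & (d[iu, ju] <= cutoff[iu, ju])
    for i, j in zip(iu[clashes], ju[clashes]):
        logger.warning("steric clash: atoms %d-%d at %.3f Å (< mbd %.2f Å)", i, j, d[i, j], mbd)
    return [(int(i), int(j)) for i, j in zip(iu[bonded], ju[bonded])]


def _rotation_matrix(rot: Rotation) -> np.ndarray:
    """Right-handed rotation: x-axis first, then y, then z."""
    ax, ay, az = (math.radians(v) for v in rot.as_tuple())
    cx, sx = math.cos(ax), math.sin(ax)
    cy, sy = math.cos(ay), math.sin(ay)
    cz, sz = math.cos(az), math.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _draw_sphere(img, zbuf, cx, cy, pr, zc, rw, color, scale):
    """Rasterise a lit sphere into the image with z-testing."""
    size = img.shape[0]
    x0, x1 = max(0, int(math.floor(cx - pr))), min(size - 1, int(math.ceil(cx + pr)))
    y0, y1 = max(0, int(math.floor(cy - pr))), min(size - 1, int(math.ceil(cy + pr)))
    if x0 > x1 or y0 > y1 or pr <= 0:
        return
    xs = np.arange(x0, x1 + 1) + 0.5
    ys = np.arange(y0, y1 + 1) + 0.5
    dx = (xs[None, :] - cx) / pr
    dy = (ys[:, None] - cy) / pr
    d2 = dx * dx + dy * dy
    mask = d2 <= 1.0
    if not mask.any():
        return
    nz = np.sqrt(np.clip(1.0 - d2, 0.0, 1.0))
    # surface depth in world units (viewer looks down +z)
    z = zc + nz * rw
    patchz = zbuf[y0 : y1 + 1, x0 : x1 + 1]
    win = mask & (z > patchz)
    if not win.any():
        return
    # lambert shading; screen y grows downward, so the normal's y flips
    shade = _AMBIENT + (1 - _AMBIENT) * np.clip(
        dx * _LIGHT[0] - dy * _LIGHT[1] + nz * _LIGHT[2], 0.0, 1.0
    )
    patch = img[y0 : y1 + 1, x0 : x1 + 1]
    for c in range(3):
        ch = patch[:, :, c]
        ch[win] = np.clip(color[c] * shade[win], 0, 255).astype(np.uint8)
    patchz[win] = z[win]


def _draw_bond(img, zbuf, a, b, za, zb, halfwidth, color_a, color_b):
    """Rasterise a bond as a z-interpolated thick segment, split-colored."""
    size = img.shape[0]
    ax, ay = a
    bx, by = b
    x0 = max(0, int(math.floor(min(ax, bx) - halfwidth)))
    x1 = min(size - 1, int(math.ceil(max(ax, bx) + halfwidth)))
    y0 = max(0, int(math.floor(min(ay, by) - halfwidth)))
    y1 = min(size - 1, int(math.ceil(max(ay, by) + halfwidth)))
    if x0 > x1 or y0 > y1:
        return
    xs = np.arange(x0, x1 + 1) + 0.5
    ys = np.arange(y0, y1 + 1) + 0.5
    px = np.broadcast_to(xs[None, :], (len(ys), len(xs)))
    py = np.broadcast_to(ys[:, None], (len(ys), len(xs)))
    vx, vy = bx - ax, by - ay
    seg2 = vx * vx + vy * vy
    if seg2 == 0:
        return
    t = np.clip(((px - ax) * vx + (py - ay) * vy) / seg2, 0.0, 1.0)
    dist2 = (px - (ax + t * vx)) ** 2 + (py - (ay + t * vy)) ** 2
    mask = dist2 <= halfwidth * halfwidth
    if not mask.any():
        return
    z = za + t * (zb - za)
    patchz = zbuf[y0 : y1 + 1, x0 : x1 + 1]
    win = mask & (z > patchz)
    if not win.any():
        return
    shade = 0.85  # flat-shaded cylinder
    patch = img[y0 : y1 + 1, x0 : x1 + 1]
    near_a = t < 0.5
    for c in range(3):
        ch = patch[:, :, c]
        vals = np.where(near_a, color_a[c] * shade, color_b[c] * shade)
        ch[win] = np.clip(vals[win], 0, 255).astype(np.uint8)
    patchz[win] = z[win]


def render_snapshot(
    mol: Molecule3D,
    rot: Rotation,
    params: RenderParams = RenderParams(),
    bonds: Optional[Sequence[tuple[int, int]]] = None,
) -> np.ndarray:
    """Render one rotated view as a (pixel, pixel, 3) uint8 RGB array.

    Coordinates rotate about the molecule centroid (x, then y, then z axis,
    right-handed) and project orthographically. The projection scale is set
    from the rotation-invariant bounding sphere so the molecule fills zf% of
    the image edge in every view, and the same scale applies to all rotations
    of the molecule. The output is a pure function of the inputs.
    """
    if mol.n_atoms == 0:
        raise ValueError("cannot render an empty molecule")
    pts = np.asarray(mol.coords, dtype=float)
    pts = pts - pts.mean(axis=0)
    if bonds is None:
        bonds = perceive_bonds(mol.elements, pts, params.mbd, params.bt)

    draw_r = np.array([vdw_radius(s) * params.at / 100.0 for s in mol.elements])
    bound = float(np.max(np.linalg.norm(pts, axis=1) + draw_r))
    bound = max(bound, 1e-6)
    scale = (params.zf / 100.0) * params.pixel / (2.0 * bound)

    rpts = pts @ _rotation_matrix(rot).T
    half = params.pixel / 2.0
    sx = half + scale * rpts[:, 0]
    sy = half - scale * rpts[:, 1]
    sz = rpts[:, 2]

    img = np.empty((params.pixel, params.pixel, 3), dtype=np.uint8)
    img[:, :] = np.array(params.background, dtype=np.uint8)
    zbuf = np.full((params.pixel, params.pixel), -np.inf)

    colors = [cpk_color(s) for s in mol.elements]
    bond_halfwidth = max(scale * params.br / 1000.0, 1.0)
    for i, j in bonds:
        _draw_bond(
            img, zbuf, (sx[i], sy[i]), (sx[j], sy[j]), sz[i], sz[j],
            bond_halfwidth, colors[i], colors[j],
        )
    order = np.argsort(sz, kind="stable")  # back to front (z-buffer makes this cosmetic)
    for i in order:
        _draw_sphere(img, zbuf, sx[i], sy[i], scale * draw_r[i], sz[i], draw_r[i], colors[i], scale)
    return img


def save_png(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(image, mode="RGB").save(str(path), format="PNG")


def snapshot_filename(mol_id: str, rot: Rotation) -> str:
    def fmt(v: float) -> str:
        return str(int(v)) if float(v).is_integer() else str(v)

    return f"{mol_id}_{fmt(rot.rx)}_{fmt(rot.ry)}_{fmt(rot.rz)}.png"


def snap_dataset(
    mols: Sequence[Molecule3D],
    labels: Sequence[str],
    params: RenderParams,
    outdir: str | Path,
    write_chunks: bool = False,
) -> pd.DataFrame:
    """Render every molecule at every enumerated rotation.

    Returns the snapshot manifest: one row per (molecule, rotation) with
    columns (mol_id, rx, ry, rz, path, label). Molecules are processed in
    chunks of ``params.mps`` structures; with ``write_chunks`` each chunk is
    also written as an intermediate SDF. Chunking never affects image
    content. Per-molecule render failures are logged and reported in
    ``render_failures.csv``; the pipeline continues.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rotations = enumerate_rotations(params.angle_step)
    rows: list[tuple] = []
    failures: list[tuple[str, str]] = []
    for start in range(0, len(mols), params.mps):
        chunk = list(range(start, min(start + params.mps, len(mols))))
        if write_chunks and chunk:
            write_molecules_sdf(
                [mols[k] for k in chunk],
                [labels[k] for k in chunk],
                outdir / f"chunk_{start // params.mps:04d}.sdf",
            )
        for k in chunk:
            mol, label = mols[k], labels[k]
            try:
                pts = np.asarray(mol.coords, dtype=float)
                bonds = perceive_bonds(mol.elements, pts - pts.mean(axis=0), params.mbd, params.bt)
                for rot in rotations:
                    img = render_snapshot(mol, rot, params, bonds=bonds)
                    fname = snapshot_filename(mol.mol_id, rot)
                    save_png(img, outdir / fname)
                    rows.append((mol.mol_id, rot.rx, rot.ry, rot.rz, str(outdir / fname), label))
            except Exception as exc:
                logger.error("render failed for %s: %s", mol.mol_id, exc)
                failures.append((mol.mol_id, str(exc)))
    manifest = pd.DataFrame(rows, columns=["mol_id", "rx", "ry", "rz", "path", "label"])
    if failures:
        pd.DataFrame(failures, columns=["mol_id", "error"]).to_csv(outdir / "render_failures.csv", index=False)
    return manifest


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"mol_id": str, "label": str})
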