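"""Element property tables used by bond perception and rendering.

Covalent radii (Å) follow the single-bond values of Cordero et al.,
rounded to 2 decimals, with carbon fixed at the classic 0.77 Å sp3 value
so that a C–C bond at 1.54 Å sits exactly at twice the radius. Van der
Waals radii (Å) are Bondi's. CPK colors are the conventional
element-to-color depiction mapping (RGB, 0–255).
"""

from __future__ import annotations

COVALENT_RADIUS: dict[str, float] = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.77, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Zn": 1.22, "Fe": 1.32, "Cu": 1.32, "Mn": 1.39,
    "Se": 1.20, "Br": 1.20, "Kr": 1.16,
    "I": 1.39, "Xe": 1.40, "Sn": 1.39, "As": 1.19, "Hg": 1.32, "Pb": 1.46,
}

VDW_RADIUS: dict[str, float] = {
    "H": 1.20, "He": 1.40,
    "Li": 1.82, "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "Ne": 1.54,
    "Na": 2.27, "Mg": 1.73, "Al": 1.84, "Si": 2.10, "P": 1.80, "S": 1.80,
    "Cl": 1.75, "Ar": 1.88,
    "K": 2.75, "Ca": 2.31, "Zn": 1.39, "Fe": 1.95, "Cu": 1.40, "Mn": 1.95,
    "Se": 1.90, "Br": 1.85, "Kr": 2.02,
    "I": 1.98, "Xe": 2.16, "Sn": 2.17, "As": 1.85, "Hg": 1.55, "Pb": 2.02,
}

# Conventional CPK mapping; elements not listed render in fallback pink.
CPK_COLOR: dict[str, tuple[int, int, int]] = {
    "H": (255, 255, 255),
    "C": (144, 144, 144),
    "N": (48, 80, 248),
    "O": (255, 13, 13),
    "F": (144, 224, 80),
    "Cl": (31, 240, 31),
    "Br": (166, 41, 41),
    "I": (148, 0, 148),
    "S": (255, 255, 48),
    "P": (255, 128, 0),
    "B": (255, 181, 181),
    "Si": (240, 200, 160),
    "Na": (171, 92, 242),
    "K": (143, 64, 212),
    "Mg": (138, 255, 0),
    "Ca": (61, 255, 0),
    "Fe": (224, 102, 51),
    "Zn": (125, 128, 176),
    "Cu": (200, 128, 51),
    "Se": (255, 161, 0),
}

FALLBACK_COLOR: tuple[int, int, int] = (255, 105, 180)


def covalent_radius(symbol: str) -> float:
    """Return the covalent radius in Å, raising for unknown symbols."""
    try:
        return COVALENT_RADIUS[symbol]
    except KeyError:
        raise KeyError(f"no covalent radius tabulated for element {symbol!r}") from None


def vdw_radius(symbol: str) -> float:
    try:
        return VDW_RADIUS[symbol]
    except KeyError:
        raise KeyError(f"no van der Waals radius tabulated for element {symbol!r}") from None


def cpk_color(symbol: str) -> tuple[int, int, int]:
    return CPK_COLOR.get(symbol, FALLBACK_COLOR)
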