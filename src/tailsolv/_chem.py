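"""Shared amino-acid tables: codes, heavy-atom topology, elements, masses,
van der Waals radii, hydrophobicity, and background compositions.

Everything downstream operates in heavy-atom mode; hydrogens are accepted on
input but carry no role in SASA or energy evaluation.
"""

from __future__ import annotations

import numpy as np

# --- one/three letter codes (20 standard amino acids) ---------------------

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AA3 = tuple(sorted(THREE_TO_ONE))
STANDARD_AA1 = tuple(sorted(ONE_TO_THREE))

# --- heavy-atom topology (PDB v3 atom names, backbone first) --------------

BACKBONE_ATOMS = ("N", "CA", "C", "O")

SIDE_CHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}

HEAVY_ATOMS: dict[str, tuple[str, ...]] = {
    code3: BACKBONE_ATOMS + side for code3, side in SIDE_CHAIN_ATOMS.items()
}

SUPPORTED_ELEMENTS = ("C", "N", "O", "S", "H")

ATOMIC_MASS = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "H": 1.008}

# Bundled per-element van der Waals radii (Å) used by the SASA engine.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}


def element_of(atom_name: str) -> str:
    """Infer the element from a PDB heavy-atom (or hydrogen) name.

    Digits are stripped; the leading letter of the remainder is the element
    for the C/N/O/S/H set used here (e.g. ``OG1`` -> O, ``1HB`` -> H).
    """
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    first = stripped[0].upper()
    if first not in SUPPORTED_ELEMENTS:
        raise ValueError(f"unsupported element {first!r} in atom name {atom_name!r}")
    return first


# --- hydrophobicity (Kyte-Doolittle) and compositions ---------------------

KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

# Background amino-acid frequencies of globular proteins (sums to 1).
GLOBULAR_COMPOSITION = {
    "A": 0.083, "R": 0.055, "N": 0.041, "D": 0.054, "C": 0.014,
    "Q": 0.039, "E": 0.067, "G": 0.071, "H": 0.022, "I": 0.059,
    "L": 0.096, "K": 0.058, "M": 0.024, "F": 0.039, "P": 0.046,
    "S": 0.066, "T": 0.053, "W": 0.011, "Y": 0.029, "V": 0.073,
}

# Low-complexity hydrophilic tail composition: glycine/proline plus charged
# and polar residues, the signature of disorder-promoting terminal tails.
HYDROPHILIC_TAIL_COMPOSITION = {
    "G": 0.20, "P": 0.10, "R": 0.175, "K": 0.175, "S": 0.10,
    "E": 0.10, "Q": 0.05, "D": 0.05, "N": 0.05,
}

# --- deterministic free-residue template geometry -------------------------

# Atoms of a free residue (and of generated residues) sit on a fine cubic
# lattice; FINE_SPACING exceeds the 2.0 Å clash bound so any two distinct
# sites are automatically clash-free.
FINE_SPACING = 2.2  # Å


def _offset_shells(max_radius: int = 4) -> list[tuple[int, int, int]]:
    """Integer lattice offsets sorted by (euclidean norm, x, y, z)."""
    offsets = [
        (i, j, k)
        for i in range(-max_radius, max_radius + 1)
        for j in range(-max_radius, max_radius + 1)
        for k in range(-max_radius, max_radius + 1)
    ]
    offsets.sort(key=lambda o: (o[0] * o[0] + o[1] * o[1] + o[2] * o[2], o))
    return offsets


OFFSET_SHELLS = _offset_shells()


def template_coordinates(code3: str) -> dict[str, np.ndarray]:
    """Coordinates (Å) of an isolated residue in the bundled template pose.

    Atoms are assigned, in topology order (CA first so it anchors the
    template), to the nearest free fine-lattice sites around the origin.
    The construction is deterministic, so the derived quantities (e.g. the
    fully-hydrated reference SASA) are bit-reproducible.
    """
    if code3 not in HEAVY_ATOMS:
        raise KeyError(code3)
    names = ("CA",) + tuple(n for n in HEAVY_ATOMS[code3] if n != "CA")
    taken: set[tuple[int, int, int]] = set()
    coords: dict[str, np.ndarray] = {}
    for name in names:
        for off in OFFSET_SHELLS:
            if off not in taken:
                taken.add(off)
                coords[name] = np.asarray(off, dtype=float) * FINE_SPACING
                break
    return coords
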