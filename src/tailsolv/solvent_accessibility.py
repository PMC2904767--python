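"""Solvent-accessible surface area by Shrake–Rupley quadrature.

A probe sphere (default 1.4 Å, a water molecule) is rolled over the van der
Waals spheres of the heavy atoms; each atom's SASA is the fraction of
golden-spiral quadrature points on its expanded sphere not occluded by any
neighbour, times the sphere area. Relative accessibility divides a residue's
SASA by that of the completely hydrated free amino acid, and residues above
a cutoff on this ratio are classified as surface.

Quadrature points ride with their atoms, so SASA is exactly invariant under
translation; under rotation the fixed point orientations shift the shadow
boundaries by at most a few quadrature cells (~0.1% of the total).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._chem import (
    STANDARD_AA3,
    THREE_TO_ONE,
    VDW_RADII,
    element_of,
    template_coordinates,
)
from .errors import ParameterizationError
from .structure_model import Atom, Chain, Residue, SegmentDefinition, StructureModel

__all__ = [
    "SasaSettings",
    "AccessibilityTable",
    "MaxSaReference",
    "shrake_rupley",
    "residue_sasa",
    "max_sa_reference",
    "relative_accessibility",
    "surface_residues",
    "sasa_fraction",
    "free_residue_model",
]


@dataclass(frozen=True)
class SasaSettings:
    """Probe radius (Å), quadrature density, and the van der Waals radius
    table keyed by element."""

    probe_radius: float = 1.4
    n_sphere_points: int = 960
    radius_table: tuple[tuple[str, float], ...] = tuple(sorted(VDW_RADII.items()))

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.n_sphere_points < 92:
            raise ValueError("n_sphere_points must be at least 92")

    @property
    def radii(self) -> dict[str, float]:
        return dict(self.radius_table)

    def radius_of(self, atom: Atom) -> float:
        try:
            return self.radii[atom.element]
        except KeyError:
            raise ParameterizationError(
                f"no van der Waals radius for atom {atom.name!r} "
                f"(element {atom.element!r})"
            ) from None


@dataclass
class AccessibilityTable:
    """Per-residue absolute (Å²) and relative solvent accessibility.

    ``frame`` columns: chain, seq_index, code1, abs_sa, rel_sa (rel_sa is NaN
    until :func:`relative_accessibility` fills it).
    """

    frame: pd.DataFrame

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


MaxSaReference = dict[str, float]  # one-letter code -> SASA of the free residue, Å²


@lru_cache(maxsize=8)
def _sphere_points(n: int) -> np.ndarray:
    """n points ~uniform on the unit sphere via the golden spiral."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = np.pi * (3.0 - np.sqrt(5.0)) * k
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _atom_arrays(model: StructureModel, settings: SasaSettings):
    atoms = list(model.heavy_atoms())
    coords = np.asarray([a.coords for a in atoms], dtype=float).reshape(len(atoms), 3)
    radii = np.asarray([settings.radius_of(a) for a in atoms], dtype=float)
    return atoms, coords, radii


def shrake_rupley(model: StructureModel, settings: SasaSettings = SasaSettings()) -> np.ndarray:
    """Per-heavy-atom SASA (Å²) in chain/residue/atom order."""
    _, coords, radii = _atom_arrays(model, settings)
    return _shrake_rupley_arrays(coords, radii, settings)


def _shrake_rupley_arrays(
    coords: np.ndarray, radii: np.ndarray, settings: SasaSettings
) -> np.ndarray:
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    probe = settings.probe_radius
    expanded = radii + probe
    unit = _sphere_points(settings.n_sphere_points)
    tree = cKDTree(coords)
    # atom j can bury points of atom i only if their expanded spheres meet
    reach = expanded.max()
    out = np.empty(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        neigh = [j for j in tree.query_ball_point(coords[i], expanded[i] + reach)
                 if j != i]
        if neigh:
            nc = coords[neigh]
            nr = expanded[neigh]
            # point is buried if inside any neighbour's expanded sphere
            d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nr**2)[None, :]).any(axis=1)
            exposed = np.count_nonzero(~buried)
        else:
            exposed = settings.n_sphere_points
        out[i] = (
            4.0 * np.pi * expanded[i] ** 2 * exposed / settings.n_sphere_points
        )
    return out


def residue_sasa(
    model: StructureModel, settings: SasaSettings = SasaSettings()
) -> AccessibilityTable:
    """Sum per-atom SASA into one row per residue (absolute column)."""
    per_atom = shrake_rupley(model, settings)
    rows = []
    k = 0
    for chain in model.chains:
        for res in chain.residues:
            n_heavy = len(res.heavy_atoms)
            rows.append(
                {
                    "chain": chain.chain_id,
                    "seq_index": res.seq_index,
                    "code1": res.code1,
                    "abs_sa": float(per_atom[k : k + n_heavy].sum()),
                    "rel_sa": np.nan,
                }
            )
            k += n_heavy
    return AccessibilityTable(frame=pd.DataFrame(rows))


def free_residue_model(code3: str) -> StructureModel:
    """An isolated residue in the bundled template pose (the "completely
    hydrated individual amino acid")."""
    coords = template_coordinates(code3)
    atoms = [
        Atom(name=name, element=element_of(name), coords=xyz, serial=i + 1)
        for i, (name, xyz) in enumerate(coords.items())
    ]
    res = Residue(code3=code3, seq_index=1, atoms=atoms)
    return StructureModel(chains=[Chain("A", [res])], label=f"free_{code3}")


@lru_cache(maxsize=8)
def _max_sa_cached(settings: SasaSettings) -> tuple[tuple[str, float], ...]:
    out = {}
    for code3 in STANDARD_AA3:
        model = free_residue_model(code3)
        out[THREE_TO_ONE[code3]] = float(shrake_rupley(model, settings).sum())
    return tuple(sorted(out.items()))


def max_sa_reference(settings: SasaSettings = SasaSettings()) -> MaxSaReference:
    """SASA (Å²) of each free amino acid, the denominator of relative SA.

    Computed with the same engine and settings as the structures it
    normalizes, from deterministic template coordinates, and cached."""
    return dict(_max_sa_cached(settings))


def relative_accessibility(
    table: AccessibilityTable, ref: MaxSaReference | None = None,
    settings: SasaSettings = SasaSettings(),
) -> AccessibilityTable:
    """Fill the relative column: absolute SA / free-residue SA.

    The ratio is deliberately not capped at 1: odd conformations may expose
    slightly more area than the reference pose, and cutoff logic is
    unaffected."""
    if ref is None:
        ref = max_sa_reference(settings)
    frame = table.frame.copy()
    unknown = sorted(set(frame["code1"]) - set(ref))
    if unknown:
        raise ParameterizationError(
            f"no free-residue reference SASA for residue type(s) {unknown}"
        )
    frame["rel_sa"] = frame["abs_sa"] / frame["code1"].map(ref)
    return AccessibilityTable(frame=frame)


def surface_residues(table: AccessibilityTable, cutoff: float) -> set[tuple[str, int]]:
    """(chain, seq_index) pairs with relative SA ≥ cutoff.

    A cutoff of 0.0 returns every residue — buried and surface alike."""
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    frame = table.frame
    if frame["rel_sa"].isna().any():
        raise ValueError("relative column not filled; call relative_accessibility first")
    sel = frame[frame["rel_sa"] >= cutoff]
    return set(zip(sel["chain"], sel["seq_index"]))


def sasa_fraction(
    model: StructureModel,
    segs: list[SegmentDefinition],
    settings: SasaSettings = SasaSettings(),
    table: AccessibilityTable | None = None,
) -> float:
    """Percentage of the intact model's total SASA contributed by the
    segments' residues (e.g. the disordered tails)."""
    if table is None:
        table = residue_sasa(model, settings)
    frame = table.frame
    total = frame["abs_sa"].sum()
    if total == 0:
        return 0.0
    in_seg = frame.apply(
        lambda row: any(
            s.chain_id == row["chain"] and s.first <= row["seq_index"] <= s.last
            for s in segs
        ),
        axis=1,
    )
    return float(100.0 * frame.loc[in_seg, "abs_sa"].sum() / total)
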