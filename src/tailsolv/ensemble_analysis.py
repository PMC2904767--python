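"""Structural descriptors and distribution statistics over conformer
ensembles: radius of gyration, optimal (Kabsch) superposition, backbone
RMSD, all-against-all pair statistics, per-frame trajectory summaries, and
placement of a query value within a reference distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._chem import ATOMIC_MASS
from .errors import (
    CorrespondenceError,
    GeometryError,
    InsufficientEnsembleError,
)
from .structure_model import Ensemble, SegmentDefinition, StructureModel, extract_segment

__all__ = [
    "RmsdMatrix",
    "ReferenceDistribution",
    "radius_of_gyration",
    "kabsch_superpose",
    "backbone_rmsd",
    "pairwise_rmsd_matrix",
    "pairwise_rmsd_stats",
    "timeseries_stats",
    "percentile_more_positive",
    "distribution_summary",
]

BACKBONE_SELECTION = ("N", "CA", "C", "O")


@dataclass
class RmsdMatrix:
    """Square symmetric backbone-RMSD matrix (Å) with model labels."""

    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RMSD matrix must be square")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0) or (v < 0).any():
            raise ValueError("RMSD matrix must be symmetric, non-negative, zero-diagonal")
        self.values = v

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t"
        )


@dataclass
class ReferenceDistribution:
    """Per-protein scalar summaries (e.g. normalized HFE, kJ/mol/residue)."""

    values: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("reference distribution must be non-empty")

    def __len__(self) -> int:
        return self.values.size


def radius_of_gyration(model: StructureModel, mass_weighted: bool = True) -> float:
    """Mass-weighted Rg (Å) over heavy atoms; uniform weights optional."""
    coords = model.heavy_coords()
    if len(coords) == 0:
        raise GeometryError("radius of gyration needs at least one atom")
    if mass_weighted:
        w = np.array([ATOMIC_MASS[a.element] for a in model.heavy_atoms()])
    else:
        w = np.ones(len(coords))
    center = (w[:, None] * coords).sum(axis=0) / w.sum()
    return float(np.sqrt((w * ((coords - center) ** 2).sum(axis=1)).sum() / w.sum()))


def _selected_coords(model: StructureModel, atom_selection) -> np.ndarray:
    pts = []
    for res in model.residues():
        for atom in res.atoms:
            if atom_selection is None or atom.name in atom_selection:
                pts.append(atom.coords)
    return np.asarray(pts, dtype=float).reshape(len(pts), 3)


def kabsch_superpose(
    mobile: StructureModel,
    target: StructureModel,
    atom_selection: tuple[str, ...] | None = BACKBONE_SELECTION,
) -> tuple[StructureModel, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns (transformed copy of mobile, rotation matrix, translation); the
    rotation is proper (det = +1). Selected atoms must correspond 1:1 in
    order."""
    x = _selected_coords(mobile, atom_selection)
    y = _selected_coords(target, atom_selection)
    if x.shape != y.shape:
        raise CorrespondenceError(
            f"selections differ in size: {x.shape[0]} vs {y.shape[0]} atoms"
        )
    if len(x) < 3:
        raise GeometryError("superposition needs at least 3 atoms")
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    if np.linalg.matrix_rank(x0, tol=1e-8) < 2:
        raise GeometryError("superposition needs 3 non-collinear atoms")
    h = x0.T @ y0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = yc - rot @ xc
    moved = mobile.copy()
    for atom in moved.atoms():
        atom.coords = rot @ atom.coords + trans
    return moved, rot, trans


def backbone_rmsd(a: StructureModel, b: StructureModel) -> float:
    """Backbone (N, CA, C, O) RMSD (Å) after optimal superposition."""
    seq_a = [r.code3 for r in a.residues()]
    seq_b = [r.code3 for r in b.residues()]
    if seq_a != seq_b:
        raise CorrespondenceError("backbone RMSD requires identical sequences")
    moved, _, _ = kabsch_superpose(a, b, BACKBONE_SELECTION)
    x = _selected_coords(moved, BACKBONE_SELECTION)
    y = _selected_coords(b, BACKBONE_SELECTION)
    return float(np.sqrt(((x - y) ** 2).sum(axis=1).mean()))


def pairwise_rmsd_matrix(
    ensemble: Ensemble, seg: SegmentDefinition | None = None
) -> RmsdMatrix:
    """All-against-all backbone RMSD, superposing on the segment itself
    (tails fitted on tails, cores on cores)."""
    if len(ensemble) < 2:
        raise InsufficientEnsembleError("pairwise RMSD needs at least 2 models")
    models = [
        extract_segment(m, seg) if seg is not None else m for m in ensemble
    ]
    n = len(models)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = backbone_rmsd(models[i], models[j])
    return RmsdMatrix(values=mat, labels=[m.label for m in ensemble])


def pairwise_rmsd_stats(
    ensemble: Ensemble, seg: SegmentDefinition | None = None
) -> tuple[float, float]:
    """Mean ± sample sd of backbone RMSD over all n(n−1)/2 unordered pairs."""
    tri = pairwise_rmsd_matrix(ensemble, seg).upper_triangle()
    sd = float(tri.std(ddof=1)) if tri.size > 1 else 0.0
    return float(tri.mean()), sd


def timeseries_stats(trajectories: list[list[float]]) -> pd.DataFrame:
    """Frame-wise mean ± sample sd of a scalar across trajectories.

    All trajectories must have equal frame counts."""
    lengths = {len(t) for t in trajectories}
    if len(lengths) != 1:
        raise ValueError(f"ragged trajectories (frame counts {sorted(lengths)})")
    arr = np.asarray(trajectories, dtype=float)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(arr.shape[1])
    return pd.DataFrame({"frame": np.arange(arr.shape[1]), "mean": mean, "sd": sd})


def percentile_more_positive(ref: ReferenceDistribution, query: float) -> float:
    """Percentage of reference values strictly greater than the query.

    Ties count as not-more-positive; a query below every value gives 100%."""
    return float(100.0 * np.count_nonzero(ref.values > query) / len(ref))


def distribution_summary(
    ref: ReferenceDistribution, n_bins: int = 20
) -> dict:
    """Sample mean, sample sd (n−1), and fixed-width histogram bins."""
    values = ref.values
    single = values.size == 1
    counts, edges = np.histogram(values, bins=n_bins)
    return {
        "mean": float(values.mean()),
        "sd": 0.0 if single else float(values.std(ddof=1)),
        "sd_undefined": bool(single),
        "n": int(values.size),
        "bin_edges": edges.tolist(),
        "bin_counts": counts.tolist(),
    }
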