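"""Protein structures as plain containers: read/write PDB, slice segments,
truncate disordered tails.

The segment vocabulary (N-tail, core, C-tail) defined here is consumed by
every downstream stage: accessibility, entropy, hydration energy, and
ensemble statistics all operate on :class:`StructureModel` /
:class:`Ensemble` objects produced by this module.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from ._chem import SUPPORTED_ELEMENTS, THREE_TO_ONE, element_of
from .errors import (
    EmptyStructureError,
    SegmentRangeError,
    UnsupportedResidueError,
)

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "Ensemble",
    "SegmentDefinition",
    "read_pdb",
    "write_pdb",
    "extract_segment",
    "complement_segments",
    "truncate_n_terminal",
    "sequence_of",
]


@dataclass
class Atom:
    """A heavy atom (or hydrogen) with Å coordinates."""

    name: str
    element: str
    coords: np.ndarray
    serial: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if self.element not in SUPPORTED_ELEMENTS:
            raise ValueError(f"atom {self.name!r}: unsupported element {self.element!r}")


@dataclass
class Residue:
    """One amino-acid residue; ``seq_index`` keeps the author's numbering."""

    code3: str
    seq_index: int
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    @property
    def code1(self) -> str:
        try:
            return THREE_TO_ONE[self.code3]
        except KeyError:
            raise UnsupportedResidueError(
                f"residue {self.code3!r} at position {self.seq_index} is not a "
                "standard amino acid"
            ) from None

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element != "H"]


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class StructureModel:
    """One conformer: ordered chains of residues of heavy atoms."""

    chains: list[Chain] = field(default_factory=list)
    label: str = ""

    # -- iteration helpers -------------------------------------------------

    def residues(self):
        for chain in self.chains:
            yield from chain.residues

    def atoms(self):
        for res in self.residues():
            yield from res.atoms

    def heavy_atoms(self):
        for res in self.residues():
            yield from res.heavy_atoms

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise SegmentRangeError(f"no chain {chain_id!r} in model {self.label!r}")

    def heavy_coords(self) -> np.ndarray:
        """(n, 3) array of heavy-atom coordinates in chain/residue order."""
        pts = [a.coords for a in self.heavy_atoms()]
        return np.asarray(pts, dtype=float).reshape(len(pts), 3)

    def copy(self) -> "StructureModel":
        return _copy.deepcopy(self)

    def validate(self) -> None:
        """Check the container invariants (unique serials, ≥1 residue)."""
        if self.n_residues < 1:
            raise EmptyStructureError(f"model {self.label!r} has no residues")
        serials = [a.serial for a in self.atoms()]
        if len(set(serials)) != len(serials):
            raise ValueError(f"model {self.label!r} has duplicate atom serials")
        for chain in self.chains:
            idx = [(r.seq_index, r.icode) for r in chain.residues]
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError(
                    f"chain {chain.chain_id!r}: residue numbering not strictly increasing"
                )


@dataclass
class Ensemble:
    """Ordered conformers sharing one sequence and atom naming.

    ``frame_times`` (ps) is present for trajectory frames and absent for
    independent-endpoint sets.
    """

    models: list[StructureModel]
    frame_times: list[float] | None = None

    def __post_init__(self) -> None:
        if not self.models:
            raise EmptyStructureError("ensemble has no models")
        ref = self._signature(self.models[0])
        for m in self.models[1:]:
            if self._signature(m) != ref:
                raise ValueError(
                    f"model {m.label!r} differs in sequence or atom naming from "
                    f"{self.models[0].label!r}"
                )
        if self.frame_times is not None:
            if len(self.frame_times) != len(self.models):
                raise ValueError("frame_times length must match number of models")
            if any(b < a for a, b in zip(self.frame_times, self.frame_times[1:])):
                raise ValueError("frame_times must be non-decreasing")

    @staticmethod
    def _signature(model: StructureModel) -> tuple:
        return tuple(
            (c.chain_id, r.code3, r.seq_index, tuple(a.name for a in r.atoms))
            for c in model.chains
            for r in c.residues
        )

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def __getitem__(self, i):
        return self.models[i]


@dataclass(frozen=True)
class SegmentDefinition:
    """A named, inclusive 1-based residue range on one chain.

    ``first``/``last`` refer to residue ``seq_index`` values, matching the
    convention of counting residues from 1 (e.g. an 80-residue N-tail is
    residues 1–80 of its chain).
    """

    name: str
    chain_id: str
    first: int
    last: int

    def __post_init__(self) -> None:
        if self.first > self.last:
            raise SegmentRangeError(
                f"segment {self.name!r}: first ({self.first}) > last ({self.last})"
            )

    def covers(self, residue: Residue) -> bool:
        return self.first <= residue.seq_index <= self.last


# --------------------------------------------------------------------------
# PDB I/O (gemmi-backed)
# --------------------------------------------------------------------------


def _pick_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve alternate locations: highest occupancy, ties broken by the
    alphabetically first altloc label."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
        elif (atom.occ, _altloc_rank(atom)) > (prev.occ, _altloc_rank(prev)):
            best[atom.name] = atom
    return list(best.values())


def _altloc_rank(atom: gemmi.Atom) -> int:
    # '' sorts before 'A'; among labelled conformers 'A' wins ties.
    return -ord(atom.altloc) if atom.altloc else 0


def read_pdb(path: str | Path) -> Ensemble:
    """Read a (possibly multi-MODEL) PDB file into an :class:`Ensemble`.

    HETATM records and waters are skipped; alternate locations are resolved
    to the highest-occupancy conformer. Raises
    :class:`~tailsolv.errors.EmptyStructureError` if no standard residues
    remain.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise IOError(f"cannot read PDB file {path}: {exc}") from exc

    models: list[StructureModel] = []
    for gmodel in st:
        chains: list[Chain] = []
        for gchain in gmodel:
            residues: list[Residue] = []
            for gres in gchain:
                if gres.is_water() or gres.het_flag == "H":
                    continue
                if gres.name not in THREE_TO_ONE:
                    continue
                atoms = [
                    Atom(
                        name=a.name,
                        element=element_of(a.name),
                        coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        serial=a.serial,
                    )
                    for a in _pick_altlocs(gres)
                ]
                residues.append(
                    Residue(
                        code3=gres.name,
                        seq_index=gres.seqid.num,
                        atoms=atoms,
                        icode=(gres.seqid.icode or "").strip(),
                    )
                )
            if residues:
                chains.append(Chain(chain_id=gchain.name, residues=residues))
        if chains:
            models.append(
                StructureModel(chains=chains, label=f"{path.stem}:{gmodel.num}")
            )
    if not models:
        raise EmptyStructureError(f"{path}: no standard protein residues found")
    if len(models) == 1:
        models[0].label = path.stem
    return Ensemble(models=models)


def write_pdb(ensemble: Ensemble | StructureModel, path: str | Path) -> None:
    """Write an ensemble (or a single model) as a fixed-column PDB file.

    Multi-model ensembles use MODEL/ENDMDL blocks; coordinates are written
    to the format's 3-decimal precision.
    """
    if isinstance(ensemble, StructureModel):
        ensemble = Ensemble(models=[ensemble])
    st = gemmi.Structure()
    st.name = ensemble.models[0].label or "tailsolv"
    for i, model in enumerate(ensemble.models, start=1):
        gmodel = gemmi.Model(i)
        serial = 0
        for chain in model.chains:
            gchain = gemmi.Chain(chain.chain_id)
            for res in chain.residues:
                gres = gemmi.Residue()
                gres.name = res.code3
                gres.seqid = gemmi.SeqId(res.seq_index, res.icode or " ")
                gres.het_flag = "A"
                for atom in res.atoms:
                    serial += 1
                    ga = gemmi.Atom()
                    ga.name = atom.name
                    ga.element = gemmi.Element(atom.element)
                    ga.pos = gemmi.Position(*atom.coords)
                    ga.occ = 1.0
                    ga.serial = serial
                    gres.add_atom(ga)
                gchain.add_residue(gres)
            gmodel.add_chain(gchain)
        st.add_model(gmodel)
    st.setup_entities()
    path = Path(path)
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write PDB file {path}: {exc}") from exc


# --------------------------------------------------------------------------
# Slicing and truncation
# --------------------------------------------------------------------------


def extract_segment(model: StructureModel, seg: SegmentDefinition) -> StructureModel:
    """Return a new model holding exactly residues [first..last] of the
    segment's chain; the input is untouched."""
    chain = model.chain(seg.chain_id)
    present = {r.seq_index for r in chain.residues}
    missing = [i for i in (seg.first, seg.last) if i not in present]
    if missing:
        raise SegmentRangeError(
            f"segment {seg.name!r} [{seg.first}..{seg.last}] not within chain "
            f"{seg.chain_id!r} (missing residue index {missing[0]})"
        )
    kept = [_copy.deepcopy(r) for r in chain.residues if seg.covers(r)]
    return StructureModel(
        chains=[Chain(chain_id=seg.chain_id, residues=kept)],
        label=f"{model.label}|{seg.name}" if model.label else seg.name,
    )


def complement_segments(
    model: StructureModel, segs: list[SegmentDefinition]
) -> StructureModel:
    """Model with every residue NOT covered by any of ``segs`` (the core,
    when given the tail segments)."""
    chains: list[Chain] = []
    for chain in model.chains:
        kept = [
            _copy.deepcopy(r)
            for r in chain.residues
            if not any(s.chain_id == chain.chain_id and s.covers(r) for s in segs)
        ]
        if kept:
            chains.append(Chain(chain_id=chain.chain_id, residues=kept))
    if not chains:
        raise EmptyStructureError("complement of segments is empty")
    return StructureModel(chains=chains, label=f"{model.label}|complement")


def truncate_n_terminal(
    model: StructureModel, k: int, chain_ids: list[str] | None = None
) -> StructureModel:
    """Remove the first ``k`` residues of each designated chain (all chains
    by default), preserving the original numbering of the survivors."""
    if k < 0:
        raise SegmentRangeError(f"truncation length k={k} must be non-negative")
    out = model.copy()
    out.label = f"{model.label}|delta{k}" if model.label else f"delta{k}"
    for chain in out.chains:
        if chain_ids is not None and chain.chain_id not in chain_ids:
            continue
        if k >= len(chain.residues):
            raise SegmentRangeError(
                f"cannot remove {k} residues from chain {chain.chain_id!r} of "
                f"length {len(chain.residues)}"
            )
        chain.residues = chain.residues[k:]
    return out


def sequence_of(model: StructureModel) -> str:
    """One-letter sequence, chains concatenated in order."""
    return "".join(r.code1 for r in model.residues())
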