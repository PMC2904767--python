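"""Representative-reference-set assembly: the mechanical quality filters
applied to candidate structures (X-ray, resolution ≤ 2.5 Å, R-factor ≤ 0.3,
length ≥ 40, no chain breaks, no nonstandard residues, all side chains
resolved, and none of the mutant/complex/fragment/membrane exclusions), plus
construction of the background distribution of size-normalized hydration
free energies that a query protein is compared against.

"All side chains resolved" and the exclusion flags are caller-supplied
metadata, not inferred from coordinates — coordinates alone cannot decide
them. Chain-break detection, which coordinates can decide, lives here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble_analysis import ReferenceDistribution
from .errors import GeometryError, MetadataError
from .hydration_energy import GbsaSettings, ParameterSet, hydration_free_energy
from .solvent_accessibility import SasaSettings
from .structure_model import StructureModel

__all__ = [
    "StructureMetadata",
    "FilterThresholds",
    "passes_filters",
    "detect_chain_breaks",
    "build_reference_distribution",
    "filter_report",
]

#: Conventional upper bound on a trans-peptide Cα–Cα distance (Å); larger
#: separations between consecutive residues indicate a chain break.
CA_BREAK_DISTANCE = 4.5


@dataclass(frozen=True)
class FilterThresholds:
    max_resolution: float = 2.5  # Å
    max_r_factor: float = 0.3  # dimensionless
    min_length: int = 40  # residues


@dataclass(frozen=True)
class StructureMetadata:
    id: str
    method: str  # e.g. "X-ray", "NMR"
    resolution: float | None  # Å; None when not applicable
    r_factor: float | None
    length: int
    has_chain_breaks: bool = False
    has_nonstandard: bool = False
    is_mutant: bool = False
    is_complexed: bool = False
    is_fragment: bool = False
    is_membrane: bool = False
    all_side_chains_resolved: bool = True


_MANDATORY = ("id", "method", "length")


def passes_filters(
    meta: StructureMetadata, thresholds: FilterThresholds = FilterThresholds()
) -> tuple[bool, list[str]]:
    """Accept/reject one candidate; rejection reasons are enumerated.

    The filter is a pure conjunction: every clause must hold."""
    for field_name in _MANDATORY:
        if getattr(meta, field_name) in (None, ""):
            raise MetadataError(f"{meta.id or '<unnamed>'}: missing field {field_name!r}")
    reasons: list[str] = []
    if meta.method.strip().lower().replace("-", "") != "xray":
        reasons.append("method")
    else:
        if meta.resolution is None or meta.r_factor is None:
            raise MetadataError(f"{meta.id}: X-ray entry missing resolution/r_factor")
        if meta.resolution > thresholds.max_resolution:
            reasons.append("resolution")
        if meta.r_factor > thresholds.max_r_factor:
            reasons.append("r_factor")
    if meta.length < thresholds.min_length:
        reasons.append("length")
    if meta.has_chain_breaks:
        reasons.append("chain_breaks")
    if meta.has_nonstandard:
        reasons.append("nonstandard_residues")
    if not meta.all_side_chains_resolved:
        reasons.append("side_chains")
    for flag in ("is_mutant", "is_complexed", "is_fragment", "is_membrane"):
        if getattr(meta, flag):
            reasons.append(flag.removeprefix("is_"))
    return (not reasons), reasons


def detect_chain_breaks(
    model: StructureModel, max_ca_distance: float = CA_BREAK_DISTANCE
) -> list[tuple[str, int]]:
    """Positions (chain, seq_index of the residue before the gap) where
    consecutive Cα atoms are farther apart than ``max_ca_distance`` or the
    residue numbering jumps."""
    breaks: list[tuple[str, int]] = []
    for chain in model.chains:
        cas = []
        for res in chain.residues:
            ca = res.atom("CA")
            if ca is None:
                raise GeometryError(
                    f"residue {res.code3} {res.seq_index} of chain "
                    f"{chain.chain_id!r} has no CA atom"
                )
            cas.append((res.seq_index, ca.coords))
        for (i_a, xyz_a), (i_b, xyz_b) in zip(cas, cas[1:]):
            gap = i_b - i_a > 1
            far = float(np.linalg.norm(xyz_b - xyz_a)) > max_ca_distance
            if gap or far:
                breaks.append((chain.chain_id, i_a))
    return breaks


def build_reference_distribution(
    models: list[StructureModel],
    params: ParameterSet | None = None,
    settings: GbsaSettings = GbsaSettings(),
    sasa_settings: SasaSettings = SasaSettings(),
) -> ReferenceDistribution:
    """Size-normalized HFE of each reference structure, assembled for
    percentile and summary queries."""
    if not models:
        raise ValueError("reference distribution needs at least one structure")
    values, labels = [], []
    for model in models:
        result = hydration_free_energy(
            model, params, settings=settings, sasa_settings=sasa_settings
        )
        values.append(result.normalized)
        labels.append(model.label)
    return ReferenceDistribution(values=np.asarray(values), labels=labels)


def filter_report(
    metas: list[StructureMetadata],
    thresholds: FilterThresholds = FilterThresholds(),
) -> pd.DataFrame:
    """One row per candidate: accepted flag and semicolon-joined reasons."""
    rows = []
    for meta in metas:
        ok, reasons = passes_filters(meta, thresholds)
        rows.append({"id": meta.id, "accepted": ok, "reasons": ";".join(reasons)})
    return pd.DataFrame(rows)


def read_metadata_csv(path: str | Path) -> list[StructureMetadata]:
    """Load candidate metadata from CSV with the StructureMetadata fields."""
    frame = pd.read_csv(path)
    metas = []
    for _, row in frame.iterrows():
        kwargs = {}
        for f in StructureMetadata.__dataclass_fields__:
            if f in frame.columns:
                val = row[f]
                if f in ("resolution", "r_factor") and pd.isna(val):
                    val = None
                kwargs[f] = val
        metas.append(StructureMetadata(**kwargs))
    return metas
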