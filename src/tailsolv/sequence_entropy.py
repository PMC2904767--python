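"""Surface-composite sequences and their Shannon entropy.

A composite sequence collects, for one segment (or the whole structure), the
residues whose relative solvent accessibility reaches a cutoff; its Shannon
entropy H = −Σ p_i ln p_i over the 20 amino-acid frequencies measures the
compositional diversity of that surface. Sweeping the cutoff from 0 (all
residues) toward 0.4 (the conventional surface definition) tracks how the
complexity of the exposed subset changes — low-complexity disordered tails
sit well below a typical core at cutoff 0 and converge toward it as only
exposed residues are retained.

Entropies are reported in natural-log units (max ln 20 ≈ 2.996).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedEntropyError
from .solvent_accessibility import (
    AccessibilityTable,
    SasaSettings,
    relative_accessibility,
    residue_sasa,
)
from .structure_model import Ensemble, SegmentDefinition, StructureModel

__all__ = [
    "CompositeSequence",
    "EntropyResult",
    "composite_sequence",
    "shannon_entropy",
    "entropy_sweep",
    "ensemble_entropy_stats",
]

logger = logging.getLogger(__name__)

MAX_ENTROPY = float(np.log(20.0))


@dataclass(frozen=True)
class CompositeSequence:
    """Unordered collection of one-letter codes from residues at or above an
    accessibility cutoff."""

    letters: str
    source: str
    cutoff: float

    def __len__(self) -> int:
        return len(self.letters)


@dataclass(frozen=True)
class EntropyResult:
    value: float  # natural-log units, in [0, ln 20]
    n_residues: int
    cutoff: float
    source: str = ""


def composite_sequence(
    model: StructureModel,
    seg: SegmentDefinition | None,
    table: AccessibilityTable,
    cutoff: float,
) -> CompositeSequence:
    """Letters of the segment's residues with relative SA ≥ cutoff.

    ``seg=None`` means the whole structure. Cutoff 0.0 yields the full
    segment sequence (every residue has non-negative relative SA). An empty
    result is allowed."""
    frame = table.frame
    if frame["rel_sa"].isna().any():
        raise ValueError("relative column not filled; call relative_accessibility first")
    mask = frame["rel_sa"] >= cutoff
    if seg is not None:
        mask &= (frame["chain"] == seg.chain_id) & frame["seq_index"].between(
            seg.first, seg.last
        )
    letters = "".join(frame.loc[mask, "code1"])
    return CompositeSequence(
        letters=letters,
        source=seg.name if seg is not None else (model.label or "all"),
        cutoff=cutoff,
    )


def shannon_entropy(seq: CompositeSequence | str) -> EntropyResult:
    """H = −Σ p_i ln p_i over the amino acids present; order-independent."""
    if isinstance(seq, str):
        seq = CompositeSequence(letters=seq, source="", cutoff=0.0)
    n = len(seq.letters)
    if n == 0:
        raise UndefinedEntropyError(
            f"entropy undefined for empty composite {seq.source!r} "
            f"(cutoff {seq.cutoff})"
        )
    counts = np.array(list(Counter(seq.letters).values()), dtype=float)
    p = counts / n
    value = float(-(p * np.log(p)).sum())
    return EntropyResult(value=value, n_residues=n, cutoff=seq.cutoff, source=seq.source)


DEFAULT_CUTOFFS = tuple(np.round(np.arange(0.0, 0.501, 0.05), 2))


def entropy_sweep(
    model: StructureModel,
    segs: list[SegmentDefinition | None],
    table: AccessibilityTable,
    cutoffs: list[float] = DEFAULT_CUTOFFS,
) -> pd.DataFrame:
    """One row per (segment, cutoff): entropy and residue count.

    Composites that become empty at high cutoffs are flagged (``empty`` =
    True, entropy NaN), never silently dropped."""
    if any(b < a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be sorted ascending")
    rows = []
    for seg in segs:
        name = seg.name if seg is not None else "all"
        for cutoff in cutoffs:
            comp = composite_sequence(model, seg, table, cutoff)
            if len(comp) == 0:
                logger.warning(
                    "segment %r: empty composite at cutoff %.2f", name, cutoff
                )
                rows.append(
                    {"segment": name, "cutoff": cutoff, "n_residues": 0,
                     "entropy": np.nan, "empty": True}
                )
            else:
                res = shannon_entropy(comp)
                rows.append(
                    {"segment": name, "cutoff": cutoff, "n_residues": res.n_residues,
                     "entropy": res.value, "empty": False}
                )
    return pd.DataFrame(rows)


def ensemble_entropy_stats(
    ensemble: Ensemble,
    segs: list[SegmentDefinition | None],
    cutoffs: list[float] = DEFAULT_CUTOFFS,
    settings: SasaSettings = SasaSettings(),
) -> pd.DataFrame:
    """Mean ± sd of entropy per (segment, cutoff) across an ensemble.

    Per-model entropies are computed first and then averaged (not pooled
    letters), so the sd reflects conformational spread of the surface, not
    sequence length. Models whose composite is empty at a cutoff are
    excluded from that cell's statistics with a warning."""
    frames = []
    for model in ensemble:
        table = relative_accessibility(residue_sasa(model, settings), settings=settings)
        sweep = entropy_sweep(model, segs, table, cutoffs)
        sweep["model"] = model.label
        frames.append(sweep)
    long = pd.concat(frames, ignore_index=True)
    n_empty = int(long["empty"].sum())
    if n_empty:
        logger.warning("%d empty composites excluded from ensemble means", n_empty)

    def _agg(group: pd.DataFrame) -> pd.Series:
        vals = group.loc[~group["empty"], "entropy"]
        return pd.Series(
            {
                "mean_entropy": vals.mean() if len(vals) else np.nan,
                "sd_entropy": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                "mean_n_residues": group.loc[~group["empty"], "n_residues"].mean(),
                "n_models": int(len(vals)),
            }
        )

    out = (
        long.groupby(["segment", "cutoff"], sort=False)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    return out
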