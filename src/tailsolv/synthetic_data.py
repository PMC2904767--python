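"""Seeded synthetic structures with the statistical shape the analysis
assumes: compact globular cores of typical composition (hydrophobic-in,
polar-out), low-complexity hydrophilic terminal tails, and ensembles of
perturbed conformers — plus small analytic fixtures with closed-form
properties.

Geometry is deliberately coarse. Residues occupy 2×2×2 blocks of a cubic
"fine" lattice (2.2 Å pitch) traversed by a three-dimensional boustrophedon;
the Cα sits at each block origin, giving a constant 4.4 Å Cα–Cα step —
below the 4.5 Å chain-break bound — while every atom occupies its own fine
site, so all interatomic distances are ≥ 2.2 Å by construction. The point is
correct composition, compactness class, and clash-freedom, not physical
conformations: radii of gyration track the globular scaling Rg ≈ 2.2·N^0.38
Å, tails are far more variable across conformers than cores, and charged
hydrophilic tails dominate the hydration-energy budget, which is the regime
the analysis probes.
"""

from __future__ import annotations

import copy as _copy
import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._chem import (
    FINE_SPACING,
    GLOBULAR_COMPOSITION,
    HEAVY_ATOMS,
    HYDROPHILIC_TAIL_COMPOSITION,
    KYTE_DOOLITTLE,
    OFFSET_SHELLS,
    ONE_TO_THREE,
    element_of,
)
from .errors import GenerationError
from .reference_set import StructureMetadata
from .structure_model import (
    Atom,
    Chain,
    Ensemble,
    Residue,
    SegmentDefinition,
    StructureModel,
)

__all__ = [
    "GeneratorConfig",
    "generate_globule",
    "attach_tails",
    "generate_construct",
    "construct_segments",
    "generate_ensemble",
    "generate_metadata",
    "analytic_fixtures",
    "two_sphere_model",
    "helix_model",
]

Site = tuple[int, int, int]

MAX_TAIL_RESTARTS = 100
MIN_CORE_LENGTH = 12
_BURIAL_ORDER_NOISE = 2.0  # Kyte-Doolittle units; softens the in/out sorting


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic construct and its ensemble.

    Defaults mirror the desk-scale version of the case study: a 150-residue
    core carrying an 80-residue N-tail and a 40-residue C-tail of
    low-complexity hydrophilic composition, sampled as 20 independent
    conformers."""

    seed: int = 0
    core_length: int = 150
    tail_lengths: tuple[int, int] = (80, 40)
    tail_composition: tuple[tuple[str, float], ...] = tuple(
        sorted(HYDROPHILIC_TAIL_COMPOSITION.items())
    )
    core_composition: tuple[tuple[str, float], ...] = tuple(
        sorted(GLOBULAR_COMPOSITION.items())
    )
    tail_conformation: str = "extended"  # or "collapsed"
    ensemble_size: int = 20
    noise_scale: float = 0.5  # Å, Gaussian jitter of core atoms per conformer

    def __post_init__(self) -> None:
        for name in ("tail_composition", "core_composition"):
            value = getattr(self, name)
            if isinstance(value, dict):  # accept plain dicts for convenience
                object.__setattr__(self, name, tuple(sorted(value.items())))
            comp = dict(getattr(self, name))
            if abs(sum(comp.values()) - 1.0) > 1e-6:
                raise ValueError(f"{name} probabilities must sum to 1")
            if not set(comp) <= set(ONE_TO_THREE):
                raise ValueError(f"{name} has non-standard letters")
        if min(self.tail_lengths) < 0 or self.core_length < 0:
            raise ValueError("lengths must be non-negative")
        if self.tail_conformation not in ("extended", "collapsed"):
            raise ValueError("tail_conformation must be 'extended' or 'collapsed'")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")


# --------------------------------------------------------------------------
# lattice helpers
# --------------------------------------------------------------------------


def _snake_blocks(n_blocks: int) -> list[Site]:
    """First ``n_blocks`` of a 3-D boustrophedon over an n×n×n block cube;
    consecutive blocks are always face-adjacent."""
    n_side = max(1, math.ceil(n_blocks ** (1.0 / 3.0)))
    while n_side**3 < n_blocks:
        n_side += 1
    blocks: list[Site] = []
    for k in range(n_side):
        js = range(n_side) if k % 2 == 0 else range(n_side - 1, -1, -1)
        for j in js:
            is_ = range(n_side) if (j + k) % 2 == 0 else range(n_side - 1, -1, -1)
            for i in is_:
                blocks.append((i, j, k))
                if len(blocks) == n_blocks:
                    return blocks
    return blocks


def _ca_site(block: Site) -> Site:
    return (2 * block[0], 2 * block[1], 2 * block[2])


def _hull_direction(block: Site, block_set: set[Site]) -> Site | None:
    """Outward lattice direction for a hull block (None for interior)."""
    free = [
        s
        for s in _NEIGHBOR_STEPS
        if (block[0] + s[0], block[1] + s[1], block[2] + s[2]) not in block_set
    ]
    if not free:
        return None
    summed = tuple(int(np.sign(sum(s[i] for s in free))) for i in range(3))
    return summed if any(summed) else free[0]


def _site_coords(site: Site) -> np.ndarray:
    return np.asarray(site, dtype=float) * FINE_SPACING


def _place_residue_atoms(
    code3: str,
    ca_site: Site,
    occupied: set[Site],
    ray: Site | None = None,
) -> dict[str, Site]:
    """Claim fine-lattice sites for one residue's heavy atoms.

    Backbone atoms take the nearest free sites around the CA (deterministic
    tie-break). Side-chain atoms of surface residues (``ray`` set) are laid
    out along the outward lattice direction as a protruding stalk — side
    chains of surface residues point into the solvent, as in real globules,
    which is what gives surface residues their realistic relative
    accessibility. Interior residues (``ray=None``) pack side chains into
    the nearest free sites."""
    sites: dict[str, Site] = {"CA": ca_site}

    def nearest_free(name: str) -> Site:
        for off in OFFSET_SHELLS:
            cand = (ca_site[0] + off[0], ca_site[1] + off[1], ca_site[2] + off[2])
            if cand not in occupied:
                occupied.add(cand)
                return cand
        raise GenerationError(
            f"no free lattice site near CA {ca_site} for {code3} {name}; "
            "try a different seed or smaller structure"
        )

    backbone = {"N", "C", "O"}
    stalk: list[Site] = []
    if ray is not None:
        # 3-wide column along the outward direction keeps stalk lengths
        # close to real side-chain extents
        q = _perpendicular_axis(ray)
        for k in range(1, 8):
            for m in ((0, 0, 0), q, (-q[0], -q[1], -q[2])):
                stalk.append(
                    (
                        ca_site[0] + k * ray[0] + m[0],
                        ca_site[1] + k * ray[1] + m[1],
                        ca_site[2] + k * ray[2] + m[2],
                    )
                )
    stalk_iter = iter(stalk)
    for name in HEAVY_ATOMS[code3]:
        if name == "CA":
            continue
        if ray is not None and name not in backbone:
            placed = None
            for cand in stalk_iter:
                if cand not in occupied:
                    occupied.add(cand)
                    placed = cand
                    break
            sites[name] = placed if placed is not None else nearest_free(name)
        else:
            sites[name] = nearest_free(name)
    return sites


def _perpendicular_axis(ray: Site) -> Site:
    """Axis direction most perpendicular to the ray (deterministic)."""
    best = min(
        _NEIGHBOR_STEPS,
        key=lambda d: (abs(d[0] * ray[0] + d[1] * ray[1] + d[2] * ray[2]), d),
    )
    return best


def _build_residue(
    code3: str, seq_index: int, sites: dict[str, Site], serial_start: int
) -> tuple[Residue, int]:
    atoms = []
    serial = serial_start
    for name in HEAVY_ATOMS[code3]:
        serial += 1
        atoms.append(
            Atom(
                name=name,
                element=element_of(name),
                coords=_site_coords(sites[name]),
                serial=serial,
            )
        )
    return Residue(code3=code3, seq_index=seq_index, atoms=atoms), serial


def _draw_letters(rng: np.random.Generator, n: int, composition) -> list[str]:
    comp = dict(composition)
    letters = sorted(comp)
    probs = np.array([comp[c] for c in letters])
    probs = probs / probs.sum()
    return list(rng.choice(letters, size=n, p=probs))


def _occupied_sites(model: StructureModel) -> set[Site]:
    """Recover fine-lattice occupancy from a generated (on-lattice) model."""
    occ: set[Site] = set()
    for atom in model.heavy_atoms():
        site = tuple(int(round(c / FINE_SPACING)) for c in atom.coords)
        occ.add(site)  # type: ignore[arg-type]
    return occ


# --------------------------------------------------------------------------
# core globule
# --------------------------------------------------------------------------


def generate_globule(config: GeneratorConfig) -> StructureModel:
    """Compact self-avoiding core of ``core_length`` residues.

    Letters are drawn from ``core_composition`` and assigned burial-ordered
    — the most hydrophobic draws innermost, the most polar at the surface —
    reproducing the hydrophobic-core/polar-surface organisation of real
    globules that the accessibility-stratified entropy analysis relies on.
    Deterministic for a fixed seed."""
    n = config.core_length
    if n < MIN_CORE_LENGTH:
        raise GenerationError(
            f"core_length {n} too small (minimum {MIN_CORE_LENGTH})"
        )
    rng = np.random.default_rng(config.seed)
    blocks = _snake_blocks(n)
    letters = _draw_letters(rng, n, config.core_composition)

    # burial-ordered assignment: rank residue positions by distance from the
    # centroid, rank letters by noisy hydrophobicity (hydrophobic-in,
    # polar-out, but imperfectly — burial correlates only moderately with
    # hydrophobicity in real globules)
    centers = np.array([_ca_site(b) for b in blocks], dtype=float)
    dist = np.linalg.norm(centers - centers.mean(axis=0), axis=1)
    burial_rank = np.argsort(dist, kind="stable")
    noisy_kd = {
        i: KYTE_DOOLITTLE[c] + rng.normal(0.0, _BURIAL_ORDER_NOISE)
        for i, c in enumerate(letters)
    }
    letters_sorted = [letters[i] for i in sorted(range(n), key=lambda i: -noisy_kd[i])]
    assigned = [""] * n
    for rank, pos in enumerate(burial_rank):
        assigned[pos] = letters_sorted[rank]

    occupied: set[Site] = {_ca_site(b) for b in blocks}
    block_set = set(blocks)
    residues: list[Residue] = []
    serial = 0
    for i, (block, letter) in enumerate(zip(blocks, assigned), start=1):
        code3 = ONE_TO_THREE[letter]
        ray = _hull_direction(block, block_set)
        sites = _place_residue_atoms(code3, _ca_site(block), occupied, ray)
        res, serial = _build_residue(code3, i, sites, serial)
        residues.append(res)
    return StructureModel(
        chains=[Chain("A", residues)], label=f"globule_n{n}_seed{config.seed}"
    )


# --------------------------------------------------------------------------
# tails
# --------------------------------------------------------------------------

_NEIGHBOR_STEPS: tuple[Site, ...] = (
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
)


def _tail_walk(
    rng: np.random.Generator,
    start_block: Site,
    direction: Site,
    length: int,
    occupied_blocks: set[Site],
    conformation: str,
) -> list[Site]:
    """Block path of a tail leaving the core at ``start_block``.

    Extended: a straight ray along ``direction`` (other axis directions are
    tried if that ray is blocked). Collapsed: a self-avoiding random walk
    with bounded restarts."""
    if conformation == "extended":
        for d in (direction,) + tuple(s for s in _NEIGHBOR_STEPS if s != direction):
            path = [
                (
                    start_block[0] + t * d[0],
                    start_block[1] + t * d[1],
                    start_block[2] + t * d[2],
                )
                for t in range(1, length + 1)
            ]
            if not any(b in occupied_blocks for b in path):
                return path
        raise GenerationError("extended tail collides with occupied blocks")
    for _ in range(MAX_TAIL_RESTARTS):
        path = []
        taken = set(occupied_blocks)
        current = start_block
        ok = True
        for _step in range(length):
            options = [
                (current[0] + s[0], current[1] + s[1], current[2] + s[2])
                for s in _NEIGHBOR_STEPS
            ]
            options = [b for b in options if b not in taken]
            if not options:
                ok = False
                break
            current = options[rng.integers(len(options))]
            taken.add(current)
            path.append(current)
        if ok:
            return path
    raise GenerationError(
        f"collapsed tail walk self-trapped {MAX_TAIL_RESTARTS} times; reseed"
    )


def attach_tails(core: StructureModel, config: GeneratorConfig) -> StructureModel:
    """Append the N- and C-terminal tails to a generated core.

    Tail sequences are drawn from ``tail_composition``; geometry follows
    ``tail_conformation``. The whole chain is renumbered 1..total. With
    tail_lengths (0, 0) the core is returned unchanged (a fresh copy)."""
    n_len, c_len = config.tail_lengths
    if n_len == 0 and c_len == 0:
        return core.copy()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    return _attach_tails_seeded(core, config, rng)


def _attach_tails_seeded(
    core: StructureModel,
    config: GeneratorConfig,
    rng: np.random.Generator,
    tail_sequences: tuple[list[str], list[str]] | None = None,
) -> StructureModel:
    n_len, c_len = config.tail_lengths
    chain = core.chains[0]
    occupied = _occupied_sites(core)
    # A block is closed to the tail path when its origin (the CA anchor
    # site) is taken — every core block qualifies. Side-chain spill into a
    # block does not close it; the site-level search resolves those atoms.
    occupied_blocks = {
        (s[0] // 2, s[1] // 2, s[2] // 2)
        for s in occupied
        if s[0] % 2 == 0 and s[1] % 2 == 0 and s[2] % 2 == 0
    }
    first_block = tuple(
        int(round(c / FINE_SPACING)) // 2 for c in chain.residues[0].atom("CA").coords
    )
    last_block = tuple(
        int(round(c / FINE_SPACING)) // 2 for c in chain.residues[-1].atom("CA").coords
    )

    if tail_sequences is None:
        n_letters = _draw_letters(rng, n_len, config.tail_composition)
        c_letters = _draw_letters(rng, c_len, config.tail_composition)
    else:
        n_letters, c_letters = tail_sequences

    conf = config.tail_conformation
    n_path = (
        _tail_walk(rng, first_block, (-1, 0, 0), n_len, occupied_blocks, conf)
        if n_len
        else []
    )
    occupied_blocks.update(n_path)
    c_path = (
        _tail_walk(rng, last_block, (0, 0, 1), c_len, occupied_blocks, conf)
        if c_len
        else []
    )

    # claim CA sites of both tails before filling side atoms
    n_ca = [_ca_site(b) for b in n_path]
    c_ca = [_ca_site(b) for b in c_path]
    occupied.update(n_ca)
    occupied.update(c_ca)

    serial = 0
    residues: list[Residue] = []
    # N-tail: the walk leaves the core, the chain enters it — reverse
    for i, (letter, ca) in enumerate(zip(n_letters, reversed(n_ca)), start=1):
        code3 = ONE_TO_THREE[letter]
        sites = _place_residue_atoms(code3, ca, occupied)
        res, serial = _build_residue(code3, i, sites, serial)
        residues.append(res)
    for i, core_res in enumerate(chain.residues, start=n_len + 1):
        res = _copy.deepcopy(core_res)
        res.seq_index = i
        for atom in res.atoms:
            serial += 1
            atom.serial = serial
        residues.append(res)
    for i, (letter, ca) in enumerate(
        zip(c_letters, c_ca), start=n_len + len(chain.residues) + 1
    ):
        code3 = ONE_TO_THREE[letter]
        sites = _place_residue_atoms(code3, ca, occupied)
        res, serial = _build_residue(code3, i, sites, serial)
        residues.append(res)

    return StructureModel(
        chains=[Chain(chain.chain_id, residues)],
        label=f"{core.label}+tails{n_len}_{c_len}",
    )


def generate_construct(config: GeneratorConfig) -> StructureModel:
    """Core plus tails in one call (the full synthetic protein)."""
    return attach_tails(generate_globule(config), config)


def construct_segments(config: GeneratorConfig) -> dict[str, SegmentDefinition]:
    """Segment vocabulary for a generated construct: n_tail, core, c_tail."""
    n_len, c_len = config.tail_lengths
    n_total = n_len + config.core_length + c_len
    segs = {}
    if n_len:
        segs["n_tail"] = SegmentDefinition("n_tail", "A", 1, n_len)
    segs["core"] = SegmentDefinition("core", "A", n_len + 1, n_len + config.core_length)
    if c_len:
        segs["c_tail"] = SegmentDefinition(
            "c_tail", "A", n_len + config.core_length + 1, n_total
        )
    return segs


# --------------------------------------------------------------------------
# ensembles
# --------------------------------------------------------------------------


def generate_ensemble(model: StructureModel, config: GeneratorConfig) -> Ensemble:
    """Perturbed conformers of a generated construct.

    Tails are re-sampled as collapsed self-avoiding walks (high structural
    diversity, mirroring the variability of disordered regions) while core
    atoms receive Gaussian jitter of width ``noise_scale`` (low diversity).
    ``noise_scale = 0`` switches perturbation off entirely and yields
    identical copies. Deterministic for a fixed seed."""
    size = config.ensemble_size
    if config.noise_scale == 0.0:
        models = []
        for m in range(size):
            conf = model.copy()
            conf.label = f"conf_{m:03d}"
            models.append(conf)
        return Ensemble(models=models)

    n_len, c_len = config.tail_lengths
    chain = model.chains[0]
    core_residues = chain.residues[n_len : len(chain.residues) - c_len]
    core = StructureModel(
        chains=[Chain(chain.chain_id, _copy.deepcopy(core_residues))],
        label=model.label,
    )
    n_letters = [r.code1 for r in chain.residues[:n_len]]
    c_letters = [r.code1 for r in chain.residues[len(chain.residues) - c_len :]]
    collapsed_cfg = replace(config, tail_conformation="collapsed")

    seeds = np.random.SeedSequence([config.seed, 11]).spawn(size)
    models = []
    for m in range(size):
        rng = np.random.default_rng(seeds[m])
        if n_len or c_len:
            conf = _attach_tails_seeded(
                core, collapsed_cfg, rng, tail_sequences=(n_letters, c_letters)
            )
        else:
            conf = core.copy()
        _jitter_core(conf, n_len, c_len, config.noise_scale, rng)
        conf.label = f"conf_{m:03d}"
        models.append(conf)
    return Ensemble(models=models)


_JITTER_RHO = 0.9  # along-chain correlation of the displacement field
_MAX_TRANSVERSE_STEP = 0.8  # Å; caps per-bond stretch at sqrt(4.4²+0.8²) < 4.5


def _jitter_core(
    conf: StructureModel, n_len: int, c_len: int, scale: float, rng: np.random.Generator
) -> None:
    """Perturb core residues with a chain-correlated displacement field.

    Each residue moves rigidly by an AR(1) displacement whose increments are
    projected perpendicular to the local chain direction, so consecutive
    CA–CA distances grow only quadratically and the chain stays continuous;
    a bridge correction pins both tail junctions in place."""
    residues = conf.chains[0].residues
    core = residues[n_len : len(residues) - c_len]
    n = len(core)
    if n < 2 or scale == 0.0:
        return
    cas = np.array([r.atom("CA").coords for r in core])
    delta = np.zeros((n, 3))
    sigma_inc = scale * math.sqrt(1.0 - _JITTER_RHO**2)
    for i in range(1, n):
        inc = (_JITTER_RHO - 1.0) * delta[i - 1] + rng.normal(0.0, sigma_inc, 3)
        bond = cas[i] - cas[i - 1]
        u = bond / np.linalg.norm(bond)
        perp = inc - (inc @ u) * u
        norm = float(np.linalg.norm(perp))
        if norm > _MAX_TRANSVERSE_STEP:  # keep every stretched bond < 4.5 Å
            perp *= _MAX_TRANSVERSE_STEP / norm
        delta[i] = delta[i - 1] + perp
    # Brownian-bridge pinning: both junction residues stay put, and the
    # per-bond longitudinal leakage is only |delta_end|/(n-1).
    delta -= np.outer(np.arange(n) / (n - 1), delta[-1])
    for i, res in enumerate(core):
        for atom in res.atoms:
            atom.coords = atom.coords + delta[i]


# --------------------------------------------------------------------------
# metadata fixtures for the reference-set filters
# --------------------------------------------------------------------------


def generate_metadata(
    config: GeneratorConfig, n_accept: int = 5
) -> list[tuple[StructureMetadata, list[str]]]:
    """Metadata records with designed ground truth.

    Returns (record, expected rejection reasons) pairs — an empty reason
    list marks a designed accept. Every filter clause is violated by at
    least one record."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    records: list[tuple[StructureMetadata, list[str]]] = []

    def clean(ident: str, **overrides) -> StructureMetadata:
        base = dict(
            id=ident,
            method="X-ray",
            resolution=float(np.round(rng.uniform(1.0, 2.5), 2)),
            r_factor=float(np.round(rng.uniform(0.15, 0.30), 3)),
            length=int(rng.integers(40, 800)),
        )
        base.update(overrides)
        return StructureMetadata(**base)

    for i in range(n_accept):
        records.append((clean(f"ok_{i:03d}"), []))
    records.append((clean("bad_method", method="NMR", resolution=None, r_factor=None),
                    ["method"]))
    records.append((clean("bad_resolution", resolution=2.6), ["resolution"]))
    records.append((clean("bad_rfactor", r_factor=0.35), ["r_factor"]))
    records.append((clean("bad_length", length=39), ["length"]))
    records.append((clean("bad_breaks", has_chain_breaks=True), ["chain_breaks"]))
    records.append((clean("bad_nonstandard", has_nonstandard=True),
                    ["nonstandard_residues"]))
    records.append((clean("bad_sidechains", all_side_chains_resolved=False),
                    ["side_chains"]))
    records.append((clean("bad_mutant", is_mutant=True), ["mutant"]))
    records.append((clean("bad_complex", is_complexed=True), ["complexed"]))
    records.append((clean("bad_fragment", is_fragment=True), ["fragment"]))
    records.append((clean("bad_membrane", is_membrane=True), ["membrane"]))
    records.append(
        (clean("bad_two_ways", resolution=3.1, length=20), ["resolution", "length"])
    )
    return records


# --------------------------------------------------------------------------
# analytic fixtures
# --------------------------------------------------------------------------


def _single_atom_model(
    name: str = "CA", coords=(0.0, 0.0, 0.0), label: str = "single"
) -> StructureModel:
    atom = Atom(name=name, element=element_of(name), coords=np.asarray(coords), serial=1)
    res = Residue(code3="GLY", seq_index=1, atoms=[atom])
    return StructureModel(chains=[Chain("A", [res])], label=label)


def two_sphere_model(separation: float) -> StructureModel:
    """Two carbon atoms a given distance apart (SASA cap-formula fixture)."""
    a = Atom(name="CA", element="C", coords=np.zeros(3), serial=1)
    b = Atom(name="CA", element="C", coords=np.array([separation, 0.0, 0.0]), serial=2)
    return StructureModel(
        chains=[
            Chain("A", [Residue("GLY", 1, [a]), Residue("GLY", 2, [b])])
        ],
        label=f"two_sphere_d{separation:g}",
    )


def helix_model(n_residues: int = 20, gap_after: int | None = None) -> StructureModel:
    """Cα trace of an ideal α-helix (rise 1.5 Å, 100°/residue, radius 2.3 Å
    — consecutive Cα ≈ 3.8 Å apart). ``gap_after`` deletes the following
    residue, leaving a numbering gap and a >4.5 Å jump."""
    residues = []
    serial = 0
    for i in range(1, n_residues + 1):
        if gap_after is not None and i == gap_after + 1:
            continue
        theta = math.radians(100.0) * (i - 1)
        coords = np.array([2.3 * math.cos(theta), 2.3 * math.sin(theta), 1.5 * (i - 1)])
        serial += 1
        residues.append(
            Residue("GLY", i, [Atom("CA", "C", coords, serial)])
        )
    label = "helix" if gap_after is None else f"helix_gap{gap_after}"
    return StructureModel(chains=[Chain("A", residues)], label=label)


def analytic_fixtures() -> dict[str, StructureModel]:
    """Named fixtures with closed-form properties: a single ion, a touching
    two-sphere pair, a symmetric dumbbell, a continuous helix, and a helix
    with an engineered break."""
    return {
        "single_ion": _single_atom_model(name="N", label="single_ion"),
        "two_sphere": two_sphere_model(2.5),
        "dumbbell": two_sphere_model(2.0),
        "helix": helix_model(20),
        "helix_gap": helix_model(20, gap_after=10),
    }
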