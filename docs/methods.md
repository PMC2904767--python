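# Methods

## The question the package operationalizes

Low-complexity hydrophilic terminal tails ("intrinsically disordered
regions") change a protein's relationship with water. The package measures
this along four axes on any structure or ensemble: (i) the GB/SA hydration
free energy of the intact protein versus truncated and core-only variants,
(ii) how much of the solvent-accessible surface the tails contribute,
(iii) how the sequence complexity of the *exposed* residues compares
between tails and core, and (iv) how structurally variable tails are
relative to the core across conformers. A filtered reference distribution
of normalized hydration energies supplies the "typical protein" baseline a
query is placed against (percentage of reference proteins with a more
positive value; strict inequality, ties count against the query).

## Hydration free energy

ΔG_hyd = ΔG_pol + ΔG_np.

**Polar term (generalized Born, OBC-II).** Each atom carries a partial
charge q (e), an intrinsic radius ρ (Å), and an HCT screening scale S. The
reduced radius is ρ̃ = ρ − δ with offset δ = 0.09 Å. The burial integral of
atom *i* is the closed-form HCT pairwise sum over neighbour spheres of
radius S_j·ρ̃_j (with the engulfed-atom correction), verified in the tests
against direct numerical integration of r⁻⁴ over the neighbour volume. The
OBC correction 1/R = 1/ρ̃ − tanh(αΨ − βΨ² + γΨ³)/ρ with Ψ = I·ρ̃ and
(α, β, γ) = (1.0, 0.8, 4.85) maps the integral to the effective Born
radius; an isolated atom recovers R = ρ̃ exactly. The pair energy uses the
Still interpolation f_GB = √(r² + R_iR_j·exp(−r²/4R_iR_j)) including self
terms (f_GB = R_i), summed over all pairs directly in O(n²) — single-point
evaluations make exact summation affordable, and the direct sum is the
reference any optimization must match (tests hold a pure-loop
re-implementation to 0.1%). Dielectrics default to ε_in = 1, ε_w = 78.5;
the Coulomb constant 332.0636 kcal·Å/(mol·e²) is converted once
(4.184 kJ/kcal). A single ion reproduces the Born equation to machine
precision.

**Nonpolar term.** σ × total SASA with σ = 0.0209 kJ/(mol·Å²)
(= 0.005 kcal/(mol·Å²)), the conventional GB/SA surface tension.

**Transfer between media.** The polar term is proportional to
(1/ε_a − 1/ε_b); `transfer_scaling` rescales a water–vacuum result to any
dielectric pair, the basis for arguing that orderings computed against
vacuum carry over to transfer into low-permittivity desiccated
environments.

**Parameterization: united heavy atoms.** The bundled plain-text table
(`data/gbsa_params.dat`) assigns each heavy atom its own charge plus that
of its bonded hydrogens, with a common backbone block (N −0.15, CA +0.10,
C +0.60, O −0.55) and side-chain blocks that sum to each residue's formal
charge (Asp/Glu −1, Lys/Arg +1, His neutral). Radii are per-element
mbondi-style values (C 1.70, N 1.55, O 1.50, S 1.80 Å) and screening
factors HCT-style (0.72/0.79/0.85/0.96). Charged termini are the default
(+1 on the first backbone N, −1 on the last backbone O or OXT), switchable
to neutral caps. This scheme was chosen so that plain heavy-atom PDB files
need no protonation step; its absolute energies are *not* comparable to
all-atom force-field numbers. All conclusions the package draws — and all
its tests — live on orderings, differences, percentiles and fractions,
which the monopole-level treatment preserves.

## Solvent accessibility

Shrake–Rupley quadrature: golden-spiral points (default 960) on each
atom's probe-expanded sphere (probe 1.4 Å, a water molecule), a point
buried if inside any neighbour's expanded sphere, neighbour search via a
k-d tree. Hydrogens are ignored throughout (consistent with the
united-atom energy model). Convergence of the 960-point default against
4000 points is within 2% on generated globules; an isolated atom is exact
(4π(r+1.4)²). Translation invariance is exact; rotation moves shadow
boundaries by a few quadrature cells (~0.1% of the total) because point
orientations are fixed in the laboratory frame — the standard behaviour of
this algorithm's implementations.

Relative accessibility divides a residue's SASA by that of the free
("completely hydrated") amino acid, computed with the same engine from a
deterministic bundled template pose, cached, and shipped as
`data/max_sa_default.csv` for bit-reproducibility. The ratio is not capped
at 1: a protruding side chain in an unusual context can exceed the
template's exposure, and cutoff logic is unaffected. Surface residues are
those with relative SA ≥ cutoff; cutoff 0.0 therefore selects every
residue, and 0.4 is the conventional surface definition.

## Surface sequence entropy

A composite sequence collects the residues of a segment at or above a
cutoff; H = −Σ p_i ln p_i over the 20 amino-acid frequencies. Natural
logarithms are used (uniform composition gives ln 20 ≈ 2.996, the value
near-uniform protein surfaces converge to); order is irrelevant by
construction. Ensemble statistics are per-model-then-average (mean and
n−1 sd across conformers), not pooled letters, so the spread reflects
conformational variability of the surface. Empty composites at high
cutoffs are flagged and excluded from means with a logged warning, never
silently dropped. The default sweep grid is 0.0–0.5 in steps of 0.05.

## Ensemble statistics

Radius of gyration is mass-weighted over heavy atoms (uniform weighting is
a switch). Superposition is the Kabsch SVD solution constrained to proper
rotations; backbone RMSD uses the four-atom convention (N, CA, C, O).
Pairwise RMSD statistics superpose on the segment itself — tails are
fitted on tails, cores on cores — over all n(n−1)/2 unordered pairs, with
sample (n−1) standard deviations. Degenerate inputs fail loudly: fewer
than three non-collinear atoms, mismatched sequences, single-model
ensembles.

## Reference set

The metadata filter is a pure conjunction — X-ray method, resolution
≤ 2.5 Å, R-factor ≤ 0.3 (treated as dimensionless), length ≥ 40, no chain
breaks, no nonstandard residues, all side chains resolved, and none of the
mutant/complex/fragment/membrane exclusions — with every rejection reason
enumerated. Boundary values pass. "Side chains resolved" and the exclusion
flags are caller-supplied annotations; coordinates cannot decide them.
Chain breaks, which coordinates can decide, use consecutive Cα–Cα
> 4.5 Å (the conventional trans-peptide bound) or a residue-numbering gap.
Candidate structures are scored as provided, without prior energy
minimization. The reference distribution holds per-protein normalized
hydration energies and supports mean ± sd, histogram, and strict
more-positive percentile queries.

## Synthetic structures

The generator produces the statistical situation the analysis assumes,
not physical conformations. Residues occupy 2×2×2 blocks of a 2.2 Å fine
lattice traversed by a three-dimensional boustrophedon; the Cα anchors
each block's origin, so consecutive Cα are exactly 4.4 Å apart (the chain
never trips the 4.5 Å break detector) and every atom sits on its own fine
site (all interatomic distances ≥ 2.2 Å, above the 2.0 Å clash bound).
Core sequences are drawn from background globular composition and
assigned burial-ordered — hydrophobic draws inward, polar outward, with
Gaussian noise (sd 2.0 Kyte–Doolittle units) on the ordering because the
real correlation between burial and hydrophobicity is only moderate.
Surface residues extend their side chains along outward lattice rays in
3-wide columns, giving them realistic relative accessibilities (median
~0.28, ~40% above the 0.4 cutoff in a 150-residue core) and the package's
radii of gyration track the globular scaling Rg ≈ 2.2·N^0.38 Å within
±30% from N = 12 to 500.

Tails default to 80 (N) and 40 (C) residues of hydrophilic low-complexity
composition (G 0.20, P 0.10, R 0.175, K 0.175, S 0.10, E 0.10, Q/D/N
0.05) — glycine/proline plus charged and polar residues, the canonical
disorder signature; the requested composition's entropy (≈ 2.07) sits well
below background (≈ 2.93). Geometry is an extended ray or a collapsed
self-avoiding walk on the block lattice.

Ensembles re-sample the tails as fresh collapsed walks per conformer
(high diversity, as disordered regions show) and perturb the core with a
chain-correlated displacement field: per-residue AR(1) displacements
whose increments are projected perpendicular to the local chain direction
and Brownian-bridge-pinned at both tail junctions, so bonds stretch only
quadratically and conformers remain break-free; the default scale is
0.5 Å. A noise scale of 0 disables perturbation entirely and yields
identical copies. All randomness flows from one integer seed through
numpy `SeedSequence`s; regeneration is bit-identical.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: real covalent geometry (bonds are 2.2–4.4 Å,
not 1.2–1.5 Å), secondary structure, Ramachandran statistics, side-chain
rotamers, or thermodynamically weighted conformers. It preserves the
properties the analysis actually consumes: composition, compactness
class, burial-composition coupling, clash-freedom, chain continuity, and
the tail/core contrast in exposure and variability. Absolute energies and
surfaces are therefore internally consistent but not comparable to
experimental structures; orderings and fractions are.

## Default study conditions

The acceptance script and the direction-of-effect tests run 20 seeded
replicates of a 150-residue core with 80/40-residue tails (270 residues,
~2100 heavy atoms), a 30-globule reference set spanning 60–300 residues,
and one 20-conformer ensemble — sizes chosen so the full study completes
in minutes on a single CPU while each replicate remains large enough for
the tail effect to dominate sampling noise.

## Numerical choices and degenerate inputs

- Quadrature: 960 golden-spiral points; settings are part of every result.
- GB: no distance cutoff; exact O(n²) summation is the reference path.
- Identical atomic coordinates raise a geometry error in GB (the
  descreening integral is singular); the generator never produces them.
- Effective radii are floored at ρ̃ as a numerical guard (analytically
  1/R > 0 always holds since tanh < 1 and ρ > ρ̃).
- Altloc resolution on PDB input: highest occupancy, ties to label 'A'.
- Empty composites, empty reference distributions, ragged trajectories,
  and single-value standard deviations are all explicit, flagged cases.
- Sample (n−1) standard deviations everywhere.

## Known limitations

- United-atom charges reproduce monopole-level solvation trends only;
  absolute kJ/mol values are scheme-specific.
- The free-residue SASA reference uses the package's own template pose;
  relative accessibilities are consistent within the package but not
  numerically interchangeable with DSSP-convention values.
- The reference set here is synthetic; with real curated structures the
  same code paths apply, but metadata quality governs the filter's value.
- Rotation invariance of SASA holds to quadrature precision, not exactly.
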