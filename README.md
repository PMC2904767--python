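# tailsolv

Solvation analysis of proteins carrying intrinsically disordered terminal
tails.

Many proteins — prominently stress-resistance enzymes of extremophile
bacteria such as the nudix hydrolase of *Deinococcus radiodurans* — carry
long, low-complexity, hydrophilic N- and C-terminal tails rich in glycine,
proline, arginine and lysine. `tailsolv` quantifies how such tails change a
protein's solvation surface, for structural bioinformaticians who want to
test the "tails as hydrators" picture on their own structures or on
synthetic constructs:

- **Hydration free energy (GB/SA).** ΔG_hyd = ΔG_pol + σ·SASA, with the
  polar term from the generalized Born model in the Onufriev–Bashford–Case
  (OBC-II) variant:

  ΔG_pol = −½ (1/ε_in − 1/ε_w) k_C Σ_ij q_i q_j / f_GB(r_ij, R_i, R_j),
  f_GB = √(r² + R_i R_j e^(−r²/4R_iR_j)),

  where the effective Born radii R_i come from HCT pairwise descreening
  with the OBC tanh correction. Energies are reported absolute (kJ/mol) and
  size-normalized (kJ/mol/residue), for full-length, N-terminally truncated
  (Δk), and core-only structures.
- **Solvent accessibility.** Shrake–Rupley SASA (1.4 Å probe, golden-spiral
  quadrature), relative accessibility against the free amino acid, surface
  classification at a cutoff (0.4 conventional), and the tails' share of
  the total surface.
- **Surface sequence entropy.** Shannon entropy H = −Σ p_i ln p_i of the
  composite sequence of residues above an accessibility cutoff, swept from
  0 to 0.4, per segment (N-tail / core / C-tail) and across ensembles.
- **Ensemble statistics.** Radius of gyration, Kabsch superposition,
  all-against-all pairwise backbone RMSD per segment, and percentile
  placement of a query against a reference distribution of normalized
  hydration energies.
- **Reference-set filters.** The standard quality screen (X-ray, resolution
  ≤ 2.5 Å, R-factor ≤ 0.3, ≥ 40 residues, no chain breaks or nonstandard
  residues, exclusion flags) over structure metadata.
- **Synthetic structures.** A seeded generator producing clash-free compact
  globular cores (hydrophobic-in/polar-out), hydrophilic low-complexity
  tails, and conformer ensembles, so the whole pipeline runs without any
  external data.

## Worked example

```python
import tailsolv as ts
from tailsolv.synthetic_data import construct_segments
from tailsolv.solvent_accessibility import residue_sasa, relative_accessibility
from tailsolv.sequence_entropy import entropy_sweep

cfg = ts.GeneratorConfig(seed=1, core_length=150, tail_lengths=(80, 40))
construct = ts.generate_construct(cfg)          # 270-residue tailed protein
segs = construct_segments(cfg)                  # n_tail / core / c_tail

full = ts.hydration_free_energy(construct)
core = ts.hydration_free_energy(ts.extract_segment(construct, segs["core"]))
print(full.total, full.normalized)              # -74742.5 kJ/mol, -276.82 kJ/mol/residue
print(core.total, core.normalized)              # -31130.2 kJ/mol, -207.53 kJ/mol/residue

table = relative_accessibility(residue_sasa(construct))
print(ts.sasa_fraction(construct, [segs["n_tail"], segs["c_tail"]], table=table))
# 65.5  (percent of the total surface contributed by the tails)

print(entropy_sweep(construct, [segs["n_tail"], segs["core"]], table, [0.0, 0.4]))
#  segment  cutoff  n_residues  entropy
#   n_tail     0.0          80    1.823
#   n_tail     0.4          76    1.827
#     core     0.0         150    2.779
#     core     0.4          24    1.827
```

The numbers tell the story in miniature: the tailed construct is far more
hydrophilic per residue than its own core (−276.8 vs −207.5 kJ/mol/residue),
the tails dominate the solvent-accessible surface (65.5%), and while the
whole core is compositionally diverse (H = 2.78), its *surface* residues at
the conventional 0.4 cutoff have tail-like low complexity (H = 1.83 vs the
tail's 1.82) — the disordered tail looks like pure protein surface.

## Command line

Every stage is also a subcommand of the `tailsolv` console script:

```sh
tailsolv simulate --seed 7 --out ens.pdb        # synthetic construct + ensemble
tailsolv sasa ens.pdb --out sasa.csv
tailsolv hfe ens.pdb --out hfe.csv
tailsolv entropy-sweep ens.pdb --segment n_tail:A:1:80 --out entropy.csv
tailsolv ensemble-stats ens.pdb --segment core:A:81:230 --out stats.json
tailsolv truncate ens.pdb -k 44 --out delta44.pdb
tailsolv ref-filter metadata.csv --out report.csv
tailsolv run ens.pdb --config config.toml --outdir out/   # everything at once
```

`run` emits six artifacts (hydration energies for full/Δk/core variants,
the entropy sweep, per-model Rg/SASA series, pairwise RMSD statistics, the
reference percentile, and the tail SASA fraction), each row stamped with
the seed and a hash of the effective TOML configuration.

## Documentation

`docs/methods.md` describes the model, its parameters and defaults, the
synthetic generator's design and its limits, and the numerical choices.
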