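"""GB/OBC hydration energy: analytic limits, descreening oracle, orderings."""

import math
from dataclasses import replace
from importlib import resources

import numpy as np
import pytest

from tailsolv import (
    AtomParameters,
    GbsaSettings,
    ParameterSet,
    assign_parameters,
    effective_born_radii,
    gb_polar_energy,
    hydration_free_energy,
    sa_nonpolar_energy,
    transfer_scaling,
)
from tailsolv.errors import GeometryError, ParameterizationError
from tailsolv.hydration_energy import COULOMB_KCAL, KCAL_TO_KJ, _hct_integrals
from tailsolv.structure_model import Atom, Chain, Residue, StructureModel
from tailsolv.synthetic_data import analytic_fixtures

SETTINGS = GbsaSettings()


def _free_model(code3):
    from tailsolv.solvent_accessibility import free_residue_model

    return free_residue_model(code3)


def born_ion_energy(q, r_eff, settings=SETTINGS):
    """Closed-form Born equation, kJ/mol."""
    return (
        -settings.dielectric_factor * COULOMB_KCAL * q * q / (2.0 * r_eff) * KCAL_TO_KJ
    )


class TestAssignParameters:
    def test_polyglycine_neutral_with_capped_termini(self):
        from tailsolv.synthetic_data import GeneratorConfig, generate_globule

        cfg = GeneratorConfig(seed=3, core_length=12, tail_lengths=(0, 0),
                              core_composition={"G": 1.0})
        model = generate_globule(cfg)
        params = assign_parameters(model, charged_termini=False)
        assert params.charge.sum() == pytest.approx(0.0, abs=1e-9)

    def test_single_lysine_net_plus_one(self):
        params = assign_parameters(_free_model("LYS"), charged_termini=True)
        assert params.charge.sum() == pytest.approx(1.0, abs=1e-9)

    def test_template_sums_match_file_oracle(self):
        """Per-residue charge sums from an independent parse of the bundled
        file equal the residues' formal charges."""
        ref = resources.files("tailsolv.data").joinpath("gbsa_params.dat")
        sums = {}
        for line in ref.read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            code3, _atom, q, _r, _s = line.split()
            sums[code3] = sums.get(code3, 0.0) + float(q)
        formal = {"ASP": -1.0, "GLU": -1.0, "LYS": 1.0, "ARG": 1.0}
        assert len(sums) == 20
        for code3, total in sums.items():
            assert total == pytest.approx(formal.get(code3, 0.0), abs=1e-9)
        pset = ParameterSet.default()
        for code3 in sums:
            assert pset.residue_charge(code3) == pytest.approx(sums[code3], abs=1e-12)

    def test_unknown_atom_names_residue_and_atom(self):
        model = _free_model("ALA")
        model.chains[0].residues[0].atoms[0].name = "XQ1"
        model.chains[0].residues[0].atoms[0].element = "C"
        with pytest.raises(ParameterizationError, match="ALA"):
            assign_parameters(model)


class TestBornRadii:
    def test_isolated_atom_reduces_to_offset_radius(self):
        model = analytic_fixtures()["single_ion"]
        params = AtomParameters(
            charge=[1.0], intrinsic_radius=[1.70], screening_scale=[0.72]
        )
        r = effective_born_radii(model, params, SETTINGS)
        assert r[0] == pytest.approx(1.70 - 0.09, abs=1e-12)

    def test_burial_increases_radius(self):
        from tailsolv.solvent_accessibility import _sphere_points

        radii = []
        for n_shell in (0, 12, 40):
            atoms = [Atom("CA", "C", np.zeros(3), 1)]
            shell = 4.0 * _sphere_points(n_shell) if n_shell else []
            atoms += [Atom("CA", "C", xyz, i + 2) for i, xyz in enumerate(shell)]
            residues = [Residue("GLY", 1, [atoms[0]])]
            if len(atoms) > 1:
                residues.append(Residue("GLY", 2, atoms[1:]))
            model = StructureModel(chains=[Chain("A", residues)])
            n = len(atoms)
            params = AtomParameters(
                charge=np.zeros(n),
                intrinsic_radius=np.full(n, 1.70),
                screening_scale=np.full(n, 0.72),
            )
            radii.append(effective_born_radii(model, params, SETTINGS)[0])
        assert radii[0] < radii[1] < radii[2]

    def test_two_atom_descreening_matches_numeric_integral(self):
        """Closed-form HCT pairwise term vs direct numerical integration of
        r^-4 over the neighbour sphere."""

        def numeric(d, rho_i, s_j, n=260):
            g = np.linspace(-s_j, s_j, n)
            dx = g[1] - g[0]
            x, y, z = np.meshgrid(g + d, g, g, indexing="ij")
            inside = ((x - d) ** 2 + y**2 + z**2) <= s_j**2
            r2 = x**2 + y**2 + z**2
            mask = inside & (r2 > rho_i**2)
            return (1.0 / (4 * np.pi)) * (1.0 / r2[mask] ** 2).sum() * dx**3

        for d, rho_i, s_j in [(4.0, 1.5, 1.2), (2.0, 1.5, 1.2), (0.4, 0.3, 1.2)]:
            coords = np.array([[0.0, 0, 0], [d, 0, 0]])
            closed = _hct_integrals(
                coords, np.array([rho_i, s_j]), np.array([0.0, s_j])
            )[0]
            assert closed == pytest.approx(numeric(d, rho_i, s_j), rel=2e-3)

    def test_identical_coordinates_rejected(self):
        model = StructureModel(
            chains=[
                Chain(
                    "A",
                    [
                        Residue("GLY", 1, [Atom("CA", "C", np.zeros(3), 1)]),
                        Residue("GLY", 2, [Atom("CA", "C", np.zeros(3), 2)]),
                    ],
                )
            ]
        )
        params = AtomParameters(
            charge=[0.0, 0.0],
            intrinsic_radius=[1.7, 1.7],
            screening_scale=[0.72, 0.72],
        )
        with pytest.raises(GeometryError):
            effective_born_radii(model, params, SETTINGS)


class TestPolarEnergy:
    def test_zero_charges_zero_energy(self, small_construct):
        params = assign_parameters(small_construct)
        zero = AtomParameters(
            charge=np.zeros(len(params)),
            intrinsic_radius=params.intrinsic_radius,
            screening_scale=params.screening_scale,
        )
        r = effective_born_radii(small_construct, zero, SETTINGS)
        assert gb_polar_energy(small_construct, zero, r, SETTINGS) == 0.0

    def test_single_ion_born_equation(self):
        model = analytic_fixtures()["single_ion"]
        params = AtomParameters(
            charge=[1.0], intrinsic_radius=[4.09], screening_scale=[0.72]
        )
        r_eff = np.array([4.0])
        got = gb_polar_energy(model, params, r_eff, SETTINGS)
        want = born_ion_energy(1.0, 4.0)
        assert got == pytest.approx(want, rel=1e-12)
        assert want == pytest.approx(-171.5, abs=0.1)

    def test_single_charged_atom_strictly_negative(self):
        model = analytic_fixtures()["single_ion"]
        params = AtomParameters(
            charge=[-0.55], intrinsic_radius=[1.50], screening_scale=[0.85]
        )
        r = effective_born_radii(model, params, SETTINGS)
        assert gb_polar_energy(model, params, r, SETTINGS) < 0.0


class TestNonpolarEnergy:
    def test_single_atom_analytic(self):
        model = analytic_fixtures()["single_ion"]  # one nitrogen atom
        got = sa_nonpolar_energy(model, SETTINGS)
        want = SETTINGS.surface_tension * 4 * math.pi * (1.55 + 1.4) ** 2
        assert got == pytest.approx(want, rel=1e-12)

    def test_linear_in_surface_tension(self, small_construct):
        base = sa_nonpolar_energy(small_construct, SETTINGS)
        doubled = sa_nonpolar_energy(
            small_construct, replace(SETTINGS, surface_tension=2 * SETTINGS.surface_tension)
        )
        assert doubled == pytest.approx(2 * base)

    def test_matches_independent_sasa(self, small_construct):
        from tailsolv import shrake_rupley

        total = float(shrake_rupley(small_construct).sum())
        assert sa_nonpolar_energy(small_construct, SETTINGS) == pytest.approx(
            SETTINGS.surface_tension * total
        )


class TestHydrationFreeEnergy:
    def test_rigid_motion_invariance(self, small_construct):
        from scipy.spatial.transform import Rotation

        base = hydration_free_energy(small_construct)
        moved = small_construct.copy()
        rot = Rotation.from_euler("xyz", [10.0, 80.0, -30.0], degrees=True).as_matrix()
        for atom in moved.atoms():
            atom.coords = rot @ atom.coords + np.array([-4.0, 2.0, 9.0])
        again = hydration_free_energy(moved)
        # polar term depends only on distances: invariant to fp precision;
        # nonpolar inherits the SASA quadrature's rotation tolerance
        assert again.polar == pytest.approx(base.polar, rel=1e-9)
        assert again.nonpolar == pytest.approx(base.nonpolar, rel=2e-3)

    def test_total_and_normalization_bookkeeping(self, small_construct):
        r = hydration_free_energy(small_construct)
        assert r.total == pytest.approx(r.polar + r.nonpolar)
        assert r.normalized == pytest.approx(r.total / r.n_residues)
        assert r.n_residues == small_construct.n_residues

    def test_hydrophilic_tails_lower_normalized_hfe(self):
        """Across seeded replicates, attaching hydrophilic tails lowers the
        mean per-residue hydration free energy below the cores' own (a
        distributional effect: at this reduced size individual replicates
        are noisy, the mean is not)."""
        from tailsolv import GeneratorConfig, extract_segment, generate_construct
        from tailsolv.synthetic_data import construct_segments

        full_vals, core_vals = [], []
        for seed in range(6):
            cfg = GeneratorConfig(seed=seed, core_length=30, tail_lengths=(16, 8))
            construct = generate_construct(cfg)
            segs = construct_segments(cfg)
            full_vals.append(hydration_free_energy(construct).normalized)
            core_vals.append(
                hydration_free_energy(
                    extract_segment(construct, segs["core"])
                ).normalized
            )
        assert np.mean(full_vals) < np.mean(core_vals)

    def test_charged_tails_below_apolar_tails(self):
        """Constructs differing only in tail composition order
        deterministically: charged/polar tails give a lower normalized HFE
        than apolar tails on the same core."""
        from tailsolv import GeneratorConfig, generate_construct

        apolar = {"A": 0.3, "V": 0.2, "L": 0.2, "I": 0.15, "F": 0.15}
        base = dict(seed=11, core_length=30, tail_lengths=(16, 8))
        hydrophilic = hydration_free_energy(
            generate_construct(GeneratorConfig(**base))
        )
        greasy = hydration_free_energy(
            generate_construct(GeneratorConfig(**base, tail_composition=apolar))
        )
        assert hydrophilic.normalized < greasy.normalized

    def test_removing_charged_surface_residue_raises_polar(self, small_construct):
        """Dropping a charged exposed residue makes the polar term less
        negative (direct recomputation oracle)."""
        from tailsolv.solvent_accessibility import relative_accessibility, residue_sasa

        table = relative_accessibility(residue_sasa(small_construct)).frame
        charged = table[
            table["code1"].isin(list("KRDE")) & (table["rel_sa"] > 0.3)
        ]
        idx = int(charged["seq_index"].iloc[0])
        pruned = small_construct.copy()
        pruned.chains[0].residues = [
            r for r in pruned.chains[0].residues if r.seq_index != idx
        ]
        base = hydration_free_energy(small_construct)
        less = hydration_free_energy(pruned)
        assert less.polar > base.polar


class TestTransferScaling:
    def test_identity_for_native_dielectrics(self, small_construct):
        r = hydration_free_energy(small_construct)
        assert transfer_scaling(r, SETTINGS.eps_in, SETTINGS.eps_solv) == pytest.approx(
            r.total
        )

    def test_equal_dielectrics_zero_polar(self, small_construct):
        r = hydration_free_energy(small_construct)
        assert transfer_scaling(r, 10.0, 10.0) == pytest.approx(r.nonpolar)

    def test_monotone_in_inverse_dielectric_difference(self, small_construct):
        r = hydration_free_energy(small_construct)
        diffs = []
        totals = []
        for eps_a, eps_b in [(1.0, 2.0), (1.0, 10.0), (1.0, 78.5), (1.0, 1000.0)]:
            diffs.append(1 / eps_a - 1 / eps_b)
            totals.append(transfer_scaling(r, eps_a, eps_b))
        # polar part is negative, so larger inverse-dielectric difference
        # means a more negative scaled total
        assert all(b < a for a, b in zip(totals, totals[1:]))
        assert all(b > a for a, b in zip(diffs, diffs[1:]))
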