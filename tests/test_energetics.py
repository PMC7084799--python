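"""Closed-form and brute-force oracles for the MM/PBSA energetics."""

import numpy as np
import pytest

from ppimutscan.energetics import (
    PBSettings,
    ensemble_binding_energy,
    frame_binding_energy,
    mm_interaction_energy,
    mm_interaction_per_atom,
    nonpolar_solvation,
    shrake_rupley_sasa,
)
from ppimutscan.ensemble_io import Ensemble
from ppimutscan import pbsolver
from ppimutscan.pbsolver import COULOMB_CONSTANT as F
from conftest import two_chain_structure

BORN = lambda q, R, e_in, e_out: -(F * q * q / (2 * R)) * (1 / e_in - 1 / e_out)


class TestMMInteraction:
    def test_lj_minimum_energy_is_minus_epsilon(self):
        eps, sig = 0.3, 3.0
        d = 2 ** (1 / 6) * sig
        s = two_chain_structure([[0.0, 0, 0]], [[d, 0, 0]], epsilon=eps, sigma=sig)
        e_vdw, e_elec = mm_interaction_energy(s, "A", "B")
        assert e_vdw == pytest.approx(-eps, rel=1e-12)
        assert e_elec == 0.0

    def test_coulomb_pair_matches_constant(self):
        s = two_chain_structure([[0.0, 0, 0]], [[10.0, 0, 0]], charges=[1.0, 1.0],
                                epsilon=0.0)
        _, e_elec = mm_interaction_energy(s, "A", "B")
        assert e_elec == pytest.approx(F / 10.0)
        assert e_elec == pytest.approx(138.935458, abs=1e-6)

    def test_matches_double_loop_brute_force(self):
        rng = np.random.default_rng(21)
        pa = rng.uniform(0, 12, size=(50, 3))
        pb = rng.uniform(0, 12, size=(50, 3)) + np.array([16.0, 0, 0])
        q = rng.uniform(-0.8, 0.8, size=100)
        s = two_chain_structure(pa, pb, charges=q)
        s.lj_sigmas[:] = rng.uniform(2.5, 3.5, size=100)
        s.lj_epsilons[:] = rng.uniform(0.1, 0.6, size=100)
        e_vdw, e_elec = mm_interaction_energy(s, "A", "B")
        ref_vdw = ref_elec = 0.0
        for i in range(50):
            for j in range(50, 100):
                d = np.linalg.norm(s.positions[i] - s.positions[j])
                sig = 0.5 * (s.lj_sigmas[i] + s.lj_sigmas[j])
                eps = np.sqrt(s.lj_epsilons[i] * s.lj_epsilons[j])
                ref_vdw += 4 * eps * ((sig / d) ** 12 - (sig / d) ** 6)
                ref_elec += F * s.charges[i] * s.charges[j] / d
        assert e_vdw == pytest.approx(ref_vdw, rel=1e-9)
        assert e_elec == pytest.approx(ref_elec, rel=1e-9)

    def test_per_atom_ledger_complete_on_each_chain(self):
        rng = np.random.default_rng(22)
        s = two_chain_structure(
            rng.uniform(0, 8, (20, 3)),
            rng.uniform(0, 8, (20, 3)) + 12.0,
            charges=rng.uniform(-0.5, 0.5, 40),
        )
        vdw, elec = mm_interaction_per_atom(s, "A", "B")
        tot_vdw, tot_elec = mm_interaction_energy(s, "A", "B")
        ia, ib = s.chain_indices("A"), s.chain_indices("B")
        assert vdw[ia].sum() == pytest.approx(tot_vdw, rel=1e-12)
        assert vdw[ib].sum() == pytest.approx(tot_vdw, rel=1e-12)
        assert elec[ia].sum() == pytest.approx(tot_elec, rel=1e-12)

    def test_overlapping_atoms_rejected(self):
        s = two_chain_structure([[0.0, 0, 0]], [[0.0, 0, 0]])
        with pytest.raises(ValueError, match="overlap"):
            mm_interaction_energy(s, "A", "B")


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        s = two_chain_structure([[0.0, 0, 0]], [[50.0, 0, 0]])
        areas = shrake_rupley_sasa(s, probe=1.4, n_points=512)
        exact = 4 * np.pi * (1.7 + 1.4) ** 2
        assert areas[0] == pytest.approx(exact, rel=0.01)
        assert areas[0] == pytest.approx(120.76, abs=1.3)

    def test_coincident_spheres_total_equals_one_sphere(self):
        s = two_chain_structure([[0.0, 0, 0]], [[1e-4, 0, 0]])
        areas = shrake_rupley_sasa(s, probe=1.4, n_points=512)
        exact = 4 * np.pi * (1.7 + 1.4) ** 2
        assert areas.sum() == pytest.approx(exact, rel=0.01)

    def test_cluster_matches_independent_quadrature_oracle(self):
        rng = np.random.default_rng(23)
        pos = rng.uniform(0, 6.0, size=(20, 3))
        s = two_chain_structure(pos[:10], pos[10:])
        areas = shrake_rupley_sasa(s, probe=1.4, n_points=960)

        # independent oracle: latitude-longitude quadrature with sin-weights
        def latlon_sasa(positions, radii, probe, n_theta=120, n_phi=240):
            total = 0.0
            theta = (np.arange(n_theta) + 0.5) * np.pi / n_theta
            phi = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
            tt, pp = np.meshgrid(theta, phi, indexing="ij")
            dirs = np.stack(
                [np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp), np.cos(tt)], axis=-1
            ).reshape(-1, 3)
            w = (np.sin(tt) * (np.pi / n_theta) * (2 * np.pi / n_phi)).reshape(-1)
            big = radii + probe
            for i in range(len(positions)):
                pts = positions[i] + big[i] * dirs
                occluded = np.zeros(len(pts), dtype=bool)
                for j in range(len(positions)):
                    if j == i:
                        continue
                    occluded |= (
                        np.sum((pts - positions[j]) ** 2, axis=1) <= big[j] ** 2
                    )
                total += big[i] ** 2 * np.sum(w[~occluded])
            return total

        oracle = latlon_sasa(s.positions, s.vdw_radii, 1.4)
        assert areas.sum() == pytest.approx(oracle, rel=0.02)

    def test_too_few_points_rejected(self, toy_structure):
        with pytest.raises(ValueError):
            shrake_rupley_sasa(toy_structure, n_points=50)


class TestNonpolar:
    def test_zero_area_gives_offset(self):
        st = PBSettings(nonpolar_gamma=0.5, nonpolar_offset=2.5)
        assert nonpolar_solvation(0.0, st) == 2.5

    def test_linear_in_area(self):
        st = PBSettings(nonpolar_gamma=0.0227, nonpolar_offset=0.0)
        assert nonpolar_solvation(1000.0, st) == pytest.approx(22.7)


class TestLpbSolver:
    def test_born_ion_closed_form_coarse(self):
        settings = PBSettings(grid_spacing=0.8, ionic_strength=0.0)
        g = pbsolver.polar_solvation(
            np.array([[0.05, 0.03, -0.07]]), np.array([1.0]), np.array([2.0]), settings
        )
        exact = BORN(1.0, 2.0, 2.0, 80.0)
        assert g == pytest.approx(exact, rel=0.15)

    def test_homogeneous_dielectric_gives_zero(self):
        settings = PBSettings(
            grid_spacing=0.8, solute_dielectric=2.0, solvent_dielectric=2.0,
            ionic_strength=0.0,
        )
        g = pbsolver.polar_solvation(
            np.array([[0.0, 0.0, 0.0]]), np.array([1.0]), np.array([2.0]), settings
        )
        assert g == pytest.approx(0.0, abs=0.5)

    def test_uncharged_system_zero(self):
        settings = PBSettings(grid_spacing=0.8)
        g = pbsolver.polar_solvation(
            np.array([[0.0, 0.0, 0.0]]), np.array([0.0]), np.array([2.0]), settings
        )
        assert g == 0.0

    def test_salt_strengthens_screening(self):
        c, q, r = np.array([[0.0, 0.0, 0.0]]), np.array([1.0]), np.array([2.0])
        g_salt = pbsolver.polar_solvation(
            c, q, r, PBSettings(grid_spacing=0.8, ionic_strength=150.0)
        )
        g_plain = pbsolver.polar_solvation(
            c, q, r, PBSettings(grid_spacing=0.8, ionic_strength=0.0)
        )
        assert g_salt < g_plain  # salt makes solvation more favorable

    def test_two_sphere_kirkwood_series_oracle(self):
        # well-separated charged spheres: Born terms + screened interaction
        coords = np.array([[0.0, 0.0, 0.0], [12.0, 0.0, 0.0]])
        q = np.array([1.0, -1.0])
        r = np.array([2.0, 2.0])
        settings = PBSettings(grid_spacing=0.4, ionic_strength=0.0)
        g = pbsolver.polar_solvation(coords, q, r, settings)
        oracle = (
            BORN(1.0, 2.0, 2.0, 80.0)
            + BORN(-1.0, 2.0, 2.0, 80.0)
            + F * q[0] * q[1] * (1 / 80.0 - 1 / 2.0) / 12.0
        )
        assert g == pytest.approx(oracle, rel=0.10)

    def test_debye_length_physiological(self):
        k2 = pbsolver.debye_kappa2(PBSettings(ionic_strength=150.0, temperature=310.15))
        debye_len = 1.0 / np.sqrt(k2)
        assert 7.0 < debye_len < 9.0  # ~8 Å at 150 mM


class TestFrameBindingEnergy:
    def test_far_separated_neutral_chains_vanish(self, fast_pb):
        rng = np.random.default_rng(25)
        pa = rng.uniform(0, 5, size=(4, 3))
        pb = pa + np.array([100.0, 0.0, 0.0])
        s = two_chain_structure(pa, pb)
        terms = frame_binding_energy(s, "A", "B", fast_pb)
        assert abs(terms.total) < 0.5
        for value in terms.as_dict().values():
            assert abs(value) < 0.5

    def test_lj_dimer_without_solvation(self):
        eps, sig = 0.4, 3.0
        d = 2 ** (1 / 6) * sig
        s = two_chain_structure([[0.0, 0, 0]], [[d, 0, 0]], epsilon=eps, sigma=sig)
        terms = frame_binding_energy(s, "A", "B", include_solvation=False)
        assert terms.total == pytest.approx(-eps, rel=1e-10)

    def test_component_additivity_invariants(self, variant_suite, fast_pb):
        terms = frame_binding_energy(variant_suite.wild_type.frame(0), "A", "B", fast_pb)
        assert terms.E_MM == terms.E_vdW + terms.E_elec
        assert terms.G_solvation == terms.G_polar + terms.G_nonpolar
        assert terms.total == terms.E_MM + terms.G_solvation

    def test_total_matches_component_oracles(self, fast_pb):
        # charged toy dimer: compare against an independently scripted
        # six-solve route (no reference-superposition shortcut)
        rng = np.random.default_rng(26)
        pa = rng.uniform(0, 4, (3, 3))
        pb = rng.uniform(0, 4, (3, 3)) + np.array([9.0, 0, 0])
        q = np.array([0.4, -0.3, 0.2, -0.4, 0.3, -0.2])
        s = two_chain_structure(pa, pb, charges=q)
        terms = frame_binding_energy(s, "A", "B", fast_pb)

        e_vdw, e_elec = mm_interaction_energy(s, "A", "B")
        grid = pbsolver.grid_for(s.positions, s.vdw_radii, fast_pb)
        ia, ib = s.chain_indices("A"), s.chain_indices("B")
        gp = {}
        for label, idx in (("c", slice(None)), ("a", ia), ("b", ib)):
            gp[label] = pbsolver.polar_solvation(
                s.positions[idx], s.charges[idx], s.vdw_radii[idx], fast_pb, grid=grid
            )
        g_polar = gp["c"] - gp["a"] - gp["b"]
        sasa_c = shrake_rupley_sasa(s).sum()
        sasa_a = shrake_rupley_sasa(s.subset(ia)).sum()
        sasa_b = shrake_rupley_sasa(s.subset(ib)).sum()
        g_np = (
            nonpolar_solvation(sasa_c, fast_pb)
            - nonpolar_solvation(sasa_a, fast_pb)
            - nonpolar_solvation(sasa_b, fast_pb)
        )
        assert terms.E_vdW == pytest.approx(e_vdw, rel=1e-12)
        assert terms.E_elec == pytest.approx(e_elec, rel=1e-12)
        assert terms.G_nonpolar == pytest.approx(g_np, abs=1e-9)
        assert terms.G_polar == pytest.approx(g_polar, abs=0.5)
        assert terms.total == pytest.approx(e_vdw + e_elec + g_polar + g_np, abs=0.6)


class TestEnsembleBindingEnergy:
    def test_static_ensemble_zero_uncertainty(self, toy_structure):
        coords = np.repeat(toy_structure.positions[None], 4, axis=0)
        ens = Ensemble(toy_structure, coords, 100.0 * np.arange(4))
        res = ensemble_binding_energy(ens, include_solvation=False, seed=1)
        for value in res.uncertainty.as_dict().values():
            assert value == pytest.approx(0.0, abs=1e-12)

    def test_mean_total_is_mean_of_frame_totals(self, variant_suite):
        res = ensemble_binding_energy(
            variant_suite.wild_type, include_solvation=False, seed=1
        )
        assert res.mean.total == pytest.approx(
            np.mean([t.total for t in res.per_frame]), rel=1e-12
        )

    def test_bootstrap_is_seeded(self, variant_suite):
        kw = dict(include_solvation=False)
        a = ensemble_binding_energy(variant_suite.wild_type, seed=7, **kw)
        b = ensemble_binding_energy(variant_suite.wild_type, seed=7, **kw)
        assert a.uncertainty.as_dict() == b.uncertainty.as_dict()
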