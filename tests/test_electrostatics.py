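"""Dielectric maps, LPB solver oracles, transfer energies and field maps."""

import numpy as np
import pytest

from ionpore.constants import COULOMB_KCAL
from ionpore.electrostatics import (
    LABEL_CORE,
    LABEL_PROTEIN,
    LABEL_WATER,
    DielectricMap,
    PBOptions,
    average_field_map,
    build_dielectric_map,
    kappa_from_ionic_strength,
    solve_lpb,
    solve_lpb_focused,
    transfer_energy_grid,
    uniform_dielectric_map,
)
from ionpore.errors import ConfigurationError, ConvergenceError, EmptyInputError
from ionpore.grids import Grid3D
from ionpore.synthetic import fixed_charge_ring, ideal_gas_trajectory


def centered_uniform(n, h, eps=80.0):
    ext = (n - 1) * h
    origin = -np.array([ext, ext, ext]) / 2.0
    return uniform_dielectric_map(origin, h, (n, n, n), eps=eps)


def sphere_map(a, n, h, eps_in=1.0, eps_out=80.0):
    """Ion-sized low-dielectric sphere at the origin (Born geometry)."""
    ext = (n - 1) * h
    origin = -np.array([ext, ext, ext]) / 2.0
    g = Grid3D(origin, h, np.zeros((n, n, n)))
    r = np.linalg.norm(g.points().reshape(n, n, n, 3), axis=-1)
    eps = np.where(r < a, eps_in, eps_out)
    labels = np.where(r < a, LABEL_PROTEIN, LABEL_WATER).astype(np.int8)
    return DielectricMap(
        eps=Grid3D(origin, h, eps), labels=labels, eps_water=eps_out
    )


class TestDielectricMap:
    def test_three_region_rules(self):
        atoms = np.array([[0.0, 0.0, 0.0]])
        dm = build_dielectric_map(
            atoms, [3.0], origin=(-32.0, -32.0, -32.0), spacing=2.0,
            shape=(33, 33, 33), slab_half=12.5,
        )
        def at(p):
            i = tuple(int(round((v + 32.0) / 2.0)) for v in p)
            return dm.eps.values[i], dm.labels[i]

        assert at((0.0, 0.0, 30.0)) == (80.0, LABEL_WATER)   # far outside
        assert at((0.0, 0.0, 0.0)) == (4.0, LABEL_PROTEIN)   # inside the atom
        assert at((30.0, 30.0, 0.0)) == (2.0, LABEL_CORE)    # slab, off protein
        assert at((30.0, 30.0, 14.0)) == (80.0, LABEL_WATER) # headgroup/water

    def test_pore_cylinder_stays_water(self):
        dm = build_dielectric_map(
            np.zeros((0, 3)), [], origin=(-16.0, -16.0, -16.0), spacing=2.0,
            shape=(17, 17, 17), slab_half=12.5, pore_radius=6.0,
        )
        i = (8, 8, 8)  # on the axis, mid-slab
        assert dm.labels[i] == LABEL_WATER
        assert dm.labels[(1, 8, 8)] == LABEL_CORE  # off-axis slab node

    def test_empty_structure_warns(self):
        with pytest.warns(UserWarning):
            build_dielectric_map(
                np.zeros((0, 3)), [], origin=(0, 0, 0), spacing=1.0, shape=(5, 5, 5)
            )


class TestSolverOracles:
    def test_zero_charge_gives_zero_potential(self):
        dm = centered_uniform(17, 1.0)
        phi = solve_lpb(dm, [], PBOptions(tol=1e-6, max_iter=100))
        np.testing.assert_allclose(phi.values, 0.0)

    def test_coulomb_oracle_uniform_dielectric(self):
        """Single charge in eps=80: phi = k_c q / (eps r) within 2% mid-range."""
        n, h = 97, 0.5
        dm = centered_uniform(n, h)
        phi = solve_lpb(dm, [((0.0, 0.0, 0.0), 1.0)], PBOptions(tol=1e-5, max_iter=3000))
        ic = n // 2
        for r in (5.0, 8.0, 12.0, 16.0, 20.0):
            val = phi.values[ic + int(r / h), ic, ic]
            ana = COULOMB_KCAL / (80.0 * r)
            assert val == pytest.approx(ana, rel=0.02)

    def test_debye_hueckel_oracle(self):
        """Screened charge: phi = k_c q e^(-kr)/(eps r) within 3% mid-range."""
        n, h = 81, 0.5
        dm = centered_uniform(n, h)
        opts = PBOptions(tol=1e-5, max_iter=3000, ionic_strength=0.1)
        kappa = kappa_from_ionic_strength(0.1, 300.0, 80.0)
        phi = solve_lpb(dm, [((0.0, 0.0, 0.0), 1.0)], opts)
        ic = n // 2
        for r in (5.0, 8.0, 12.0, 16.0):
            val = phi.values[ic + int(r / h), ic, ic]
            ana = COULOMB_KCAL * np.exp(-kappa * r) / (80.0 * r)
            assert val == pytest.approx(ana, rel=0.03)

    def test_born_self_energy_two_percent(self):
        """Solvation of a 2 A ion: -(k_c/2a)(1 - 1/80) at 0.25 A spacing."""
        a, n, h = 2.0, 65, 0.25
        opts = PBOptions(tol=1e-5, max_iter=3000)
        ic = n // 2
        charge = [((0.0, 0.0, 0.0), 1.0)]
        e = {}
        for eps_out in (80.0, 1.0):
            dm = sphere_map(a, n, h, eps_out=eps_out)
            phi = solve_lpb(dm, charge, opts)
            e[eps_out] = 0.5 * phi.values[ic, ic, ic]
        born = e[80.0] - e[1.0]
        analytic = -(COULOMB_KCAL / (2.0 * a)) * (1.0 - 1.0 / 80.0)
        assert born == pytest.approx(analytic, rel=0.02)

    def test_linearity_doubling_charges_doubles_potential(self):
        n, h = 33, 1.0
        dm = centered_uniform(n, h)
        opts = PBOptions(tol=1e-9, max_iter=5000)
        p1 = solve_lpb(dm, [((0.0, 0.0, 0.0), 1.0)], opts)
        p2 = solve_lpb(dm, [((0.0, 0.0, 0.0), 2.0)], opts)
        np.testing.assert_allclose(p2.values, 2.0 * p1.values, rtol=1e-6, atol=1e-9)

    def test_symmetric_charges_symmetric_potential(self):
        n, h = 33, 1.0
        dm = centered_uniform(n, h)
        charges = [((0.0, 0.0, 6.0), 1.0), ((0.0, 0.0, -6.0), 1.0)]
        phi = solve_lpb(dm, charges, PBOptions(tol=1e-7, max_iter=5000)).values
        np.testing.assert_allclose(phi, phi[:, :, ::-1], atol=1e-5)

    def test_focusing_refines_toward_analytic(self):
        opts = PBOptions(
            tol=1e-5, max_iter=3000, outer_extent=64.0, levels=2,
            final_spacing=0.25, nodes_per_level=33,
        )
        phi = solve_lpb_focused(
            lambda o, s, sh: uniform_dielectric_map(o, s, sh, eps=80.0),
            [((0.0, 0.0, 0.0), 1.0)],
            opts,
        )
        ic = 16
        r = 8 * 0.25
        val = phi.values[ic + 8, ic, ic]
        assert val == pytest.approx(COULOMB_KCAL / (80.0 * r), rel=0.03)

    def test_non_convergence_raises(self):
        dm = centered_uniform(33, 1.0)
        with pytest.raises(ConvergenceError):
            solve_lpb(dm, [((0.0, 0.0, 0.0), 1.0)], PBOptions(tol=1e-12, max_iter=3))

    def test_charge_outside_grid_rejected(self):
        dm = centered_uniform(9, 1.0)
        with pytest.raises(ConfigurationError):
            solve_lpb(dm, [((100.0, 0.0, 0.0), 1.0)], PBOptions())


class TestTransferEnergy:
    def test_homogeneous_water_is_zero(self):
        dm = centered_uniform(25, 1.0)
        grid = transfer_energy_grid(
            dm, [], sample_origin=(-4.0, 0.0, 0.0), sample_spacing=4.0,
            sample_shape=(3, 1, 1), options=PBOptions(tol=1e-6, max_iter=2000),
        )
        assert grid.mask.all()
        # zero up to solver tolerance (self-energies are ~1e2 kcal/mol each)
        np.testing.assert_allclose(grid.values, 0.0, atol=1e-4)

    def test_membrane_pore_center_is_desolvation_penalty(self):
        """An uncharged low-dielectric slab with a wide pore still costs energy."""
        n, h = 33, 1.0
        ext = (n - 1) * h
        origin = -np.array([ext, ext, ext]) / 2.0
        vals = []
        for spacing in (1.0, 0.8):
            n_s = int(round(ext / spacing)) + 1
            o_s = -np.array([1.0, 1.0, 1.0]) * (n_s - 1) * spacing / 2.0
            dm = build_dielectric_map(
                np.zeros((0, 3)), [], origin=o_s, spacing=spacing,
                shape=(n_s, n_s, n_s), slab_half=8.0, pore_radius=10.0,
            )
            grid = transfer_energy_grid(
                dm, [], sample_origin=(0.0, 0.0, 0.0), sample_spacing=1.0,
                sample_shape=(1, 1, 1),
                options=PBOptions(tol=1e-5, max_iter=3000, probe_charge=-1.0),
            )
            vals.append(grid.values[0, 0, 0])
        assert all(v > 0 for v in vals)  # desolvation penalty, sign-stable
        # grid-refinement convergence between the two working resolutions
        assert abs(vals[0] - vals[1]) < 0.10 * abs(vals[0])

    def test_static_charge_interaction_matches_coulomb(self):
        """No dielectric contrast: dG(anion) = -k_c/(80 d) within 5%."""
        n, h = 41, 0.5
        dm = centered_uniform(n, h)
        d = 5.0
        grid = transfer_energy_grid(
            dm, [((0.0, 0.0, d), 1.0)],
            sample_origin=(0.0, 0.0, 0.0), sample_spacing=1.0,
            sample_shape=(1, 1, 1),
            options=PBOptions(tol=1e-6, max_iter=3000, probe_charge=-1.0),
        )
        expect = -COULOMB_KCAL / (80.0 * d)
        assert grid.values[0, 0, 0] == pytest.approx(expect, rel=0.05)

    def test_clashing_points_masked(self):
        dm = centered_uniform(25, 1.0)
        grid = transfer_energy_grid(
            dm, [], sample_origin=(0.0, 0.0, 0.0), sample_spacing=5.0,
            sample_shape=(2, 1, 1),
            options=PBOptions(tol=1e-5, max_iter=2000, probe_radius=2.0),
            atom_coords=np.array([[0.0, 0.0, 0.0]]), atom_radii=np.array([1.5]),
        )
        assert not grid.mask[0, 0, 0]   # inside vdW + probe radius
        assert grid.mask[1, 0, 0]


class TestFieldMap:
    def test_no_charges_zero_field(self):
        fm = average_field_map(
            [], origin=(-5.0, -5.0, -5.0), spacing=1.0, shape=(11, 11, 11)
        )
        np.testing.assert_allclose(fm.magnitude.values, 0.0)

    def test_single_charge_matches_coulomb_midrange(self):
        sigma = 1.0
        fm = average_field_map(
            [((0.0, 0.0, 0.0), 1.0)], origin=(-15.0, -15.0, -15.0),
            spacing=0.5, shape=(61, 61, 61), smoothing=sigma,
        )
        ic = 30
        for r in (3.0, 5.0, 7.0):
            i = ic + int(r / 0.5)
            val = fm.magnitude.values[i, ic, ic]
            assert val == pytest.approx(COULOMB_KCAL / r**2, rel=0.05)

    def test_field_is_negative_gradient_of_potential(self):
        fm = average_field_map(
            [((0.0, 0.0, 0.0), 1.0)], origin=(-6.0, -6.0, -6.0),
            spacing=1.0, shape=(13, 13, 13),
        )
        grad = np.gradient(fm.potential.values, 1.0)
        np.testing.assert_allclose(fm.vectors, -np.stack(grad, axis=-1), atol=1e-12)

    def test_positive_ring_attracts_anions_inward_along_axis(self):
        """At both pore mouths the field points away from the ring along z,
        so the force on an anion (-e) points toward the ring: hand Coulomb
        summation gives E_z > 0 above the ring and E_z < 0 below."""
        ring = fixed_charge_ring(8, 6.0, 0.0, 0.5)
        fm = average_field_map(
            ring, origin=(-2.0, -2.0, -12.0), spacing=1.0, shape=(5, 5, 25),
            smoothing=1.0,
        )
        above = fm.vectors[2, 2, 20, 2]   # z = +8 on the axis
        below = fm.vectors[2, 2, 4, 2]    # z = -8
        assert above > 0 and below < 0
        # independent direct Coulomb sum at z = +8
        ez = sum(
            COULOMB_KCAL * q * (8.0 - p[2]) / np.linalg.norm([p[0], p[1], p[2] - 8.0]) ** 3
            for p, q in ring
        )
        assert above == pytest.approx(ez, rel=0.05)

    def test_trajectory_frames_averaged(self):
        traj = ideal_gas_trajectory(6, 3, box=(20.0, 20.0, 20.0), seed=8)
        fm = average_field_map(
            traj, origin=(-5.0, -5.0, -5.0), spacing=2.5, shape=(5, 5, 5)
        )
        assert np.isfinite(fm.potential.values).all()

    def test_zero_frames_rejected(self):
        traj = ideal_gas_trajectory(4, 1)
        traj.positions = traj.positions[:0]
        traj.times = traj.times[:0]
        with pytest.raises(EmptyInputError):
            average_field_map(traj, origin=(0, 0, 0), spacing=1.0, shape=(3, 3, 3))
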