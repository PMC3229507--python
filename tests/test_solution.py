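"""RDFs, ion-pair classification, solvation and dipole-orientation profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_trajectory
from ionpore.errors import ConfigurationError, EmptyInputError
from ionpore.solution import (
    PairThresholds,
    RDFResult,
    classify_ion_pairs,
    dipole_orientation_profile,
    find_rdf_extrema,
    langevin,
    pairing_profile,
    rdf,
    solvation_count,
    thresholds_from_rdf,
)
from ionpore.synthetic import dipole_ensemble, ideal_gas_trajectory
from ionpore.trajectory import Trajectory, minimum_image


def two_species_trajectory(cation_pos, anion_pos, box=(30.0, 30.0, 60.0)):
    cation_pos = np.asarray(cation_pos, dtype=float)
    if cation_pos.ndim == 2:
        cation_pos = cation_pos[None]
    anion_pos = np.asarray(anion_pos, dtype=float)
    if anion_pos.ndim == 2:
        anion_pos = anion_pos[None]
    nc, na = cation_pos.shape[1], anion_pos.shape[1]
    pos = np.concatenate([cation_pos, anion_pos], axis=1)
    return Trajectory(
        times=np.arange(pos.shape[0], dtype=float),
        ids=np.arange(nc + na),
        species=np.asarray(["cation"] * nc + ["anion"] * na),
        positions=pos,
        box=np.asarray(box, dtype=float),
    )


class TestRDF:
    def test_ideal_gas_is_unity(self):
        traj = ideal_gas_trajectory(320, 150, box=(24.0, 24.0, 24.0), seed=4)
        res = rdf(traj, ("anion", "anion"), bin_width=0.5, r_max=10.0)
        beyond = res.r_centers > 1.0
        np.testing.assert_allclose(res.g[beyond], 1.0, atol=0.02)

    def test_two_fixed_particles_single_bin(self):
        d = 4.25
        traj = two_species_trajectory(
            [[0.0, 0.0, 0.0]], [[0.0, 0.0, d]], box=(20.0, 20.0, 20.0)
        )
        res = rdf(traj, ("cation", "anion"), bin_width=0.2, r_max=8.0)
        occupied = np.nonzero(res.g > 0)[0]
        assert len(occupied) == 1
        assert abs(res.r_centers[occupied[0]] - d) <= 0.1 + 1e-9

    def test_coordination_number_closed_form(self):
        """N(r) for uniform density equals (4/3) pi r^3 rho within binning."""
        traj = ideal_gas_trajectory(300, 50, box=(24.0, 24.0, 24.0), seed=6)
        res = rdf(traj, ("anion", "anion"), bin_width=0.25, r_max=10.0)
        rho = res.density
        bw = res.meta["bin_width"]
        for r_test in (4.0, 7.0, 10.0):
            i = np.searchsorted(res.r_centers, r_test) - 1
            upper_edge = res.r_centers[i] + bw / 2.0  # cumsum runs to the edge
            expect = 4.0 / 3.0 * np.pi * upper_edge**3 * rho
            assert res.coordination[i] == pytest.approx(expect, rel=0.05)

    def test_r_max_beyond_half_box_rejected(self):
        traj = ideal_gas_trajectory(10, 2, box=(20.0, 20.0, 20.0))
        with pytest.raises(ConfigurationError):
            rdf(traj, ("anion", "anion"), r_max=12.0)


class TestExtrema:
    def _curve(self, r, g):
        return RDFResult(
            r_centers=np.asarray(r), g=np.asarray(g),
            coordination=np.cumsum(g), pair=("cation", "anion"), density=0.01,
        )

    def test_constructed_peak_and_dip(self):
        r = np.arange(0.05, 8.0, 0.1)
        g = 1.0 + 1.5 * np.exp(-((r - 3.5) ** 2) / 0.18) - 0.6 * np.exp(
            -((r - 5.0) ** 2) / 0.18
        )
        ext = find_rdf_extrema(self._curve(r, g))
        assert ext.first_peak == pytest.approx(3.5, abs=0.15)
        assert ext.first_minimum == pytest.approx(5.0, abs=0.15)

    def test_monotone_curve_not_found(self):
        r = np.arange(0.05, 8.0, 0.1)
        ext = find_rdf_extrema(self._curve(r, 1.0 - np.exp(-r)))
        assert not ext.found

    def test_default_thresholds_are_the_solution_rdf_minima(self):
        # shipped defaults when no solution trajectory is supplied
        t = PairThresholds()
        assert t.cip_max == pytest.approx(3.95)
        assert t.ssip_max == pytest.approx(6.37)

    def test_thresholds_from_two_minimum_curve(self):
        r = np.arange(0.05, 10.0, 0.1)
        g = (
            1.0
            + 2.0 * np.exp(-((r - 3.0) ** 2) / 0.2)
            - 0.5 * np.exp(-((r - 4.5) ** 2) / 0.2)
            + 0.8 * np.exp(-((r - 5.8) ** 2) / 0.2)
            - 0.3 * np.exp(-((r - 7.0) ** 2) / 0.2)
        )
        t = thresholds_from_rdf(self._curve(r, g))
        assert t.cip_max == pytest.approx(4.5, abs=0.2)
        assert t.ssip_max == pytest.approx(7.0, abs=0.2)


class TestPairClassification:
    def test_threshold_labels(self):
        box = (40.0, 40.0, 40.0)
        for d, cip, ssip in ((3.0, 1, 0), (5.0, 0, 1), (7.0, 0, 0)):
            cl = classify_ion_pairs(
                np.array([[0.0, 0.0, 0.0]]), np.array([[d, 0.0, 0.0]]), box
            )
            assert cl.n_cip[0] == cip and cl.n_ssip[0] == ssip
            assert cl.paired[0] == bool(cip + ssip)

    def test_cip_boundary_inclusive(self):
        box = (40.0, 40.0, 40.0)
        cl = classify_ion_pairs(
            np.array([[0.0, 0.0, 0.0]]), np.array([[3.95, 0.0, 0.0]]), box
        )
        assert cl.n_cip[0] == 1 and cl.n_ssip[0] == 0

    def test_multiple_partners_count_paired_once(self):
        box = (40.0, 40.0, 40.0)
        cl = classify_ion_pairs(
            np.array([[0.0, 0.0, 0.0]]),
            np.array([[3.0, 0.0, 0.0], [0.0, 5.0, 0.0]]),
            box,
        )
        assert cl.n_cip[0] == 1 and cl.n_ssip[0] == 1
        assert cl.n_paired == 1

    def test_minimum_image_distances_used(self):
        box = (10.0, 10.0, 10.0)
        cl = classify_ion_pairs(
            np.array([[4.8, 0.0, 0.0]]), np.array([[-4.8, 0.0, 0.0]]), box
        )
        assert cl.n_cip[0] == 1  # 0.4 A through the periodic boundary


@settings(deadline=None, max_examples=60, derandomize=True)
@given(data=st.data())
def test_pair_classification_matches_double_loop(data):
    """Vectorized classification equals a brute-force all-pairs loop."""
    nc = data.draw(st.integers(1, 6))
    na = data.draw(st.integers(0, 6))
    box = np.array([15.0, 15.0, 15.0])
    coords = data.draw(
        st.lists(
            st.tuples(*[st.floats(-7.5, 7.5) for _ in range(3)]),
            min_size=nc + na, max_size=nc + na,
        )
    )
    coords = np.asarray(coords)
    cpos, apos = coords[:nc], coords[nc:]
    t = PairThresholds()
    cl = classify_ion_pairs(cpos, apos, box, t)
    for i in range(nc):
        n_cip = n_ssip = 0
        for j in range(na):
            d = np.linalg.norm(minimum_image(apos[j] - cpos[i], box))
            if d <= t.cip_max:
                n_cip += 1
            elif d <= t.ssip_max:
                n_ssip += 1
        assert cl.n_cip[i] == n_cip
        assert cl.n_ssip[i] == n_ssip
        assert cl.paired[i] == (n_cip + n_ssip > 0)


class TestPairingProfile:
    def test_isolated_cation_never_paired(self):
        traj = two_species_trajectory(
            np.zeros((4, 1, 3)), np.full((4, 1, 3), 14.0)
        )
        prof = pairing_profile(traj)
        assert np.all(prof.values == 0.0)

    def test_pairs_only_inside_slab(self):
        n_frames = 6
        cpos = np.zeros((n_frames, 4, 3))
        cpos[:, :, 2] = [-10.0, -5.0, 5.0, 10.0]      # cations inside the slab
        apos = cpos.copy()
        apos[:, :, 0] += 2.0                          # contact partner each
        cpos2 = np.zeros((n_frames, 2, 3))
        cpos2[:, :, 2] = [-25.0, 25.0]                # lone cations outside
        traj = two_species_trajectory(
            np.concatenate([cpos, cpos2], axis=1), apos
        )
        prof = pairing_profile(traj, bin_width=5.0)
        inside = np.abs(prof.z_centers) < 15.0
        sampled = prof.counts > 0
        assert np.all(prof.values[inside & sampled] == 1.0)
        assert np.all(prof.values[~inside & sampled] == 0.0)

    def test_profile_sums_to_whole_box_count(self):
        rng = np.random.default_rng(12)
        cpos = rng.uniform(-15.0, 15.0, size=(5, 12, 3))
        apos = rng.uniform(-15.0, 15.0, size=(5, 12, 3))
        traj = two_species_trajectory(cpos, apos)
        prof = pairing_profile(traj, bin_width=2.0)
        total_from_profile = prof.meta["paired_per_frame"].sum()
        per_frame = [
            classify_ion_pairs(cpos[f], apos[f], traj.box).n_paired
            for f in range(5)
        ]
        assert total_from_profile == pytest.approx(np.mean(per_frame))

    def test_mass_action_pairing_increases_with_concentration(self):
        fracs = []
        for c, n in ((0.1, 8), (1.0, 80)):
            traj = ideal_gas_trajectory(n, 40, box=(30.0, 30.0, 30.0), seed=21)
            half = n // 2
            traj.species[:half] = "cation"
            prof = pairing_profile(traj, bin_width=30.0)
            w = prof.counts > 0
            fracs.append((prof.values[w] * prof.counts[w]).sum() / prof.counts[w].sum())
        assert fracs[1] > fracs[0]


class TestSolvation:
    def test_absent_neighbor_species_zero(self):
        traj = two_species_trajectory(np.zeros((3, 2, 3)), np.zeros((3, 0, 3)))
        prof = solvation_count(traj, "cation", "anion", cutoff=5.0)
        assert np.all(prof.values == 0.0)

    def test_uniform_density_closed_form(self):
        n = 400
        traj = ideal_gas_trajectory(n, 30, box=(30.0, 30.0, 30.0), seed=14)
        cutoff = 6.0
        prof = solvation_count(traj, "anion", "anion", cutoff=cutoff, bin_width=30.0)
        rho = (n - 1) / 30.0**3
        expect = 4.0 / 3.0 * np.pi * cutoff**3 * rho
        w = prof.counts > 0
        mean = (prof.values[w] * prof.counts[w]).sum() / prof.counts[w].sum()
        assert mean == pytest.approx(expect, rel=0.05)

    def test_depletion_zone_localized_to_slab(self):
        rng = np.random.default_rng(3)
        n_frames = 10
        centers = np.zeros((n_frames, 7, 3))
        centers[:, :, 2] = np.linspace(-28.0, 28.0, 7)
        # neighbors fill the box except the slab |z| < 10
        nb = rng.uniform(-30.0, 30.0, size=(n_frames, 500, 3))
        nb[:, :, 2] = np.where(
            np.abs(nb[:, :, 2]) < 10.0, nb[:, :, 2] + 40.0 * np.sign(nb[:, :, 2] + 1e-9), nb[:, :, 2]
        )
        nb[:, :, 2] = (nb[:, :, 2] + 30.0) % 60.0 - 30.0
        traj = two_species_trajectory(centers, nb, box=(60.0, 60.0, 60.0))
        prof = solvation_count(traj, "cation", "anion", cutoff=4.0, bin_width=8.0)
        sampled = prof.counts > 0
        inner = sampled & (np.abs(prof.z_centers) < 6.0)
        outer = sampled & (np.abs(prof.z_centers) > 20.0)
        assert prof.values[inner].mean() < 0.2 * prof.values[outer].mean()


class TestDipoles:
    def test_isotropic_mean_near_zero(self):
        traj = dipole_ensemble(500, 40, alignment=0.0, seed=17)
        prof = dipole_orientation_profile(traj, bin_width=60.0)
        n = 500 * 40
        w = prof.counts > 0
        assert abs(prof.mean_cos[w][0]) < 3.0 / np.sqrt(n) + 0.01

    def test_fully_aligned_mean_is_one(self):
        traj = dipole_ensemble(20, 5, alignment=0.0, seed=1)
        traj.dipoles[:] = [0.0, 0.0, 1.0]
        prof = dipole_orientation_profile(traj, bin_width=60.0)
        w = prof.counts > 0
        np.testing.assert_allclose(prof.mean_cos[w], 1.0)

    def test_langevin_mean_in_uniform_field(self):
        a = 1.5
        traj = dipole_ensemble(800, 60, alignment=a, seed=23)
        prof = dipole_orientation_profile(traj, bin_width=60.0)
        w = prof.counts > 0
        n = 800 * 60
        assert prof.mean_cos[w][0] == pytest.approx(
            langevin(a), abs=3.0 / np.sqrt(n) + 0.01
        )

    def test_histograms_row_normalized(self):
        traj = dipole_ensemble(100, 10, alignment=1.0, seed=2)
        prof = dipole_orientation_profile(traj, bin_width=10.0)
        w = prof.counts > 0
        np.testing.assert_allclose(prof.histograms[w].sum(axis=1), 1.0)

    def test_missing_dipoles_rejected(self):
        traj = ideal_gas_trajectory(5, 2)
        with pytest.raises(EmptyInputError):
            dipole_orientation_profile(traj)
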