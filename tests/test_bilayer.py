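"""Bilayer structural observables: composition, COM, order, profiles, thickness."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memprobe import bilayer_analysis as ba
from memprobe import synthetic_data as syn
from memprobe.errors import CompositionError, InputValidationError
from conftest import chain_frame, chain_topology, single_frame_traj

MAGIC_ANGLE = math.degrees(math.acos(1.0 / math.sqrt(3.0)))  # 54.7356 deg


class TestComposeSystem:
    def test_anionic_solute_gets_counterions(self):
        comp = ba.compose_system(140, 5, "nonanoic_acid", -1)
        assert comp.n_herbicide == 28
        assert comp.n_counterions == 28

    def test_neutral_solute_needs_no_ions(self):
        comp = ba.compose_system(140, 5, "sorgoleone", 0)
        assert comp.n_herbicide == 28
        assert comp.n_counterions == 0

    def test_non_integral_count_rejected(self):
        with pytest.raises(CompositionError):
            ba.compose_system(142, 5, "sorgoleone", 0)

    def test_odd_lipid_count_rejected(self):
        with pytest.raises(CompositionError):
            ba.compose_system(141, 5, "sorgoleone", 0)


class TestCenterOfMass:
    def make_two_atom_frame(self, z1, z2):
        return chain_frame([np.array([[1.0, 1.0, z1]]), np.array([[2.0, 2.0, z2]])])

    def test_equal_masses(self):
        frame = self.make_two_atom_frame(1.0, 3.0)
        sel = np.ones(frame.n_atoms, dtype=bool)
        assert ba.bilayer_center_of_mass(frame, sel) == pytest.approx(2.0)

    def test_mass_weighting(self):
        frame = self.make_two_atom_frame(0.0, 4.0)
        sel = np.ones(2, dtype=bool)
        z = ba.bilayer_center_of_mass(frame, sel, masses=np.array([1.0, 3.0]))
        assert z == pytest.approx(3.0)

    def test_symmetric_bilayer_centered(self):
        traj, topo = syn.gen_bilayer_frames(syn.BilayerSpec(
            n_lipids=20, chain_length=6, order_level=1.0, n_frames=1, box_Lz_nm=12.0))
        frame = traj.frames[0]
        sel = np.ones(frame.n_atoms, dtype=bool)
        assert ba.bilayer_center_of_mass(frame, sel) == pytest.approx(6.0, abs=1e-6)

    def test_empty_selection_rejected(self):
        frame = self.make_two_atom_frame(0.0, 1.0)
        with pytest.raises(InputValidationError):
            ba.bilayer_center_of_mass(frame, np.zeros(2, dtype=bool))


class TestZProfile:
    def test_p_planes_at_construction_distance(self, p_plane_frame):
        frame, topo = p_plane_frame
        zp = ba.z_profile(single_frame_traj(frame), topo, ["P"])
        # P atoms sit at +/-1.9 nm from the bilayer COM by construction
        assert zp.mean_abs_z_nm[0] == pytest.approx(1.9, abs=1e-9)

    def test_generator_polar_depth_recovered(self):
        spec = syn.BilayerSpec(seed=21, n_lipids=40, chain_length=8,
                               order_level=0.8, n_frames=100,
                               lipid_to_herbicide_ratio=5,
                               herbicide_polar_depth_nm=1.2, noise_sd=0.05,
                               head_separation_nm=3.8)
        traj, topo = syn.gen_bilayer_frames(spec)
        zp = ba.z_profile(traj, topo, ["polar"])
        assert zp.mean_abs_z_nm[0] == pytest.approx(1.2, abs=0.01)

    def test_rewrap_invariance(self):
        spec = syn.BilayerSpec(seed=4, n_lipids=20, chain_length=6,
                               order_level=0.9, n_frames=2, head_separation_nm=3.8)
        traj, topo = syn.gen_bilayer_frames(spec)
        zp_ref = ba.z_profile(traj, topo, ["P", "glycerol"])
        wrapped_frames = []
        for f in traj.frames:
            coords = f.coords % f.box  # wrap every atom into the box
            wrapped_frames.append(dataclasses.replace(f, coords=coords))
        zp_wrapped = ba.z_profile(ba.Trajectory(frames=tuple(wrapped_frames)), topo,
                                  ["P", "glycerol"])
        assert np.allclose(zp_ref.mean_abs_z_nm, zp_wrapped.mean_abs_z_nm, atol=1e-9)


class TestOrderParameters:
    def test_all_trans_along_z_is_half(self):
        chains = [syn.make_all_trans_chain(10) + np.array([x, 2.0, 2.0])
                  for x in (1.0, 3.0)]
        traj = single_frame_traj(chain_frame(chains))
        prof = ba.order_parameters(traj, chain_topology(10), "palmitoyl")
        assert prof.carbon_indices == tuple(range(2, 10))
        assert np.allclose(prof.values, 0.5, atol=1e-12)

    def test_magic_angle_averages_to_zero(self):
        rng = np.random.default_rng(42)
        theta = math.radians(MAGIC_ANGLE)
        chains = [syn.make_all_trans_chain(8, axis_theta=theta,
                                           axis_phi=rng.uniform(0, 2 * math.pi),
                                           zigzag_phi=rng.uniform(0, 2 * math.pi))
                  + np.array([5.0, 5.0, 5.0])
                  for _ in range(10_000)]
        traj = single_frame_traj(chain_frame(chains, box=(1e3, 1e3, 1e3)))
        prof = ba.order_parameters(traj, chain_topology(8), "palmitoyl")
        assert abs(np.mean(prof.values)) < 0.01

    def test_isotropic_orientations_average_to_zero(self):
        rng = np.random.default_rng(7)
        chains = []
        for _ in range(10_000):
            theta = math.acos(rng.uniform(-1.0, 1.0))
            chains.append(syn.make_all_trans_chain(
                8, axis_theta=theta, axis_phi=rng.uniform(0, 2 * math.pi),
                zigzag_phi=rng.uniform(0, 2 * math.pi)) + np.array([5.0, 5.0, 5.0]))
        traj = single_frame_traj(chain_frame(chains, box=(1e3, 1e3, 1e3)))
        prof = ba.order_parameters(traj, chain_topology(8), "palmitoyl")
        assert abs(np.mean(prof.values)) < 0.01

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_magnitude_bounded_for_random_geometry(self, seed):
        rng = np.random.default_rng(seed)
        chain = rng.uniform(0.0, 5.0, size=(6, 3))
        traj = single_frame_traj(chain_frame([chain], box=(50, 50, 50)))
        try:
            prof = ba.order_parameters(traj, chain_topology(6), "palmitoyl")
        except InputValidationError:
            return  # collinear backbone triplet: no defined C-H frame
        assert all(abs(v) <= 0.5 + 1e-9 for v in prof.values)

    def test_monotone_in_generator_order_level(self):
        means = []
        for s in (0.0, 0.25, 0.5, 0.75, 1.0):
            traj, topo = syn.gen_bilayer_frames(syn.BilayerSpec(
                seed=13, n_lipids=60, chain_length=8, order_level=s, n_frames=5))
            prof = ba.order_parameters(traj, topo, "palmitoyl")
            means.append(float(np.mean(prof.values)))
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_rigid_translation_and_z_rotation_invariance(self):
        spec = syn.BilayerSpec(seed=3, n_lipids=20, chain_length=8,
                               order_level=0.7, n_frames=2)
        traj, topo = syn.gen_bilayer_frames(spec)
        ref = ba.order_parameters(traj, topo, "palmitoyl")
        ang = 0.77
        rot = np.array([[math.cos(ang), -math.sin(ang), 0],
                        [math.sin(ang), math.cos(ang), 0], [0, 0, 1.0]])
        moved = []
        for f in traj.frames:
            coords = f.coords @ rot.T + np.array([1.3, -0.4, 2.2])
            moved.append(dataclasses.replace(f, coords=coords, box=f.box * 10))
        prof2 = ba.order_parameters(ba.Trajectory(frames=tuple(moved)), topo, "palmitoyl")
        assert np.allclose(ref.values, prof2.values, atol=1e-9)

    def test_chain_too_short_rejected(self):
        chains = [np.array([[0.0, 0.0, 0.0], [0.1, 0.0, 0.1]])]
        traj = single_frame_traj(chain_frame(chains))
        with pytest.raises(InputValidationError):
            ba.order_parameters(traj, chain_topology(2), "palmitoyl")


class TestThickness:
    def test_p_plane_construction(self, p_plane_frame):
        frame, topo = p_plane_frame
        thickness, se = ba.bilayer_thickness(single_frame_traj(frame), topo)
        assert thickness == pytest.approx(3.8, abs=1e-9)
        assert se == 0.0

    def test_ordered_thicker_than_disordered(self):
        vals = {}
        for s in (0.1, 0.9):
            traj, topo = syn.gen_bilayer_frames(syn.BilayerSpec(
                seed=9, n_lipids=40, chain_length=10, order_level=s, n_frames=3))
            vals[s], _ = ba.bilayer_thickness(traj, topo)
        assert vals[0.9] > vals[0.1]

    def test_single_leaflet_rejected(self, p_plane_frame):
        frame, topo = p_plane_frame
        upper = frame.coords[:, 2] > 5.0
        one_leaflet = dataclasses.replace(
            frame,
            coords=frame.coords[upper],
            atom_names=frame.atom_names[upper],
            species=frame.species[upper],
            mol_ids=frame.mol_ids[upper],
        )
        with pytest.raises(InputValidationError):
            ba.bilayer_thickness(single_frame_traj(one_leaflet), topo)


class TestLeafletMirrorSymmetry:
    def test_observables_invariant_under_midplane_mirror(self):
        spec = syn.BilayerSpec(seed=6, n_lipids=20, chain_length=8,
                               order_level=0.8, n_frames=2, head_separation_nm=3.6)
        traj, topo = syn.gen_bilayer_frames(spec)
        mirrored = []
        for f in traj.frames:
            coords = f.coords.copy()
            coords[:, 2] = f.box[2] - coords[:, 2]
            mirrored.append(dataclasses.replace(f, coords=coords))
        mtraj = ba.Trajectory(frames=tuple(mirrored))
        t1, _ = ba.bilayer_thickness(traj, topo)
        t2, _ = ba.bilayer_thickness(mtraj, topo)
        assert t1 == pytest.approx(t2, abs=1e-9)
        p1 = ba.order_parameters(traj, topo, "palmitoyl")
        p2 = ba.order_parameters(mtraj, topo, "palmitoyl")
        assert np.allclose(p1.values, p2.values, atol=1e-9)
        z1 = ba.z_profile(traj, topo, ["P"])
        z2 = ba.z_profile(mtraj, topo, ["P"])
        assert np.allclose(z1.mean_abs_z_nm, z2.mean_abs_z_nm, atol=1e-9)


class TestEquilibrationSplit:
    def make_traj(self, n, dt=1.0, t0=1.0):
        frames = [chain_frame([np.zeros((1, 3))], time_ps=t0 + i * dt) for i in range(n)]
        return ba.Trajectory(frames=tuple(frames))

    def test_production_window(self):
        traj = self.make_traj(250)  # times 1..250
        out = ba.equilibration_split(traj, 0.6)
        assert len(out.frames) == 100
        assert out.frames[0].time_ps == pytest.approx(151.0)

    def test_zero_fraction_is_identity(self):
        traj = self.make_traj(10)
        out = ba.equilibration_split(traj, 0.0)
        assert len(out.frames) == 10

    def test_full_fraction_rejected(self):
        with pytest.raises(InputValidationError):
            ba.equilibration_split(self.make_traj(10), 1.0)
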