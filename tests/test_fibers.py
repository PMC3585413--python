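"""Stress-fiber nucleation, strain alignment, contraction and forces."""

import numpy as np
import pytest

from cellmech import fibers as F
from cellmech.fibers import (MOTOR, DEPOLYMERIZING, EXPIRED, POLYMERIZING,
                             SFParams, StressFiber)
from cellmech.mesh import TriMesh, build_sphere_mesh, update_differentials

P = SFParams()


class TestNuclearNucleation:
    def test_nearest_node_by_symmetry(self):
        nucleus = build_sphere_mesh(1000.0, 42)
        node_pos = np.array([5000.0, 0.0, 0.0])
        sf = F.nucleate_nuclear_sf(7, node_pos, nucleus)
        # the +x pole of the nucleus is the nearest node
        assert nucleus.positions[sf.end_b, 0] == pytest.approx(
            nucleus.positions[:, 0].max(), abs=1e-6)

    def test_compartment_rounding(self):
        nucleus = build_sphere_mesh(10.0, 12)
        # distances ~4.0 µm and ~0.3 µm from the nucleus surface
        sf = F.nucleate_nuclear_sf(0, np.array([4010.0, 0.0, 0.0]), nucleus)
        assert sf.N_sf == 5                     # round(4000/800)
        sf2 = F.nucleate_nuclear_sf(0, np.array([310.0, 0.0, 0.0]), nucleus)
        assert sf2.N_sf == 1                    # clamp at 1


class TestSurfaceStrain:
    def test_zero_at_reference(self, flat_patch):
        t, vals, dirs = F.surface_strain(flat_patch)
        assert np.abs(vals).max() < 1e-12

    def test_uniaxial_stretch(self, flat_patch):
        m = flat_patch
        m.positions = m.positions * np.array([1.1, 1.0, 1.0])
        update_differentials(m)
        _, vals, dirs = F.surface_strain(m)
        # Green strain (1.1² − 1)/2 = 0.105 along x, 0 along y
        assert vals[:, 1] == pytest.approx(0.105, abs=1e-9)
        assert vals[:, 0] == pytest.approx(0.0, abs=1e-9)
        # lower principal direction is the unstretched (y) axis
        assert np.abs(dirs[:, 0, 1]) == pytest.approx(1.0, abs=1e-6)

    def test_objectivity_under_rotation(self, flat_patch):
        m = flat_patch
        th = 0.9
        R = np.array([[np.cos(th), 0, np.sin(th)], [0, 1, 0],
                      [-np.sin(th), 0, np.cos(th)]])
        m.positions = m.ref_positions @ R.T
        update_differentials(m)
        _, vals, _ = F.surface_strain(m)
        assert np.abs(vals).max() < 1e-10


class TestVentralNucleation:
    def test_no_candidates(self):
        pos = np.zeros((3, 3))
        assert F.nucleate_ventral_sf(0, np.array([1.0, 0, 0]),
                                     np.array([0]), pos) is None

    def test_aligned_partner_at_8um(self):
        pos = np.array([[0.0, 0, 0], [8000.0, 0, 0], [0.0, 8000.0, 0]])
        sf = F.nucleate_ventral_sf(0, np.array([1.0, 0, 0]),
                                   np.array([0, 1, 2]), pos)
        assert sf is not None and sf.end_b == 1
        assert sf.N_sf == 10                    # round(8000/800)

    def test_orthogonal_candidate_rejected(self):
        pos = np.array([[0.0, 0, 0], [0.0, 8000.0, 0]])
        sf = F.nucleate_ventral_sf(0, np.array([1.0, 0, 0]),
                                   np.array([0, 1]), pos)
        assert sf is None

    def test_length_window(self):
        pos = np.array([[0.0, 0, 0], [500.0, 0, 0], [60_000.0, 0, 0]])
        sf = F.nucleate_ventral_sf(0, np.array([1.0, 0, 0]),
                                   np.array([0, 1, 2]), pos)
        assert sf is None                       # too short and too long


class TestStiffnessAndHill:
    def test_unit_stiffness_at_800(self):
        # 0.23 pN/nm² × π·250² nm² / 800 nm ≈ 56.45 pN/nm
        assert F.sf_unit_stiffness(800.0, P) == pytest.approx(56.45, abs=0.01)
        assert F.sf_unit_stiffness(400.0, P) == pytest.approx(
            2 * F.sf_unit_stiffness(800.0, P), rel=1e-12)

    def test_cross_section_from_radius(self):
        assert P.A_SF / 1e6 == pytest.approx(0.196, abs=5e-4)

    def test_hill_endpoints_and_monotonicity(self):
        assert F.hill_velocity(0.0, P) == pytest.approx(10.0)
        assert F.hill_velocity(P.F_m, P) == 0.0
        assert F.hill_velocity(2 * P.F_m, P) == 0.0   # clamped, no lengthening
        forces = np.linspace(0.0, P.F_m, 50)
        v = F.hill_velocity(forces, P)
        assert np.all(np.diff(v) < 0)


class TestContraction:
    def test_unloaded_rate(self):
        # both ends slide at 10 nm/s: ΔL = 20 nm over 1 s
        assert F.advance_contraction(800.0, 0.0, 1.0, P) == pytest.approx(780.0)

    def test_floor_reached_in_16s_unloaded(self):
        L, t, dt = 800.0, 0.0, 0.01
        while L > P.floor_length + 1e-9:
            L = F.advance_contraction(L, 0.0, dt, P)
            t += dt
        assert t == pytest.approx(16.0, abs=2 * dt)
        assert L == pytest.approx(0.6 * 800.0)

    def test_stalled_fiber_does_not_contract(self):
        assert F.advance_contraction(700.0, P.F_m, 1.0, P) == 700.0


class TestSFForces:
    def test_zero_at_rest_length(self):
        fa, fb = F.sf_forces(5, 600.0, np.zeros(3),
                             np.array([3000.0, 0, 0]), P)
        assert np.allclose(fa, 0.0) and np.allclose(fb, 0.0)

    def test_newton_pair_and_collinearity(self, rng):
        a, b = rng.normal(size=3) * 1e3, rng.normal(size=3) * 1e3 + 5e3
        fa, fb = F.sf_forces(4, 700.0, a, b, P)
        assert np.allclose(fa, -fb)
        axis = (b - a) / np.linalg.norm(b - a)
        assert np.abs(np.cross(fa, axis)).max() < 1e-9 * np.linalg.norm(fa)

    def test_tension_magnitude_example(self):
        # N_sf=5, L_a0=480: k'_unit ≈ 94.08 pN/nm, chain K = k'/5;
        # d = 3000, rest = 2400 → tension ≈ (94.08/5)·600 ≈ 1.129e4 pN
        fa, _ = F.sf_forces(5, 480.0, np.zeros(3),
                            np.array([3000.0, 0, 0]), P)
        assert np.linalg.norm(fa) == pytest.approx(1.129e4, rel=1e-3)

    def test_compression_transmits_nothing(self):
        fa, fb = F.sf_forces(5, 600.0, np.zeros(3),
                             np.array([2000.0, 0, 0]), P)
        assert np.allclose(fa, 0.0)

    def test_degenerate_fiber_raises(self):
        with pytest.raises(ValueError):
            F.sf_forces(1, 800.0, np.zeros(3), np.zeros(3), P)


class TestLifecycle:
    def _run_motor(self, load=0.0, dt=0.01):
        sf = StressFiber("nuclear", 0, 0, 1, phase=MOTOR)
        t = 0.0
        while sf.phase == MOTOR and t < 1000.0:
            sf.L_a0 = F.advance_contraction(sf.L_a0, load, dt, P)
            F.update_phase(sf, dt, fa_alive=True, connected=True, params=P)
            t += dt
        return sf, t

    def test_polymerization_gate(self):
        sf = StressFiber("nuclear", 0, 0, 1)
        F.update_phase(sf, P.t_poly + 1.0, fa_alive=True, connected=False,
                       params=P)
        assert sf.phase == POLYMERIZING       # not connected yet
        F.update_phase(sf, P.t_poly + 1.0, fa_alive=True, connected=True,
                       params=P)
        assert sf.phase == MOTOR

    def test_unloaded_motor_phase_is_16s(self):
        sf, t = self._run_motor(load=0.0)
        assert sf.phase == DEPOLYMERIZING
        assert sf.motor_duration == pytest.approx(16.0, abs=0.03)

    def test_loaded_motor_phase_longer(self):
        _, t_unloaded = self._run_motor(0.0)
        _, t_loaded = self._run_motor(0.6 * P.F_m)
        assert t_loaded > t_unloaded

    def test_fa_loss_terminates_motor(self):
        sf = StressFiber("nuclear", 0, 0, 1, phase=MOTOR)
        F.update_phase(sf, 0.01, fa_alive=False, connected=True, params=P)
        assert sf.phase == DEPOLYMERIZING
        assert sf.motor_duration == pytest.approx(0.01)

    def test_depolymerization_expiry_and_clock_sum(self):
        sf = StressFiber("nuclear", 0, 0, 1)
        dt, total = 0.1, 0.0
        while sf.phase != EXPIRED and total < 400.0:
            if sf.phase == MOTOR:
                sf.L_a0 = F.advance_contraction(sf.L_a0, 0.0, dt, P)
            F.update_phase(sf, dt, fa_alive=True, connected=True, params=P)
            total += dt
        # polymerization (180) + motor (16) + depolymerization (1)
        assert total == pytest.approx(180.0 + 16.0 + 1.0, abs=0.5)
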