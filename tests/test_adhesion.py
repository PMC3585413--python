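"""Bond kinetics (Bell model), Monte Carlo updates and FA forces."""

import numpy as np
import pytest

from cellmech.adhesion import (AdhesionParams, FAState, bell_rate,
                               binding_probability, focal_adhesion_force,
                               rupture_probability, update_bonds)
from cellmech.substrate import build_planar_field

P = AdhesionParams()


class TestRates:
    def test_binding_probability_values(self):
        assert binding_probability(0, 1.0, 0.01) == 0.0
        assert binding_probability(100, 1.0, 0.01) == pytest.approx(
            1 - np.exp(-1.0), rel=1e-12)
        assert binding_probability(100, 1.0, 1e6) == pytest.approx(1.0)

    def test_bell_rate_unstressed_and_unit_exponent(self):
        assert bell_rate(0.0, P) == pytest.approx(1.0, abs=0)
        f_unit = P.kBT / P.x_b                    # force giving exponent 1
        assert bell_rate(f_unit, P) == pytest.approx(np.e, rel=1e-12)
        # k_B·310 K = 4.2812 pN·nm, so F = 214.06 pN gives exponent 1.0000
        assert 214.06 * P.x_b / P.kBT == pytest.approx(1.0, abs=1e-3)

    def test_bell_log_linearity(self):
        forces = np.linspace(0.0, 400.0, 9)
        logs = np.log(bell_rate(forces, P))
        slope = np.polyfit(forces, logs, 1)[0]
        assert slope == pytest.approx(P.x_b / P.kBT, rel=1e-9)

    def test_rupture_probability(self):
        assert rupture_probability(0.0, 0.01) == 0.0
        assert rupture_probability(1.0, 0.01) == pytest.approx(
            1 - np.exp(-0.01), rel=1e-12)
        k = np.array([0.5, 1.0, 2.0, 4.0])
        assert np.all(np.diff(rupture_probability(k, 0.01)) > 0)


class TestFAForce:
    def _fa(self, n_b, root):
        fa = FAState(1, 300)
        fa.n_b[0] = n_b
        fa.root[0] = root
        fa.tri[0] = 0
        return fa

    def test_no_bonds_no_force(self):
        f = focal_adhesion_force(np.zeros((1, 3)), self._fa(0, np.zeros(3)))
        assert np.allclose(f, 0.0)

    def test_equilibrium_length_no_force(self):
        fa = self._fa(5, np.array([0.0, 0.0, 0.0]))
        f = focal_adhesion_force(np.array([[0.0, 0.0, 30.0]]), fa)
        assert np.allclose(f, 0.0, atol=1e-12)

    def test_stretched_bond_cluster(self):
        # 10 bonds × 1 pN/nm × (35 − 30) nm = 50 pN toward the root
        fa = self._fa(10, np.array([0.0, 0.0, 0.0]))
        f = focal_adhesion_force(np.array([[0.0, 0.0, 35.0]]), fa)
        assert f[0] == pytest.approx([0.0, 0.0, -50.0], abs=1e-9)

    def test_compression_transmits_nothing(self):
        fa = self._fa(10, np.array([0.0, 0.0, 0.0]))
        f = focal_adhesion_force(np.array([[0.0, 0.0, 12.0]]), fa)
        assert np.allclose(f, 0.0)


class _SeqRng:
    """Deterministic stand-in returning preset values per draw call.

    update_bonds draws once for binding and once for rupture; 0.0 forces
    the event, 1.0 suppresses it.
    """

    def __init__(self, *draws):
        self.draws = list(draws)

    def random(self, n):
        v = self.draws.pop(0) if self.draws else 1.0
        return np.full(n, v)


def _projection(field, n, z=100.0):
    pos = np.zeros((n, 3))
    pos[:, 2] = z
    pos[:, 0] = np.arange(n) * 1500.0       # separate triangles
    nrm = np.tile([0.0, 0.0, -1.0], (n, 1))
    from cellmech.substrate import project_node

    return pos, project_node(pos, nrm, field)


class TestUpdateBonds:
    def test_forced_draw_binds_exactly_once(self):
        field = build_planar_field(20.0, 1140.0)
        fa = FAState(1, 300)
        pos, (tri, h_p, x_L, ok) = _projection(field, 1)
        update_bonds(fa, tri, x_L, ok, np.zeros(1), 0.01,
                     _SeqRng(0.0, 1.0), field)
        assert fa.n_b[0] == 1
        assert fa.tri[0] == tri[0]
        assert np.allclose(fa.root[0], x_L[0])
        assert field.bound[tri[0]] == 1

    def test_ineligible_node_unchanged(self):
        field = build_planar_field(20.0, 1140.0)
        fa = FAState(1, 300)
        eligible = np.array([False])
        update_bonds(fa, np.array([0]), np.zeros((1, 3)), eligible,
                     np.zeros(1), 0.01, _SeqRng(0.0, 0.0), field)
        assert fa.n_b[0] == 0 and fa.tri[0] == -1

    def test_rupture_returns_ligand_and_dissolves(self):
        field = build_planar_field(20.0, 1140.0)
        fa = FAState(1, 300)
        pos, (tri, h_p, x_L, ok) = _projection(field, 1)
        update_bonds(fa, tri, x_L, ok, np.zeros(1), 0.01,
                     _SeqRng(0.0, 1.0), field)
        assert fa.n_b[0] == 1
        # forced rupture: draw 0 < P_r, and binding blocked (eligible False)
        update_bonds(fa, tri, x_L, np.array([False]), np.zeros(1), 0.01,
                     _SeqRng(0.0, 0.0), field)
        assert fa.n_b[0] == 0
        assert fa.tri[0] == -1 and np.isnan(fa.root[0]).all()
        assert field.conservation_ok() and field.bound.sum() == 0

    def test_binding_frequency_matches_binomial(self, rng):
        """1e4 single-step trials vs the binomial oracle (±3 SE)."""
        n = 10_000
        field = build_planar_field(400.0, 150.0)   # 36 free ligands/triangle
        fa = FAState(n, 300)
        pos = np.zeros((n, 3))
        pos[:, 2] = 100.0
        side = 100
        pos[:, 0] = (np.arange(n) % side) * 1800.0 - 90e3
        pos[:, 1] = (np.arange(n) // side) * 1800.0 - 90e3
        nrm = np.tile([0.0, 0.0, -1.0], (n, 1))
        from cellmech.substrate import project_node

        tri, h_p, x_L, ok = project_node(pos, nrm, field)
        assert ok.all()
        p_b = 1 - np.exp(-36 * 1.0 * 0.01)
        update_bonds(fa, tri, x_L, ok, np.zeros(n), 0.01, rng, field)
        mean = fa.n_b.mean()
        se = np.sqrt(p_b * (1 - p_b) / n)
        assert abs(mean - p_b) < 3 * se

    def test_budget_never_exceeded(self, rng):
        field = build_planar_field(10.0, 1140.0)
        fa = FAState(1, 3)                       # tiny receptor budget
        pos, (tri, h_p, x_L, ok) = _projection(field, 1)
        for _ in range(200):
            f = focal_adhesion_force(pos, fa)
            update_bonds(fa, tri, x_L, ok, np.linalg.norm(f, axis=1),
                         0.01, _SeqRng(0.0, 1.0), field)
            assert 0 <= fa.n_b[0] <= 3
        assert field.conservation_ok()


class TestFALifetimeMasterEquation:
    def test_mean_lifetime_matches_birth_death_chain(self, rng):
        """Monte Carlo FA survival vs the exact absorption time of the
        corresponding discrete birth–death chain (unstressed bonds)."""
        dt, kf, free0, cap = 0.05, 0.2, 8, 6
        p_r = 1 - np.exp(-1.0 * dt)             # k_off0 = 1, F = 0

        def p_b(n):                              # shared ligand pool shrinks
            avail = free0 - n
            if n >= cap or avail <= 0:
                return 0.0
            return 1 - np.exp(-kf * avail * dt)

        # exact chain: from state n, bind then rupture; solve the expected
        # absorption time into n = 0 starting from n = 1
        idx = {n: n - 1 for n in range(1, cap + 1)}
        A = np.zeros((cap, cap))
        b = np.ones(cap) * dt
        for n in range(1, cap + 1):
            A[idx[n], idx[n]] = 1.0
            for up, pu in ((n + 1, p_b(n)), (n, 1 - p_b(n))):
                if pu == 0.0:
                    continue
                for down, pd in ((up - 1, p_r), (up, 1 - p_r)):
                    p = pu * pd
                    if down >= 1:
                        A[idx[n], idx[down]] -= p
        expected = np.linalg.solve(A, b)[idx[1]]

        # simulate the same chain through update_bonds
        params = AdhesionParams(k_f=kf)
        trials, lifetimes = 500, []
        field = build_planar_field(5.0, free0 / 0.24356964481437335)
        assert field.initial[0] == free0
        for _ in range(trials):
            fa = FAState(1, cap)
            fa.n_b[0] = 1
            fa.tri[0] = 0
            fa.root[0] = 0.0
            field.free[:] = field.initial
            field.bound[:] = 0
            field.take_ligand(0)
            t = 0.0
            while fa.n_b[0] > 0 and t < 3000 * dt:
                update_bonds(fa, np.array([0]), np.zeros((1, 3)),
                             np.array([True]), np.zeros(1), dt, rng, field,
                             params)
                t += dt
            lifetimes.append(t)
        mean = np.mean(lifetimes)
        se = np.std(lifetimes, ddof=1) / np.sqrt(trials)
        assert abs(mean - expected) < max(4 * se, 0.1 * expected)
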