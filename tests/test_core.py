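"""Order-tensor field operations: free energy, molecular field,
co-rotation, polarity and the explicit evolution step."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from active2d import (ModelParams, NematicField, PolarityField,
                      assemble_stress, assign_polarity, beris_edwards_step,
                      corotation, decompose, elastic_energy_density,
                      molecular_field)
from active2d.core import initial_polarity

Q_MIN_BULK = 1.0 / np.sqrt(2.0)  # order magnitude minimising the bulk term


def uniform_field(L, Qxx, Qxy):
    return NematicField(np.full((L, L), float(Qxx)),
                        np.full((L, L), float(Qxy)))


class TestDecompose:
    @pytest.mark.parametrize("Qxx,Qxy,q,theta", [
        (1.0, 0.0, 1.0, 0.0),
        (0.0, 1.0, 1.0, np.pi / 4),
    ])
    def test_known_states(self, Qxx, Qxy, q, theta):
        qf, tf = decompose(uniform_field(8, Qxx, Qxy))
        assert np.allclose(qf, q) and np.allclose(tf, theta)

    def test_round_trip_random(self, random_Q):
        q, theta = decompose(random_Q)
        assert np.abs(q * np.cos(2 * theta) - random_Q.Qxx).max() < 1e-12
        assert np.abs(q * np.sin(2 * theta) - random_Q.Qxy).max() < 1e-12

    @given(qxx=st.floats(-2, 2), qxy=st.floats(-2, 2))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_property(self, qxx, qxy):
        q, theta = decompose(uniform_field(8, qxx, qxy))
        assert abs(q[0, 0] * np.cos(2 * theta[0, 0]) - qxx) < 1e-12
        assert abs(q[0, 0] * np.sin(2 * theta[0, 0]) - qxy) < 1e-12

    def test_zero_order_convention(self):
        q, theta = decompose(uniform_field(8, 0.0, 0.0))
        assert np.all(q == 0.0) and np.all(theta == 0.0)


class TestElasticEnergy:
    def test_uniform_state_has_zero_energy(self):
        E = elastic_energy_density(uniform_field(16, 0.4, -0.2), K=0.05)
        assert np.all(E == 0.0)

    def test_plane_wave_matches_continuum(self):
        # Qxx = eps cos(kx): average E = K eps^2 k_eff^2 / 2 with the
        # central-difference wavenumber k_eff = sin(k)
        L, eps, K = 64, 0.01, 0.05
        k = 2 * np.pi * 4 / L
        x = np.arange(L)
        Q = NematicField(eps * np.cos(k * x)[:, None] * np.ones(L),
                         np.zeros((L, L)))
        E = elastic_energy_density(Q, K)
        k_eff = np.sin(k)
        assert np.isclose(E.mean(), K * eps ** 2 * k_eff ** 2 / 2,
                          rtol=1e-10)

    def test_matches_brute_force_gradient_sum(self, random_Q):
        K = 0.05
        E = elastic_energy_density(random_Q, K)
        # brute force: sum over all four tensor components and both
        # derivative directions
        comps = [random_Q.Qxx, random_Q.Qxy, random_Q.Qxy, -random_Q.Qxx]
        acc = np.zeros_like(random_Q.Qxx)
        for f in comps:
            for ax in (0, 1):
                d = (np.roll(f, -1, ax) - np.roll(f, 1, ax)) / 2
                acc += d ** 2
        assert np.abs(E - K / 2 * acc).max() < 1e-14

    def test_rotating_lattice_by_90_degrees_commutes(self, random_Q):
        # rotating the director by 90 deg maps (Qxx, Qxy) -> -(Qxx, Qxy)
        # and the lattice rotation permutes sites
        K = 0.05
        E = elastic_energy_density(random_Q, K)
        rot = NematicField(-np.rot90(random_Q.Qxx), -np.rot90(random_Q.Qxy))
        E_rot = elastic_energy_density(rot, K)
        assert np.abs(np.rot90(E) - E_rot).max() < 1e-14


class TestMolecularField:
    def test_bulk_minimum_is_stationary(self):
        H = molecular_field(uniform_field(8, Q_MIN_BULK, 0.0), K=0.05, A=0.1)
        assert np.abs(H.Qxx).max() < 1e-14 and np.abs(H.Qxy).max() < 1e-14

    def test_overordered_state_relaxes_down(self):
        # q = 1 gives Q:Q = 2, so Hxx = 4A(1-2)*1 = -4A
        H = molecular_field(uniform_field(8, 1.0, 0.0), K=0.05, A=0.1)
        assert np.allclose(H.Qxx, -0.4) and np.allclose(H.Qxy, 0.0)

    def test_plane_wave_discrete_laplacian_eigenvalue(self):
        L, eps, K = 64, 1e-3, 0.05
        k = 2 * np.pi * 3 / L
        x = np.arange(L)
        Q = NematicField(eps * np.cos(k * x)[:, None] * np.ones(L),
                         np.zeros((L, L)))
        H = molecular_field(Q, K=K, A=0.0)
        k_eff_sq = 2.0 * (1.0 - np.cos(k))
        assert np.abs(H.Qxx + K * k_eff_sq * Q.Qxx).max() < 1e-15


class TestCorotation:
    def test_uniform_flow_gives_zero(self, random_Q):
        L = random_Q.shape[0]
        S = corotation(random_Q, np.full((L, L), 0.3),
                       np.full((L, L), -0.1), lam=0.2)
        assert np.abs(S.Qxx).max() < 1e-15 and np.abs(S.Qxy).max() < 1e-15

    def test_simple_shear_of_isotropic_state_gives_lam_E(self):
        # Q = 0 collapses the co-rotation to lam*E: S_xy = lam*gammadot/2
        L, gd, lam = 32, 1e-3, 0.2
        y = np.arange(L, dtype=float)
        vx = (gd * y)[None, :] * np.ones((L, 1))
        Q = uniform_field(L, 0.0, 0.0)
        S = corotation(Q, vx, np.zeros((L, L)), lam)
        interior = S.Qxy[:, 1:-1]  # wrap rows see the jump in gd*y
        assert np.allclose(interior, lam * gd / 2, rtol=1e-12)
        assert np.abs(S.Qxx[:, 1:-1]).max() < 1e-15

    def test_rigid_rotation_corotates_director(self):
        # v = (-w y, w x), Q = diag(q, -q): S_xy = 2 w q
        L, w, q = 32, 1e-3, 0.3
        c = (L - 1) / 2
        x, y = np.meshgrid(np.arange(L, dtype=float),
                           np.arange(L, dtype=float), indexing="ij")
        vx = -w * (y - c)
        vy = w * (x - c)
        S = corotation(uniform_field(L, q, 0.0), vx, vy, lam=0.2)
        interior = S.Qxy[2:-2, 2:-2]
        assert np.allclose(interior, 2 * w * q, rtol=1e-12)


class TestPolarity:
    def test_follows_flow_sign(self):
        L = 8
        Q = uniform_field(L, 1.0, 0.0)  # director along x
        prev = initial_polarity(Q)
        p = assign_polarity(Q, np.full((L, L), 1.0),
                            np.full((L, L), 0.1), prev)
        assert np.allclose(p.px, 1.0) and np.allclose(p.py, 0.0)
        p = assign_polarity(Q, np.full((L, L), -1.0),
                            np.zeros((L, L)), prev)
        assert np.allclose(p.px, -1.0)

    def test_tie_keeps_previous_sign(self):
        L = 8
        Q = uniform_field(L, 1.0, 0.0)
        prev = PolarityField(np.full((L, L), -1.0), np.zeros((L, L)))
        p = assign_polarity(Q, np.zeros((L, L)), np.zeros((L, L)), prev)
        assert np.allclose(p.px, -1.0)

    def test_perpendicular_flow_is_a_tie(self):
        L = 8
        Q = uniform_field(L, 1.0, 0.0)
        prev = PolarityField(np.full((L, L), -1.0), np.zeros((L, L)))
        p = assign_polarity(Q, np.zeros((L, L)), np.full((L, L), 0.7), prev)
        assert np.allclose(p.px, -1.0)

    def test_unit_norm_everywhere(self, random_Q, rng):
        L = random_Q.shape[0]
        prev = initial_polarity(random_Q)
        p = assign_polarity(random_Q, rng.normal(size=(L, L)),
                            rng.normal(size=(L, L)), prev)
        assert np.abs(np.hypot(p.px, p.py) - 1.0).max() < 1e-12


class TestStress:
    def test_uniform_state_is_purely_active(self):
        Q = uniform_field(8, 0.5, -0.2)
        H = molecular_field(Q, K=0.05, A=0.0)  # zero for uniform Q, A=0
        sig = assemble_stress(Q, H, lam=0.2, zeta=0.05, K=0.05)
        assert np.allclose(sig.sigma_xx, -0.05 * 0.5)
        assert np.allclose(sig.sigma_xy, -0.05 * -0.2)
        assert np.allclose(sig.sigma_yx, sig.sigma_xy)
        assert np.allclose(sig.sigma_yy, 0.05 * 0.5)

    def test_active_part_direct_substitution(self):
        # sigma_active = -zeta Q: diag(q, -q) with zeta=0.05, q=1
        Q = uniform_field(8, 1.0, 0.0)
        H = NematicField(np.zeros((8, 8)), np.zeros((8, 8)))
        sig = assemble_stress(Q, H, lam=0.0, zeta=0.05, K=0.05)
        assert np.allclose(sig.sigma_xx, -0.05)
        assert np.allclose(sig.sigma_yy, 0.05)

    def test_antisymmetric_part_is_QH_minus_HQ(self, random_Q):
        K, lam, zeta = 0.05, 0.2, 0.03
        H = molecular_field(random_Q, K=K, A=0.1)
        sig = assemble_stress(random_Q, H, lam=lam, zeta=zeta, K=K)
        anti = (sig.sigma_xy - sig.sigma_yx) / 2
        # brute-force commutator from full 2x2 matrices
        a, b = random_Q.Qxx, random_Q.Qxy
        h, g = H.Qxx, H.Qxy
        expected = np.empty_like(a)
        for i in range(a.shape[0]):
            for j in range(a.shape[1]):
                Qm = np.array([[a[i, j], b[i, j]], [b[i, j], -a[i, j]]])
                Hm = np.array([[h[i, j], g[i, j]], [g[i, j], -h[i, j]]])
                expected[i, j] = (Qm @ Hm - Hm @ Qm)[0, 1]
        assert np.abs(anti - expected).max() < 1e-13


class TestEvolutionStep:
    def test_ordered_uniform_state_is_a_fixed_point(self):
        L = 16
        p = ModelParams(L=L, V0=0.3)
        Q = uniform_field(L, Q_MIN_BULK, 0.0)
        pol = initial_polarity(Q)
        Q1 = beris_edwards_step(Q, np.zeros((L, L)), np.zeros((L, L)),
                                pol, p)
        assert np.abs(Q1.Qxx - Q.Qxx).max() < 1e-15
        assert np.abs(Q1.Qxy - Q.Qxy).max() < 1e-15

    def test_relaxational_decay_rate_of_plane_wave(self):
        # A=0, v=0, V0=0: dQ/dt = Gamma K lap Q, discrete eigenvalue
        L = 64
        params = ModelParams(L=L, A=0.0, V0=0.0, Gamma=0.1, K=0.05)
        k = 2 * np.pi * 5 / L
        x = np.arange(L)
        base = np.cos(k * x)[:, None] * np.ones(L)
        Q = NematicField(1.0 + 1e-4 * base, np.zeros((L, L)))
        pol = initial_polarity(Q)
        zeros = np.zeros((L, L))
        for _ in range(200):
            Q = beris_edwards_step(Q, zeros, zeros, pol, params)
        amp = (Q.Qxx - 1.0)[:, 0] @ base[:, 0] / (base[:, 0] @ base[:, 0])
        k_eff_sq = 2 * (1 - np.cos(k))
        expected = 1e-4 * (1 - params.Gamma * params.K * k_eff_sq) ** 200
        assert np.isclose(amp, expected, rtol=0.01)

    def test_self_advection_translates_a_blob(self):
        # Gamma = 0, v = 0, V0 = 0.1, uniform polarity +x: a localized
        # blob on Qxy rides at speed V0
        L, V0, steps = 64, 0.1, 100
        params = ModelParams(L=L, Gamma=1e-30, A=0.0, V0=V0)
        x, y = np.meshgrid(np.arange(L, dtype=float),
                           np.arange(L, dtype=float), indexing="ij")
        blob = 0.05 * np.exp(-(((x - 20) / 5) ** 2 + ((y - 32) / 5) ** 2))
        Q = NematicField(np.ones((L, L)), blob)
        pol = PolarityField(np.ones((L, L)), np.zeros((L, L)))
        zeros = np.zeros((L, L))
        for _ in range(steps):
            Q = beris_edwards_step(Q, zeros, zeros, pol, params)
        shift = V0 * steps
        # the first moment of an upwind-advected field moves at exactly
        # the carrier speed (summation by parts); the shape spreads by the
        # scheme's numerical diffusion ~ V0/2 per unit time
        centroid = (x * Q.Qxy).sum() / Q.Qxy.sum()
        assert np.isclose(centroid, 20 + shift, atol=1e-8)
        assert np.isclose(Q.Qxy.sum(), blob.sum(), atol=1e-9)
        target = 0.05 * np.exp(
            -(((x - 20 - shift) / 5) ** 2 + ((y - 32) / 5) ** 2))
        err = np.sqrt(np.mean((Q.Qxy - target) ** 2) / np.mean(target ** 2))
        assert err < 0.3

    def test_advection_conserves_lattice_sum(self):
        # pure advection with uniform carrier velocity telescopes exactly
        L = 32
        params = ModelParams(L=L, Gamma=1e-30, A=0.0, V0=0.2)
        rng = np.random.default_rng(0)
        Q = NematicField(rng.normal(size=(L, L)), rng.normal(size=(L, L)))
        s0 = Q.Qxx.sum(), Q.Qxy.sum()
        pol = PolarityField(np.ones((L, L)), np.zeros((L, L)))
        zeros = np.zeros((L, L))
        for _ in range(50):
            Q = beris_edwards_step(Q, zeros, zeros, pol, params)
        assert np.isclose(Q.Qxx.sum(), s0[0], atol=1e-9)
        assert np.isclose(Q.Qxy.sum(), s0[1], atol=1e-9)

    def test_blow_up_raises(self):
        L = 16
        params = ModelParams(L=L)
        Q = NematicField(np.full((L, L), 1e308), np.zeros((L, L)))
        pol = initial_polarity(Q)
        with pytest.raises(FloatingPointError):
            beris_edwards_step(Q, np.zeros((L, L)), np.zeros((L, L)),
                               pol, params)
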