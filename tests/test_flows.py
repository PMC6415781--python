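import math

import numpy as np
import pytest

from scsc import (
    BickleyParams,
    InputError,
    QuadrupleEddyParams,
    advect_ensemble,
    bickley_velocity,
    quadruple_eddy_velocity,
    random_noise_ensemble,
    trajectory_dissimilarity,
)
from scsc.dissimilarity import build_adjacency
from scipy.spatial.distance import squareform


class TestQuadrupleEddyVelocity:
    def test_time_zero_reduces_to_steady_gyres(self):
        # a = 0, b = 1, f = x at t = 0
        p = QuadrupleEddyParams()
        x, y = 0.5, -0.5
        u, v = quadruple_eddy_velocity(x, y, 0.0, p)
        assert u == pytest.approx(0.0, abs=1e-14)  # cos(pi*(-1/2)) = 0
        assert v == pytest.approx(
            math.pi * p.amplitude * math.cos(math.pi * 0.5) * math.sin(-math.pi * 0.5),
            abs=1e-14,
        )

    def test_divergence_free(self):
        rng = np.random.default_rng(0)
        h = 1e-6
        for _ in range(20):
            x, y, t = rng.uniform(0.05, 1.95), rng.uniform(-0.95, 0.95), rng.uniform(0, 40)
            dudx = (
                quadruple_eddy_velocity(x + h, y, t)[0]
                - quadruple_eddy_velocity(x - h, y, t)[0]
            ) / (2 * h)
            dvdy = (
                quadruple_eddy_velocity(x, y + h, t)[1]
                - quadruple_eddy_velocity(x, y - h, t)[1]
            ) / (2 * h)
            assert abs(dudx + dvdy) < 1e-6

    def test_domain_boundaries_are_streamlines(self):
        for t in (0.0, 2.5, 7.7):
            for x in (0.0, 2.0):
                u, _ = quadruple_eddy_velocity(x, 0.3, t)
                assert u == pytest.approx(0.0, abs=1e-12)
            for y in (-1.0, 0.0, 1.0):
                _, v = quadruple_eddy_velocity(0.7, y, t)
                assert v == pytest.approx(0.0, abs=1e-12)


class TestBickleyVelocity:
    def test_jet_axis_speed(self):
        p = BickleyParams()
        u, v = bickley_velocity(np.array([5e6]), np.array([0.0]), 0.0, p)
        # sech = 1, tanh = 0: u = U - c3 (the sech^2-derivative term vanishes)
        assert u.item() == pytest.approx(p.U - p.c[2], rel=1e-12)
        assert u.item() == pytest.approx(33.77, abs=0.01)

    def test_perturbation_decays_away_from_jet(self):
        p = BickleyParams()
        _, v_far = bickley_velocity(np.array([3e6]), np.array([8e6]), 0.0, p)
        _, v_near = bickley_velocity(np.array([3e6]), np.array([1e6]), 0.0, p)
        assert abs(v_far.item()) < 1e-2 * abs(v_near.item())

    def test_matches_streamfunction_derivatives(self):
        p = BickleyParams()

        def psi(x, y, t):
            psi0 = p.c[2] * y - p.U * p.L * np.tanh(y / p.L)
            psi1 = (
                p.U
                * p.L
                / np.cosh(y / p.L) ** 2
                * np.sum(p.eps * np.cos(p.k * (x - p.sigma * t)))
            )
            return psi0 + psi1

        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.uniform(0, 2e7)
            y = rng.uniform(-2.5e6, 2.5e6)
            t = rng.uniform(0, 3e6)
            hx, hy = 1.0, 1.0
            u_fd = -(psi(x, y + hy, t) - psi(x, y - hy, t)) / (2 * hy)
            v_fd = (psi(x + hx, y, t) - psi(x - hx, y, t)) / (2 * hx)
            u, v = bickley_velocity(np.array([x]), np.array([y]), t, p)
            assert u.item() == pytest.approx(u_fd, rel=1e-5, abs=1e-8)
            assert v.item() == pytest.approx(v_fd, rel=1e-5, abs=1e-8)

    def test_wave_periods_commensurate_with_domain(self):
        p = BickleyParams()
        for n, k in enumerate(p.k, start=1):
            assert 2 * math.pi / k == pytest.approx(math.pi * p.r0 / n)
        assert 2 * math.pi / p.k[0] == pytest.approx(2.0015e7, rel=1e-3)

    def test_periodic_in_x(self):
        p = BickleyParams()
        x = np.array([1.3e6])
        y = np.array([5e5])
        u1, v1 = bickley_velocity(x, y, 1e5, p)
        # the wavenumbers are not exactly commensurate with 2e7 m, so the
        # field repeats with the waves' common period pi*r0
        u2, v2 = bickley_velocity(x + math.pi * p.r0, y, 1e5, p)
        np.testing.assert_allclose(u1, u2, rtol=1e-9)
        np.testing.assert_allclose(v1, v2, rtol=1e-9)


class TestAdvection:
    DOMAIN = ((0.0, 1.0), (0.0, 1.0))

    def test_zero_field_keeps_positions(self):
        ens = advect_ensemble(
            lambda t, p: np.zeros_like(p),
            5,
            seed=0,
            domain=self.DOMAIN,
            t_span=(0, 1),
            dt=0.1,
            n_saved=6,
        )
        for k in range(6):
            np.testing.assert_array_equal(ens.positions[:, k], ens.positions[:, 0])

    def test_uniform_field_translates_exactly(self):
        vel = np.array([0.3, -0.2])
        ens = advect_ensemble(
            lambda t, p: np.tile(vel, (p.shape[0], 1)),
            4,
            seed=1,
            domain=self.DOMAIN,
            t_span=(0, 2),
            dt=0.25,
            n_saved=5,
            clamp=False,
        )
        for k, t in enumerate(ens.times):
            np.testing.assert_allclose(
                ens.positions[:, k], ens.positions[:, 0] + vel * t, atol=1e-12
            )

    def test_fifth_order_richardson_convergence(self):
        omega = 1.0

        def rotation(t, p):
            return np.stack([-omega * p[:, 1], omega * p[:, 0]], axis=1)

        def endpoint_error(dt):
            ens = advect_ensemble(
                rotation,
                2,
                seed=3,
                domain=((0.5, 1.0), (0.5, 1.0)),
                t_span=(0.0, 2.0),
                dt=dt,
                n_saved=2,
                clamp=False,
            )
            start = ens.positions[:, 0]
            angle = omega * 2.0
            rot = np.array(
                [[math.cos(angle), -math.sin(angle)], [math.sin(angle), math.cos(angle)]]
            )
            exact = start @ rot.T
            return np.abs(ens.positions[:, -1] - exact).max()

        ratio = endpoint_error(0.2) / endpoint_error(0.1)
        assert 20 < ratio < 48  # fifth order: halving dt gains ~2^5

    def test_escape_clamping_warns(self):
        with pytest.warns(UserWarning, match="escaped"):
            ens = advect_ensemble(
                lambda t, p: np.ones_like(p),
                3,
                seed=0,
                domain=self.DOMAIN,
                t_span=(0, 5),
                dt=0.5,
                n_saved=3,
            )
        assert ens.positions.max() <= 1.0

    def test_input_validation(self):
        with pytest.raises(InputError):
            advect_ensemble(
                lambda t, p: p, 1, seed=0, domain=self.DOMAIN, t_span=(0, 1),
                dt=0.1, n_saved=3,
            )
        with pytest.raises(InputError):
            advect_ensemble(
                lambda t, p: p, 3, seed=0, domain=self.DOMAIN, t_span=(1, 0),
                dt=0.1, n_saved=3,
            )


class TestNoiseEnsemble:
    def test_unit_square_support_and_reproducibility(self):
        a = random_noise_ensemble(20, 30, seed=7)
        b = random_noise_ensemble(20, 30, seed=7)
        c = random_noise_ensemble(20, 30, seed=8)
        assert a.positions.min() >= 0.0 and a.positions.max() < 1.0
        np.testing.assert_array_equal(a.positions, b.positions)
        assert not np.array_equal(a.positions, c.positions)

    def test_pairwise_dissimilarities_concentrate(self):
        ens = random_noise_ensemble(100, 500, seed=0)
        A = build_adjacency(ens)
        values = squareform(A.values, checks=False)
        assert values.std() / values.mean() < 0.1

    def test_single_pair_value_matches_matrix(self):
        ens = random_noise_ensemble(10, 50, seed=1)
        A = build_adjacency(ens)
        assert A.values[2, 7] == pytest.approx(
            trajectory_dissimilarity(ens, 2, 7), rel=1e-12
        )
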