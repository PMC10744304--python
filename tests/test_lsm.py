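"""Regularized differential operators, transport, redistancing and the
outer growth loop, checked against analytic mean-curvature-flow solutions."""

import numpy as np
import pytest

from neogrowth import (
    ChannelSpec,
    GrowthParams,
    advect,
    channel_sdf,
    curvature_field,
    filling_fraction,
    growth_velocity,
    initial_levelset,
    normal_field,
    redistance,
    simulate,
)
from neogrowth.fields import ScalarField, VectorField
from neogrowth.lsm import EmptyInterfaceWarning, _screened_solve

from conftest import radial_phi


def planar_field(spacing=0.02, n=64):
    ax = spacing * np.arange(n)
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    return ScalarField(xx - ax[n // 2], spacing)


class TestNormalField:
    def test_planar_gradient_is_unit_x(self):
        n = normal_field(planar_field(), eps=1e-4)
        assert np.allclose(n.components[0], 1.0, atol=1e-6)
        assert np.allclose(n.components[1], 0.0, atol=1e-6)

    def test_radial_void_normal_points_outward(self):
        state = radial_phi(0.3, 0.5, 0.01)
        n = normal_field(state.phi, eps=1e-4)
        xx, yy = state.phi.meshgrid()
        r = np.maximum(np.hypot(xx, yy), 1e-12)
        band = np.abs(state.phi.values) < 0.05
        rhat_x = (xx / r)[band]
        assert np.abs(n.components[0][band] - rhat_x).max() < 0.02

    def test_eps_zero_is_raw_normalized_gradient(self):
        state = radial_phi(0.3, 0.5, 0.01)
        n0 = normal_field(state.phi, eps=0.0)
        g = np.gradient(state.phi.values, 0.01)
        mag = np.hypot(*g)
        assert np.allclose(n0.components[0], g[0] / np.maximum(mag, 1e-12))

    def test_degenerate_phi_rejected(self):
        flat = ScalarField(np.full((32, 32), 1.0), 0.02)
        with pytest.raises(ValueError, match="degenerate"):
            normal_field(flat, eps=1e-4)


class TestCurvatureField:
    def test_flat_interface_zero(self):
        k = curvature_field(planar_field(), eps=1e-4)
        interior = k.values[5:-5, 5:-5]
        assert np.abs(interior).max() < 1e-6

    @pytest.mark.parametrize("dim, expected", [(2, 2.0), (3, 4.0)])
    def test_radial_void_curvature(self, dim, expected):
        """Cylindrical void r=0.5: κ=1/r=2; spherical void: κ=2/r=4."""
        h = 0.5 / 30 if dim == 2 else 0.5 / 16
        state = radial_phi(0.5, 0.7, h, dim=dim)
        k = curvature_field(state.phi, eps=1e-4)
        band = np.abs(state.phi.values) < 0.5 * h
        assert np.median(k.values[band]) == pytest.approx(expected, rel=0.05)

    def test_curvature_clamped(self):
        state = radial_phi(0.3, 0.5, 0.01)
        k = curvature_field(state.phi, eps=0.0, kappa_cap=10.0)
        assert k.values.max() <= 10.0 + 1e-12


class TestScreenedSolve:
    def test_identity_on_constants(self):
        f = np.full((40, 40), 3.7)
        assert np.allclose(_screened_solve(f, 1e-4, 0.02), f)

    def test_solves_screened_poisson(self):
        """(I − εΔ)u = f: residual of the discrete operator vanishes."""
        rng = np.random.default_rng(0)
        f = rng.normal(size=(32, 32))
        h, eps = 0.02, 1e-4
        u = _screened_solve(f, eps, h)
        # Neumann Laplacian via edge reflection
        up = np.pad(u, 1, mode="edge")
        lap = (
            up[2:, 1:-1] + up[:-2, 1:-1] + up[1:-1, 2:] + up[1:-1, :-2]
            - 4 * u
        ) / h**2
        assert np.abs(u - eps * lap - f).max() < 1e-8


class TestGrowthVelocity:
    def test_speed_and_direction(self):
        state = radial_phi(0.5, 0.7, 0.01)
        n = normal_field(state.phi, eps=0.0)
        k = curvature_field(state.phi, eps=0.0)
        V = growth_velocity(k, n, A=0.01)
        band = np.abs(state.phi.values) < 0.005
        speed = V.magnitude()[band]
        # κ = 2/mm at the interface, A = 0.01 ⟹ |V| = 0.02 mm/day
        assert np.median(speed) == pytest.approx(0.02, rel=0.05)
        # directed opposite n (into the void)
        dot = sum(v * c for v, c in zip(V.components, n.components))
        assert (dot[band] < 0).all()

    def test_nonpositive_curvature_frozen(self):
        k = ScalarField(np.full((16, 16), -1.0), 0.02)
        n = VectorField([np.ones((16, 16)), np.zeros((16, 16))], 0.02)
        V = growth_velocity(k, n, A=0.5)
        assert np.all(V.magnitude() == 0.0)

    def test_zero_coefficient(self):
        k = ScalarField(np.full((16, 16), 3.0), 0.02)
        n = VectorField([np.ones((16, 16)), np.zeros((16, 16))], 0.02)
        assert np.all(growth_velocity(k, n, A=0.0).magnitude() == 0.0)
        with pytest.raises(ValueError):
            growth_velocity(k, n, A=-1.0)


class TestAdvect:
    def test_zero_velocity_identity(self):
        state = radial_phi(0.3, 0.5, 0.01)
        V = VectorField(
            [np.zeros(state.phi.shape), np.zeros(state.phi.shape)], 0.01
        )
        out = advect(state.phi, V, dt=1.0)
        assert np.allclose(out.values, state.phi.values)

    def test_uniform_translation(self):
        """Uniform V = (c, 0): the zero set translates by c·dt."""
        state = radial_phi(0.3, 0.6, 0.01)
        c, dt = 0.004, 1.0
        V = VectorField(
            [np.full(state.phi.shape, c), np.zeros(state.phi.shape)], 0.01
        )
        out = advect(state.phi, V, dt)
        xx, yy = state.phi.meshgrid()
        expected = np.hypot(xx - c * dt, yy) - 0.3
        band = np.abs(expected) < 0.03
        assert np.abs(out.values - expected)[band].max() < 0.1 * 0.01


class TestRedistance:
    def test_idempotent_on_distance_function(self):
        state = radial_phi(0.3, 0.5, 0.01)
        out = redistance(state.phi)
        band = np.abs(state.phi.values) < 0.1
        assert np.abs(out.values - state.phi.values)[band].max() < 0.01 / 10

    def test_rescaled_input_recovers_unit_gradient(self):
        state = radial_phi(0.3, 0.5, 0.01)
        out = redistance(state.phi.with_values(3.0 * state.phi.values))
        g = np.gradient(out.values, 0.01)
        mag = np.hypot(*g)
        band = np.abs(out.values) < 0.05
        assert np.abs(mag[band] - 1.0).max() < 0.1

    def test_noise_perturbed_circle_zero_set_preserved(self):
        """Checkerboard noise off the band must not move the zero set by
        more than half a cell (oracle: brute-force distance to the clean
        circle)."""
        h = 0.01
        state = radial_phi(0.3, 0.5, h)
        rng = np.random.default_rng(1)
        noise = 0.3 * h * (-1.0) ** np.indices(state.phi.shape).sum(axis=0)
        perturbed = state.phi.with_values(state.phi.values + noise)
        out = redistance(perturbed)
        xx, yy = state.phi.meshgrid()
        clean = np.hypot(xx, yy) - 0.3
        band = np.abs(clean) < 2 * h
        assert np.abs(out.values - clean)[band].max() < 0.5 * h

    def test_empty_interface_warns(self):
        f = ScalarField(np.ones((16, 16)), 0.02)
        with pytest.warns(EmptyInterfaceWarning):
            out = redistance(f)
        assert np.allclose(out.values, 1.0)


class TestSimulate:
    def test_frozen_at_zero_coefficient(self, circle_state):
        series = simulate(
            circle_state, GrowthParams(A=0.0), t_end=21, record_at=[10, 21]
        )
        f0 = filling_fraction(circle_state)
        assert np.allclose(series.filling, f0, atol=1e-9)

    def test_circle_collapse_matches_analytic(self, circle_state):
        """d = 1 circle, A = 0.003: r(t) = √(r0² − 2At), full fill at
        r0²/2A = 41.7 days (coarse-grid smoke version of the oracle)."""
        A, h = 0.003, circle_state.phi.spacing
        series = simulate(
            circle_state, GrowthParams(A=A), t_end=50, record_at=[10, 20, 30]
        )
        for t, f in zip(series.times, series.filling):
            if t > 30:
                continue
            r_exact = np.sqrt(0.25 - 2 * A * t)
            r_sim = 0.5 * np.sqrt(max(1 - f, 0.0))
            assert abs(r_sim - r_exact) < 2 * h
        assert series.full_fill_time == pytest.approx(41.7, rel=0.05)

    def test_triangle_fills_faster_than_circle(self, circle_state, triangle_state):
        A = 0.003
        days = [5, 10, 15, 21]
        s_tri = simulate(triangle_state, GrowthParams(A=A), 21, record_at=days)
        s_cir = simulate(circle_state, GrowthParams(A=A), 21, record_at=days)
        assert np.all(s_tri.filling >= s_cir.filling)

    def test_filling_monotone_and_bounded(self, triangle_state):
        series = simulate(
            triangle_state, GrowthParams(A=0.005), 21, record_at=[2, 5, 9, 14, 21]
        )
        assert np.all(np.diff(series.filling) >= -1e-3)
        assert np.all((series.filling >= 0) & (series.filling <= 1))

    def test_halved_spacing_changes_day21_filling_little(self):
        """Grid convergence: d = 1 circle day-21 filling moves < 2 pp
        between spacing d/50 and d/100."""
        A = 0.003
        out = {}
        for frac in (50, 100):
            psi = channel_sdf(ChannelSpec("circle", 1.0), 1.0 / frac)
            state = initial_levelset(psi, 0.0)
            out[frac] = simulate(
                state, GrowthParams(A=A), 21, record_at=[21]
            ).filling[-1]
        assert abs(out[50] - out[100]) < 0.02

    def test_time_to_half_fill_scales_with_d_squared(self):
        """Circle: t(50%) ∝ d² within 10% (r² = r0² − 2At)."""
        A = 0.005
        t50 = {}
        for d in (0.7, 1.0):
            psi = channel_sdf(ChannelSpec("circle", d), d / 50)
            state = initial_levelset(psi, 0.0)
            days = list(np.arange(0.5, 40, 0.5))
            series = simulate(state, GrowthParams(A=A), 40, record_at=days)
            t50[d] = series.times[np.searchsorted(series.filling, 0.5)]
        ratio = t50[1.0] / t50[0.7]
        assert ratio == pytest.approx((1.0 / 0.7) ** 2, rel=0.10)
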