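"""Spring forces, radial forcing, wall growth and the strain statistic."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from meristemsim import mechanics as mech
from meristemsim.mechanics import ModelParams, StateIndexMap
from meristemsim.simulator import make_founder

from conftest import build_tissue


def two_vertex_tissue(distance: float, rest: float):
    """A single wall, plus a dummy triangle cell not used by force tests."""
    return build_tissue(
        points={0: (0, 0), 1: (distance, 0)},
        walls=[(2, 0, 1, rest)],
        cells={},
    )


class TestModelParams:
    def test_defaults_are_standard_set(self):
        p = ModelParams()
        assert (p.spring_k, p.growth_k, p.radial_k) == (0.05, 0.01, 0.05)
        assert (p.area_threshold, p.d_threshold, p.radius_threshold) == (1.0, 0.1, 7.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(spring_k=-1.0)
        with pytest.raises(ValueError):
            ModelParams(growth_k=-0.01)

    def test_oryzalin_preset_disables_division(self):
        assert not ModelParams().oryzalin().division_enabled


class TestWallForces:
    def test_zero_at_rest_length(self):
        t = two_vertex_tissue(1.0, 1.0)
        f = mech.wall_forces(t, 0.05)
        assert np.allclose(f[0], 0) and np.allclose(f[1], 0)

    def test_hooke_magnitude_and_direction(self):
        delta = 0.3
        t = two_vertex_tissue(1.0 + delta, 1.0)
        f = mech.wall_forces(t, 0.05)
        assert f[0] == pytest.approx([0.05 * delta, 0.0])  # pulled inward
        assert f[1] == pytest.approx([-0.05 * delta, 0.0])

    def test_hexagon_at_rest_equilibrium(self):
        t = make_founder(6)
        f = mech.wall_forces(t, 0.05)
        for v in f.values():
            assert np.allclose(v, 0, atol=1e-14)

    def test_momentum_conservation_random_state(self, rng):
        t = make_founder(9)
        for v in t.vertices.values():
            v.pos = v.pos + rng.normal(0, 0.2, 2)
        f = mech.wall_forces(t, 0.05)
        assert np.allclose(sum(f.values()), 0, atol=1e-12)

    def test_coincident_vertices_rejected(self):
        t = two_vertex_tissue(0.0, 1.0)
        with pytest.raises(FloatingPointError):
            mech.wall_forces(t, 0.05)


class TestRadialForces:
    def test_unit_vertex_constant_mode(self):
        t = two_vertex_tissue(1.0, 1.0)
        f = mech.radial_forces(t, 0.05, mode="constant")
        assert f[0] == pytest.approx([0.0, 0.0])  # at the origin
        assert f[1] == pytest.approx([0.05, 0.0])

    def test_linear_mode_scales_with_radius(self):
        t = two_vertex_tissue(2.0, 1.0)
        f = mech.radial_forces(t, 0.05, mode="linear")
        assert f[1] == pytest.approx([0.1, 0.0])

    def test_ring_center_of_mass_balance(self):
        t = make_founder(12)
        for mode in ("constant", "linear"):
            f = mech.radial_forces(t, 0.05, mode=mode)
            assert np.allclose(sum(f.values()), 0, atol=1e-14)


class TestRestLengthGrowth:
    @pytest.mark.parametrize("dist,rest,expected", [
        (1.0, 1.0, 0.0),          # at rest
        (2.0, 1.0, 0.01),         # stretched by 1
        (0.5, 1.5, 0.0),          # compressed: ramp clips to zero
    ])
    def test_ramp(self, dist, rest, expected):
        t = two_vertex_tissue(dist, rest)
        rates = mech.rest_length_rates(t, 0.01)
        assert rates[2] == pytest.approx(expected)


class TestStrainDirection:
    def _strained_rect(self, sx: float, sy: float):
        """Unit square with horizontal walls strained sx, vertical sy."""
        return build_tissue(
            points={0: (0, 0), 1: (1, 0), 2: (1, 1), 3: (0, 1)},
            walls=[(4, 0, 1, 1 / (1 + sx)), (5, 1, 2, 1 / (1 + sy)),
                   (6, 2, 3, 1 / (1 + sx)), (7, 3, 0, 1 / (1 + sy))],
            cells={8: [4, 5, 6, 7]},
        )

    def test_horizontal_strain(self):
        t = self._strained_rect(0.3, 0.0)
        assert mech.strain_direction(t, 8) == pytest.approx(0.0, abs=1e-12)

    def test_vertical_strain(self):
        t = self._strained_rect(0.0, 0.3)
        assert mech.strain_direction(t, 8) == pytest.approx(math.pi / 2)

    def test_mixed_strain_formula(self):
        # walls at 0 and 90 deg with strains 0.2 and 0.1:
        # theta = 0.5*atan2(0.1*sin180 + 0.2*sin0, 0.1*cos180 + 0.2*cos0) = 0
        t = self._strained_rect(0.2, 0.1)
        assert mech.strain_direction(t, 8) == pytest.approx(0.0, abs=1e-12)

    def test_isotropic_returns_none(self):
        t = self._strained_rect(0.0, 0.0)
        assert mech.strain_direction(t, 8) is None

    def test_rotation_equivariance(self, rng):
        t = make_founder(6)
        for w in t.walls.values():
            w.rest_length *= rng.uniform(0.6, 0.95)
        th0 = mech.strain_direction(t, max(t.cells))
        alpha = 0.7
        rot = np.array([[math.cos(alpha), -math.sin(alpha)],
                        [math.sin(alpha), math.cos(alpha)]])
        for v in t.vertices.values():
            v.pos = rot @ v.pos
        th1 = mech.strain_direction(t, max(t.cells))
        assert th1 == pytest.approx((th0 + alpha) % math.pi, abs=1e-9)


class TestOdeRhs:
    def test_rest_state_is_fixed_point(self):
        t = make_founder(6)
        p = ModelParams(radial_k=0.0)
        m = StateIndexMap.from_tissue(t)
        dy = mech.make_rhs(m, p)(0.0, m.pack(t))
        assert np.allclose(dy, 0, atol=1e-14)

    def test_stretched_wall_relaxes_while_rest_length_grows(self):
        t = two_vertex_tissue(2.0, 1.0)
        p = ModelParams(radial_k=0.0)
        m = StateIndexMap.from_tissue(t)
        dy = mech.make_rhs(m, p)(0.0, m.pack(t))
        pos_rate, rest_rate = dy[:4].reshape(-1, 2), dy[4:]
        assert pos_rate[0][0] > 0 and pos_rate[1][0] < 0  # approach each other
        assert rest_rate[0] > 0  # rest length grows toward realized length

    def test_spring_rhs_matches_numeric_energy_gradient(self, rng):
        """dx/dt equals minus the central-difference gradient of the
        spring energy (growth and radial forcing switched off)."""
        t = make_founder(5)
        for v in t.vertices.values():
            v.pos = v.pos + rng.normal(0, 0.15, 2)
        p = ModelParams(radial_k=0.0, growth_k=0.0)
        m = StateIndexMap.from_tissue(t)
        y = m.pack(t)
        dy = mech.make_rhs(m, p)(0.0, y)[: 2 * m.n_vertices]
        h = 1e-6
        for k in range(2 * m.n_vertices):
            yp, ym = y.copy(), y.copy()
            yp[k] += h
            ym[k] -= h
            m.unpack(yp, t)
            ep = mech.spring_energy(t, p.spring_k)
            m.unpack(ym, t)
            em = mech.spring_energy(t, p.spring_k)
            assert dy[k] == pytest.approx(-(ep - em) / (2 * h), abs=1e-7)

    def test_energy_non_increasing_gradient_flow(self, rng):
        """Overdamped dynamics with no turgor and frozen growth dissipates
        the elastic energy monotonically."""
        p = ModelParams(radial_k=0.0, growth_k=0.0)
        for trial in range(20):
            t = make_founder(int(rng.integers(3, 10)))
            for v in t.vertices.values():
                v.pos = v.pos + rng.normal(0, 0.25, 2)
            m = StateIndexMap.from_tissue(t)
            y0 = m.pack(t)
            sol = solve_ivp(mech.make_rhs(m, p), (0, 40.0), y0,
                            t_eval=np.linspace(0, 40, 9), rtol=1e-8, atol=1e-10)
            energies = []
            for col in sol.y.T:
                m.unpack(col, t)
                energies.append(mech.spring_energy(t, p.spring_k))
            diffs = np.diff(energies)
            assert np.all(diffs <= 1e-12)
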