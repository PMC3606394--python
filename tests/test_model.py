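"""Network structure, rate laws, derivatives and the integrator."""

import numpy as np
import pytest

from nox1sim import (
    CONTROL_SIGNALS,
    build_stoichiometry,
    complete_fluxes,
    evaluate_fluxes,
    integrate,
    moiety_totals,
    sample_flux_basis,
    time_derivative,
)
from nox1sim.model import make_jacobian, make_rhs

N = build_stoichiometry()


def manual_derivative(x, s, g):
    """Independent oracle: each balance written out monomial by monomial."""
    x1, x2, x3, x4, x5, x6, x7, x8 = x
    s1, s2, s3 = s
    f = [
        g[0] * x2 * x4 * x6 * x7, g[1] * x1, g[2] * x1, g[3] * x1,
        g[4] * x3 * s1, g[5] * x4, g[6] * x5 * s2, g[7] * x6,
        g[8] * x7 * s3, g[9] * x8, g[10], g[11], g[12], g[13] * x1,
        g[14], g[15] * x8,
    ]
    return np.array([
        f[0] - f[1] - f[2] - f[3] - f[13],
        -f[0] + f[1] + f[2] + f[3] + f[10],
        f[2] - f[4] + f[5] + f[11],
        -f[0] + f[1] + f[3] + f[4] - f[5],
        f[3] - f[6] + f[7] + f[12],
        -f[0] + f[1] + f[2] + f[6] - f[7],
        -f[0] + f[2] + f[3] - f[8] + f[9] + f[14],
        f[1] + f[8] - f[9] - f[15],
    ])


class TestStoichiometry:
    def test_shape_and_entries(self):
        assert N.shape == (8, 16)
        assert set(np.unique(N)) <= {-1, 0, 1}

    def test_assembly_column(self):
        col = N[:, 0]
        assert col[0] == 1
        assert all(col[i] == -1 for i in (1, 3, 5, 6))
        assert all(col[i] == 0 for i in (2, 4, 7))

    def test_proteolysis_column_degrades_complex_only(self):
        col = N[:, 13]
        assert col[0] == -1 and np.count_nonzero(col) == 1

    def test_recycling_columns_consume_complex(self):
        for j in (1, 2, 3):
            assert N[0, j] == -1

    def test_recycling_products(self):
        # f2 returns NoxA1_P; f3 returns free p47; f4 returns Rac1_GDP
        assert list(np.nonzero(N[:, 1] == 1)[0]) == [1, 3, 5, 7]
        assert list(np.nonzero(N[:, 2] == 1)[0]) == [1, 2, 5, 6]
        assert list(np.nonzero(N[:, 3] == 1)[0]) == [1, 3, 4, 6]

    def test_stoichiometric_factor_of_four(self, rng):
        # proteolysis removes all four subunit moieties at once, so any
        # steady flux vector obeys f11+f12+f13+f15 = 4*f14 + f16
        for _ in range(20):
            f = complete_fluxes(sample_flux_basis(rng, (-2, 2)))
            total_in = f[10] + f[11] + f[12] + f[14]
            assert total_in == pytest.approx(4 * f[13] + f[15])

    def test_null_space_of_balance_vectors(self, rng):
        """N @ F vanishes for any flux vector built from the balance
        identities, for both selector branches."""
        for _ in range(1000):
            basis = sample_flux_basis(rng, (-2, 2))
            F = complete_fluxes(basis)
            assert np.max(np.abs(N @ F)) < 1e-9 * max(F.max(), 1.0)


class TestRateLaws:
    def test_zero_state_leaves_only_influxes(self):
        g = np.arange(1.0, 17.0)
        f = evaluate_fluxes(np.zeros(8), CONTROL_SIGNALS, g)
        expected = np.zeros(16)
        expected[10], expected[11], expected[12], expected[14] = 11, 12, 13, 15
        np.testing.assert_allclose(f, expected)

    def test_single_monomials(self):
        g = np.zeros(16)
        g[1] = 0.1
        x = np.zeros(8)
        x[0] = 100.0
        assert evaluate_fluxes(x, CONTROL_SIGNALS, g)[1] == pytest.approx(10.0)
        g = np.zeros(16)
        g[0] = 1.0
        x = np.zeros(8)
        x[[1, 3, 5, 6]] = 1.0
        assert evaluate_fluxes(x, CONTROL_SIGNALS, g)[0] == pytest.approx(1.0)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            evaluate_fluxes(np.full(8, np.nan), CONTROL_SIGNALS, np.ones(16))
        with pytest.raises(ValueError):
            evaluate_fluxes(np.ones(8), (1.0, 0.0, 1.0), np.ones(16))

    def test_signal_scaling_enters_forward_reactions_only(self, rng):
        x = rng.uniform(1, 10, 8)
        g = rng.uniform(0, 1, 16)
        f1 = evaluate_fluxes(x, (1, 1, 1), g)
        f2 = evaluate_fluxes(x, (3, 5, 7), g)
        np.testing.assert_allclose(f2[4], 3 * f1[4])
        np.testing.assert_allclose(f2[6], 5 * f1[6])
        np.testing.assert_allclose(f2[8], 7 * f1[8])
        mask = np.ones(16, bool)
        mask[[4, 6, 8]] = False
        np.testing.assert_allclose(f2[mask], f1[mask])


class TestDerivative:
    def test_matches_manual_expansion(self, rng):
        for _ in range(50):
            x = rng.uniform(0, 100, 8)
            g = rng.uniform(0, 2, 16)
            s = rng.uniform(0.5, 10, 3)
            np.testing.assert_allclose(
                time_derivative(x, s, g), manual_derivative(x, s, g),
                rtol=1e-12, atol=1e-12,
            )

    def test_fast_rhs_and_jacobian_consistent(self, rng):
        x = rng.uniform(0, 100, 8)
        g = rng.uniform(0, 2, 16)
        s = (2.0, 1.0, 4.0)
        rhs = make_rhs(g, s)
        np.testing.assert_allclose(rhs(0.0, x), time_derivative(x, s, g))
        jac = make_jacobian(g, s)(0.0, x)
        eps = 1e-6
        num = np.empty((8, 8))
        for j in range(8):
            xp, xm = x.copy(), x.copy()
            xp[j] += eps
            xm[j] -= eps
            num[:, j] = (np.array(rhs(0, xp)) - np.array(rhs(0, xm))) / (2 * eps)
        # tolerance bounded by central-difference truncation error
        np.testing.assert_allclose(jac, num, rtol=1e-3, atol=1e-5)

    def test_all_zero_gamma(self):
        np.testing.assert_array_equal(
            time_derivative(np.ones(8), CONTROL_SIGNALS, np.zeros(16)),
            np.zeros(8),
        )

    def test_zero_at_parameterized_steady_state(self, make_param):
        param = make_param()
        dx = time_derivative(param.state_ss, CONTROL_SIGNALS, param.gamma)
        denom = np.maximum(np.abs(param.state_ss), 1e-6)
        assert np.max(np.abs(dx) / denom) < 1e-9


class TestIntegrate:
    def test_steady_state_stays_put(self, make_param):
        param = make_param()
        grid = np.linspace(0, 100, 11)
        traj = integrate(param.state_ss, CONTROL_SIGNALS, param.gamma, 100,
                         t_grid=grid)
        rel = np.abs(traj.states - param.state_ss) / np.maximum(
            param.state_ss, 1e-6
        )
        assert np.max(rel) < 1e-6

    def test_closed_system_conserves_moieties(self, make_param):
        param = make_param(closed=True)
        traj = integrate(param.state_ss, (10.0, 10.0, 1.0), param.gamma, 200,
                         t_grid=np.linspace(0, 200, 21))
        totals0 = moiety_totals(param.state_ss)
        for row in traj.states:
            np.testing.assert_allclose(
                moiety_totals(row), totals0, rtol=1e-6
            )

    def test_tolerance_refinement_converges(self, make_param):
        param = make_param()
        final = []
        for rtol, atol in ((1e-6, 1e-9), (5e-7, 5e-10)):
            traj = integrate(param.state_ss, (10.0, 1.0, 1.0), param.gamma,
                             50, rtol=rtol, atol=atol)
            final.append(traj.final)
        rel = np.abs(final[0] - final[1]) / np.maximum(np.abs(final[1]), 1e-6)
        assert np.max(rel) < 1e-4

    def test_rejects_bad_inputs(self, make_param):
        param = make_param()
        with pytest.raises(ValueError):
            integrate(-np.ones(8), CONTROL_SIGNALS, param.gamma, 10)
        with pytest.raises(ValueError):
            integrate(param.state_ss, CONTROL_SIGNALS, param.gamma, 0)
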