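"""Module designs, scenario flux sampling and the comparison grid."""

import numpy as np
import pytest

from nox1sim import (
    MODULE_PATHWAYS,
    ScenarioConfig,
    apportion_recycling,
    compare_modules,
    moiety_totals,
    parameterize_module,
    scenario_flux_sampler,
    summarize_modules,
    verify_steady,
)
from nox1sim.model import is_closed


class TestModuleTable:
    def test_textual_constraints(self):
        assert MODULE_PATHWAYS[1] == {"f2"}
        for m in (2, 3, 6):
            assert "f2" not in MODULE_PATHWAYS[m]
        for m in (6, 7):
            assert {"f3", "f4"} <= MODULE_PATHWAYS[m]
        assert len({frozenset(v) for v in MODULE_PATHWAYS.values()}) == 7

    def test_equal_split(self, rng):
        split = apportion_recycling(7, rng, mode="equal")
        for v in split.values():
            assert v == pytest.approx(100 / 3)
        split1 = apportion_recycling(1, rng, mode="equal")
        assert split1 == {"f2": 100.0, "f3": 0.0, "f4": 0.0}

    def test_dirichlet_split_sums_to_total(self, rng):
        for design in range(1, 8):
            split = apportion_recycling(design, rng)
            assert sum(split.values()) == pytest.approx(100)
            for name in ("f2", "f3", "f4"):
                if name not in MODULE_PATHWAYS[design]:
                    assert split[name] == 0.0


class TestScenarioSampler:
    def test_closed_branch(self, rng):
        f9, f10, f16, flag = scenario_flux_sampler(30.0, 12.0, None, rng)
        assert f16 == 0.0 and not flag
        assert f10 == pytest.approx(42.0)  # f10 = f9 + f2

    def test_scenario1_ordering_and_balance(self, rng):
        for _ in range(200):
            f2 = float(rng.uniform(0, 100))
            f9 = float(rng.uniform(0.1, 75))
            r9, f10, f16, flag = scenario_flux_sampler(f2, f9, 1, rng)
            assert r9 + f2 == pytest.approx(f10 + f16)
            if not flag:
                assert r9 > f10 and f16 > f2
                assert f10 >= 0

    def test_scenario2_ordering_and_balance(self, rng):
        for _ in range(200):
            f2 = float(rng.uniform(0.1, 100))
            f9 = float(rng.uniform(0, 75))
            r9, f10, f16, flag = scenario_flux_sampler(f2, f9, 2, rng)
            assert not flag
            assert r9 + f2 == pytest.approx(f10 + f16)
            assert r9 <= f10 and 0 < f16 <= f2

    def test_scenario2_without_f2_hits_boundary(self, rng):
        f9, f10, f16, flag = scenario_flux_sampler(0.0, 5.0, 2, rng)
        assert flag
        assert f16 <= 1e-6 and abs(f9 - f10) <= 1.1e-6


class TestParameterizeModule:
    @pytest.mark.parametrize("design", range(1, 8))
    def test_closed_cell_structure(self, rng, design):
        cfg = ScenarioConfig("closed", "slow")
        param, info = parameterize_module(design, cfg, rng)
        assert verify_steady(param) <= 1e-9
        assert param.flux_ss[0] == pytest.approx(100.0)  # f1 pinned
        assert param.flux_ss[13] == 0.0                  # f14 off
        assert is_closed(param.gamma)
        for i, name in ((1, "f2"), (2, "f3"), (3, "f4")):
            if name not in MODULE_PATHWAYS[design]:
                assert param.gamma[i] == 0.0
                assert param.flux_ss[i] == 0.0

    def test_open_scenarios_respect_ordering(self, rng):
        for design in (1, 3, 7):
            p1, i1 = parameterize_module(
                design, ScenarioConfig("open", "slow", 1), rng
            )
            if not i1["boundary"]:
                assert p1.flux_ss[8] > p1.flux_ss[9]   # f9 > f10
                assert p1.flux_ss[15] > 0
        p2, i2 = parameterize_module(
            7, ScenarioConfig("open", "slow", 2), rng
        )
        assert p2.flux_ss[8] <= p2.flux_ss[9]

    def test_bad_design_index(self, rng):
        with pytest.raises(ValueError):
            parameterize_module(0, ScenarioConfig("closed", "slow"), rng)

    def test_fair_comparison_shares_draws(self):
        """Same substream, different designs: identical control state and
        reversible-rate draws; only the apportionment differs."""
        params = {}
        for design in (1, 6, 7):
            rng = np.random.default_rng(123)
            params[design], _ = parameterize_module(
                design, ScenarioConfig("closed", "slow"), rng
            )
        s1 = params[1].state_ss
        for d in (6, 7):
            np.testing.assert_array_equal(params[d].state_ss, s1)
        # reversible fluxes f6, f8 follow the shared gamma draws + state
        np.testing.assert_allclose(
            params[6].flux_ss[[5, 7]], params[7].flux_ss[[5, 7]]
        )


class TestScenarioConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            ScenarioConfig("open", "slow")         # missing scenario
        with pytest.raises(ValueError):
            ScenarioConfig("closed", "slow", 1)    # closed has no split
        with pytest.raises(ValueError):
            ScenarioConfig("closed", "medium")


@pytest.fixture(scope="module")
def closed_slow():
    return compare_modules(ScenarioConfig("closed", "slow"), n=25, seed=9)


class TestCompareModules:

    def test_table_layout(self, closed_slow):
        assert len(closed_slow) == 7 * 25
        assert set(closed_slow.design.unique()) == set(range(1, 8))

    def test_closed_slow_similar_folds(self, closed_slow):
        s = summarize_modules(closed_slow)
        assert s.fold_mean.between(2.0, 3.8).all()

    def test_module1_slowest(self, closed_slow):
        s = summarize_modules(closed_slow).set_index("design")
        rt = (s.on_time_mean + s.off_time_mean) / 2
        assert rt.idxmax() == 1

    def test_moiety_conservation_along_closed_runs(self, rng):
        from nox1sim import integrate

        param, _ = parameterize_module(
            5, ScenarioConfig("closed", "slow"), rng
        )
        traj = integrate(
            param.state_ss, (10.0, 10.0, 1.0), param.gamma, 100,
            t_grid=np.linspace(0, 100, 11),
        )
        t0 = moiety_totals(param.state_ss)
        for row in traj.states:
            np.testing.assert_allclose(moiety_totals(row), t0, rtol=1e-6)

    def test_deterministic(self):
        cfg = ScenarioConfig("open", "fast", 1)
        a = compare_modules(cfg, n=5, seed=3, response_times=False)
        b = compare_modules(cfg, n=5, seed=3, response_times=False)
        assert a.equals(b)
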