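"""The seven recycling-module designs and their Monte-Carlo comparison.

A module design is a nonempty subset of the three recycling pathways
{f2, f3, f4}:

====== ================
1      {f2}
2      {f3}
3      {f4}
4      {f2, f3}
5      {f2, f4}
6      {f3, f4}
7      {f2, f3, f4}
====== ================

Designs are compared under an AngII-like combined S1 & S2 stimulus on a
grid of intracellular settings: closed (f16 = 0) vs open (f16 > 0)
system, slow vs fast reversible rate constants, and — in the open
system — scenario 1 (f9 > f10, net NoxA1 -> NoxA1_P conversion) vs
scenario 2 (f9 <= f10).  Proteolysis is switched off (f14 = 0, hence
f11 = f12 = f13 = 0) throughout, and the assembly flux is pinned at
f1 = 100 so differences reflect module structure, not flux magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .balance import IndependentFluxes, parameterize
from .model import IntegrationError
from .response import SignalProtocol, fold_change, on_off_protocol
from .sampling import sample_initial_state, sample_rate_constants, spawn_rngs

MODULE_PATHWAYS: dict[int, frozenset[str]] = {
    1: frozenset({"f2"}),
    2: frozenset({"f3"}),
    3: frozenset({"f4"}),
    4: frozenset({"f2", "f3"}),
    5: frozenset({"f2", "f4"}),
    6: frozenset({"f3", "f4"}),
    7: frozenset({"f2", "f3", "f4"}),
}

F1_TOTAL = 100.0
F16_MIN = 0.01
_EPS_F16 = 1e-6  # boundary fallback for structurally infeasible cells


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the comparison grid."""

    system: str = "closed"      # "closed" (f16=0) or "open" (f16>0)
    rates: str = "slow"         # gamma6/8/9 regime: "slow" or "fast"
    scenario: int | None = None  # open only: 1 (f9>f10) or 2 (f9<=f10)

    def __post_init__(self):
        if self.system not in ("closed", "open"):
            raise ValueError("system must be 'closed' or 'open'")
        if self.rates not in ("slow", "fast"):
            raise ValueError("rates must be 'slow' or 'fast'")
        if self.system == "open" and self.scenario not in (1, 2):
            raise ValueError("open system needs scenario 1 or 2")
        if self.system == "closed" and self.scenario is not None:
            raise ValueError("closed system has no scenario split")


def apportion_recycling(
    design: int, rng: np.random.Generator, mode: str = "dirichlet",
    total: float = F1_TOTAL,
) -> dict[str, float]:
    """Split the assembly flux f1 among the design's present pathways.

    ``dirichlet`` draws a flat Dirichlet split so multi-pathway modules
    explore their whole apportionment simplex; ``equal`` splits evenly
    (deterministic, used in tests).
    """
    present = sorted(MODULE_PATHWAYS[design])
    if mode == "equal":
        w = np.full(len(present), 1.0 / len(present))
    elif mode == "dirichlet":
        w = rng.dirichlet(np.ones(len(present)))
    else:
        raise ValueError("mode must be 'dirichlet' or 'equal'")
    split = {"f2": 0.0, "f3": 0.0, "f4": 0.0}
    for name, wi in zip(present, w):
        split[name] = float(wi * total)
    return split


def scenario_flux_sampler(
    f2: float,
    f9: float,
    scenario: int | None,
    rng: np.random.Generator,
) -> tuple[float, float, float, bool]:
    """Draw f16 for the scenario and derive f10 = f9 + f2 - f16.

    Returns (f9, f10, f16, boundary_flag).  The NoxA1 balance
    f9 + f2 = f10 + f16 makes scenario 1 (f9 > f10) equivalent to
    f16 > f2 and scenario 2 (f9 <= f10) to f16 <= f2.  f16 is drawn
    log10-uniformly on the feasible interval: (max(f2, F16_MIN),
    f2 + f9) for scenario 1 and (F16_MIN, f2) for scenario 2.  Closed
    cells (scenario None) set f16 = 0.  Cells whose feasible interval
    is empty — scenario 2 for designs without f2 — run at the
    f9 = f10 boundary with a vanishing f16 and are flagged.
    """
    if scenario is None:
        return f9, f9 + f2, 0.0, False
    if scenario == 1:
        hi = f2 + f9
        lo = max(f2, min(F16_MIN, 0.5 * hi))
        if lo >= hi:  # f9 ~ 0: no room above f2
            return f9, 0.0, hi, True
        u = rng.uniform(np.log10(max(lo, 1e-300)), np.log10(hi))
        f16 = 10.0 ** u
        return f9, f9 + f2 - f16, f16, False
    # scenario 2: f16 <= f2
    if f2 <= 0.0:
        # structurally infeasible at steady state: f9 = f10 + f16 > f10
        # whenever f16 > 0; fall back to the f9 ~ f10 boundary
        f16 = min(_EPS_F16, f9)
        return f9, f9 - f16, f16, True
    lo = min(F16_MIN, 1e-3 * f2)
    u = rng.uniform(np.log10(lo), np.log10(f2))
    f16 = 10.0 ** u
    return f9, f9 + f2 - f16, f16, False


def parameterize_module(
    design: int,
    scenario: ScenarioConfig,
    rng: np.random.Generator,
    apportion: str = "dirichlet",
    code: int = 1,
):
    """Build one steady-state parameterization for a module-design cell.

    The control state is drawn from initial-condition combination 1
    (free p47phox, Rac1_GDP and NoxA1 dominant, matching resting
    VSMCs); f1 = 100 is apportioned among the present recycling
    pathways; gamma6/gamma8/gamma9 are drawn from the rates regime and
    converted to fluxes at the control state; f16 follows the scenario.

    Returns ``(param, info)`` where info records the draw (gammas,
    f9/f10/f16, boundary flag).
    """
    if design not in MODULE_PATHWAYS:
        raise ValueError("design index must be 1..7")
    # state and rate constants are drawn before the design-dependent
    # apportionment so all designs see identical per-sample draws
    state = sample_initial_state(code, rng)
    g6, g8, g9 = sample_rate_constants(scenario.rates, rng)
    split = apportion_recycling(design, rng, mode=apportion)
    f6 = g6 * state[3]   # x4, p47_P
    f8 = g8 * state[5]   # x6, Rac1_GTP
    f9 = g9 * state[6]   # x7, NoxA1
    f9, f10, f16, boundary = scenario_flux_sampler(
        split["f2"], f9, scenario.scenario, rng
    )
    ind = IndependentFluxes(
        f2=split["f2"], f3=split["f3"], f4=split["f4"],
        f6=f6, f8=f8, f14=0.0, f16=f16, eighth=f9, selector="f9",
    )
    param = parameterize(ind, state)
    info = {
        "design": design, "gamma6": g6, "gamma8": g8, "gamma9": g9,
        "f9": f9, "f10": f10, "f16": f16, "boundary": boundary,
        **split,
    }
    return param, info


def compare_modules(
    scenario: ScenarioConfig,
    n: int = 2000,
    seed: int = 0,
    response_times: bool = True,
    apportion: str = "dirichlet",
    magnitude: float = 10.0,
    tol: float = 0.02,
) -> pd.DataFrame:
    """Monte-Carlo comparison of the seven designs in one grid cell.

    Every design consumes an identical per-sample random substream, so
    differences between designs reflect only the design-dependent
    apportionment — the fair-comparison contract.  Returns a tidy frame
    (design, sample, fold, on_time, off_time, flags).
    """
    protocol = SignalProtocol(("S1", "S2"), magnitude)
    rngs_seeds = np.random.SeedSequence(seed).spawn(n)
    rows = []
    for design in sorted(MODULE_PATHWAYS):
        for i, child in enumerate(rngs_seeds):
            rng = np.random.default_rng(child)
            try:
                param, info = parameterize_module(
                    design, scenario, rng, apportion=apportion
                )
                if response_times:
                    m = on_off_protocol(param, protocol, tol=tol)
                    fold, on_t, off_t = m.fold_change, m.on_time, m.off_time
                    ok = m.on_converged and m.off_converged
                else:
                    fold = fold_change(param, protocol)
                    on_t = off_t = np.nan
                    ok = np.isfinite(fold)
                failed = False
            except IntegrationError:
                fold = on_t = off_t = np.nan
                ok, failed = False, True
                info = {"boundary": False}
            rows.append(
                {"design": design, "sample": i, "fold": fold,
                 "on_time": on_t, "off_time": off_t,
                 "converged": ok, "failed": failed,
                 "boundary": info.get("boundary", False)}
            )
    return pd.DataFrame(rows)


def summarize_modules(df: pd.DataFrame) -> pd.DataFrame:
    """Per-design mean ± sd of fold change and response times."""
    ok = df[~df["failed"]]
    agg = ok.groupby("design").agg(
        fold_mean=("fold", "mean"),
        fold_sd=("fold", "std"),
        on_time_mean=("on_time", "mean"),
        on_time_sd=("on_time", "std"),
        off_time_mean=("off_time", "mean"),
        off_time_sd=("off_time", "std"),
        n=("fold", "count"),
        n_boundary=("boundary", "sum"),
    )
    return agg.reset_index()
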