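"""Functional-effectiveness criteria: responsiveness and AngII/PMA screens.

Criterion 1 profiles the steady-state fold change of X1 across the
eight initial-condition combinations and four signal sets (S1, S2, S3,
S1&S2).

Criterion 2 screens a sampled parameterization against three
semi-quantitative experimental observations in VSMCs:

1. after 4 h of AngII the total Nox1 protein (X1 + X2) is essentially
   unchanged (within a ±5% band by default);
2. after 30 min of AngII the system is at a (quasi-) steady state with
   up-regulated X1 (>= 1.1-fold by default);
3. after 30 min of PMA, X1 is up-regulated (>= 1.1-fold).

AngII enters as a combined S1 & S2 step (PKC plus GEF activation); PMA
as an S1 step alone (direct PKC activation).  Both thresholds are
implementation-declared and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .balance import (
    InfeasibleBasisError,
    SteadyStateParameterization,
    parameterize,
)
from .model import IntegrationError, integrate, make_rhs
from .response import ANGII, PMA, SignalProtocol, fold_change
from .sampling import (
    sample_flux_basis,
    sample_initial_state,
    spawn_rngs,
)

SIGNAL_SETS = {
    "S1": SignalProtocol(("S1",)),
    "S2": SignalProtocol(("S2",)),
    "S3": SignalProtocol(("S3",)),
    "S1&S2": SignalProtocol(("S1", "S2")),
}


@dataclass(frozen=True)
class ScreenSettings:
    """Tolerances and timing of the experimental-observation screens."""

    stability_tol: float = 0.05   # ±band on total Nox1 protein at 4 h
    up_tol: float = 1.1           # minimal fold counted as up-regulated
    quasi_tol: float = 0.05       # |dX1/dt| * t_short / X1 bound at 30 min
    t_short: float = 30.0         # minutes of AngII/PMA before readout
    t_long: float = 240.0         # minutes of AngII for protein stability
    magnitude: float = 10.0       # stimulus intensity for S1/S2


@dataclass
class ScreenResult:
    cond1: bool   # 4 h AngII: total Nox1 protein stable
    cond2: bool   # 30 min AngII: quasi-steady, up-regulated X1
    cond3: bool   # 30 min PMA: up-regulated X1
    failed: bool = False  # solver failure (fails every condition)

    @property
    def combined(self) -> bool:
        return self.cond1 and self.cond2 and self.cond3


def angii_screen(
    param: SteadyStateParameterization,
    settings: ScreenSettings = ScreenSettings(),
) -> tuple[bool, bool]:
    """Conditions 1 and 2 under a combined S1 & S2 (AngII) step."""
    signals = SignalProtocol(("S1", "S2"), settings.magnitude).vector()
    grid = np.array([0.0, settings.t_short, settings.t_long])
    traj = integrate(param.state_ss, signals, param.gamma, settings.t_long,
                     t_grid=grid)
    x30, x240 = traj.states[1], traj.states[2]

    total0 = param.state_ss[0] + param.state_ss[1]
    total240 = x240[0] + x240[1]
    cond1 = abs(total240 - total0) / total0 <= settings.stability_tol

    rhs = make_rhs(param.gamma, signals)
    dx1 = rhs(settings.t_short, x30)[0]
    x1_30 = x30[0]
    quasi = (
        x1_30 > 0
        and abs(dx1) * settings.t_short / x1_30 < settings.quasi_tol
    )
    up = x1_30 / param.state_ss[0] >= settings.up_tol
    return bool(cond1), bool(quasi and up)


def pma_screen(
    param: SteadyStateParameterization,
    settings: ScreenSettings = ScreenSettings(),
) -> bool:
    """Condition 3 under an S1-only (PMA) step."""
    signals = SignalProtocol(("S1",), settings.magnitude).vector()
    grid = np.array([0.0, settings.t_short])
    traj = integrate(param.state_ss, signals, param.gamma, settings.t_short,
                     t_grid=grid)
    return bool(traj.states[1][0] / param.state_ss[0] >= settings.up_tol)


def screen_parameterization(
    param: SteadyStateParameterization,
    settings: ScreenSettings = ScreenSettings(),
) -> ScreenResult:
    """Run all three screens; solver failure fails every condition."""
    try:
        c1, c2 = angii_screen(param, settings)
        c3 = pma_screen(param, settings)
    except IntegrationError:
        return ScreenResult(False, False, False, failed=True)
    return ScreenResult(c1, c2, c3)


def responsiveness_profile(
    n_per_cell: int = 2000,
    seed: int = 0,
    log10_range: tuple[float, float] = (0.0, 2.0),
    f14_zero: bool = True,
    magnitude: float = 10.0,
    codes=range(1, 9),
    signal_sets=tuple(SIGNAL_SETS),
) -> pd.DataFrame:
    """Fold-change distributions over codes x signal sets (criterion 1).

    Each cell draws its own initial states and flux bases; returns a
    tidy frame with one row per sample.
    """
    codes = list(codes)
    signal_sets = list(signal_sets)
    rows = []
    rngs = spawn_rngs(seed, len(codes) * len(signal_sets) * n_per_cell)
    k = 0
    for code in codes:
        for name in signal_sets:
            protocol = SignalProtocol(SIGNAL_SETS[name].signals, magnitude)
            for i in range(n_per_cell):
                rng = rngs[k]
                k += 1
                state = sample_initial_state(code, rng)
                basis = sample_flux_basis(rng, log10_range, f14_zero=f14_zero)
                param = parameterize(basis, state)
                try:
                    fc = fold_change(param, protocol)
                    ok = True
                except IntegrationError:
                    fc, ok = np.nan, False
                rows.append(
                    {"code": code, "signal_set": name, "sample": i,
                     "fold": fc, "converged": ok}
                )
    return pd.DataFrame(rows)


def summarize_profile(df: pd.DataFrame) -> pd.DataFrame:
    """Box-and-whisker summaries (min/quartiles/max/mean) per cell."""
    g = df.dropna(subset=["fold"]).groupby(["code", "signal_set"])["fold"]
    return g.agg(["min", lambda s: s.quantile(0.25), "median",
                  lambda s: s.quantile(0.75), "max", "mean", "count"]
                 ).rename(columns={"<lambda_0>": "q25", "<lambda_1>": "q75"}
                          ).reset_index()


def screening_ensemble(
    n: int = 10000,
    seed: int = 0,
    log10_range: tuple[float, float] = (-2.0, 2.0),
    code: int = 1,
    settings: ScreenSettings = ScreenSettings(),
) -> pd.DataFrame:
    """Sample flux bases and screen each against the three observations.

    Returns one row per sample with the independent fluxes, the derived
    flux-plane coordinates and the screen flags.
    """
    rngs = spawn_rngs(seed, n)
    rows = []
    for i, rng in enumerate(rngs):
        state = sample_initial_state(code, rng)
        basis = sample_flux_basis(rng, log10_range, f14_zero=False)
        param = parameterize(basis, state)
        res = screen_parameterization(param, settings)
        f = param.flux_ss
        rows.append(
            {
                "sample": i,
                "f2": f[1], "f3": f[2], "f4": f[3], "f14": f[13],
                "recycling": f[1] + f[2] + f[3],
                "cond1": res.cond1, "cond2": res.cond2, "cond3": res.cond3,
                "combined": res.combined, "failed": res.failed,
            }
        )
    return pd.DataFrame(rows)


def flux_distribution_summary(retained: pd.DataFrame, bins: int = 40) -> dict:
    """Histograms and log-separation of retained recycling vs proteolysis.

    Reports per-flux log10 histograms, the mean log10 separation
    between the summed recycling flux and the proteolytic flux, and the
    ratio of their arithmetic means.
    """
    if len(retained) == 0:
        return {"n_retained": 0}
    out = {"n_retained": int(len(retained))}
    log_rec = np.log10(retained["recycling"])
    log_prot = np.log10(retained["f14"])
    out["mean_log10_recycling"] = float(log_rec.mean())
    out["mean_log10_proteolysis"] = float(log_prot.mean())
    out["log10_separation"] = float(log_rec.mean() - log_prot.mean())
    out["mean_flux_ratio"] = float(
        retained["recycling"].mean() / retained["f14"].mean()
    )
    out["histograms"] = {}
    for col in ("f2", "f3", "f4", "f14", "recycling"):
        counts, edges = np.histogram(np.log10(retained[col]), bins=bins)
        out["histograms"][col] = {
            "counts": counts.tolist(), "edges": edges.tolist()
        }
    return out
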