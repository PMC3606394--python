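"""Steady-state flux balance and rate-constant back-derivation.

At the unstimulated Ready-to-Respond State (RtRS) all eight time
derivatives vanish, which forces eight linear identities among the
sixteen fluxes:

    f1 = f2 + f3 + f4 + f14          (assembly balances disassembly)
    f5 = f3 + f6 + f14               (p47 pool)
    f7 = f4 + f8 + f14               (Rac1 pool)
    f9 + f2 = f10 + f16              (NoxA1 pool)
    f11 = f12 = f13 = f14            (influxes balance proteolysis)
    f15 = f14 + f16

so a steady flux distribution has eight degrees of freedom.  We use the
basis f2, f3, f4, f6, f8, f14, f16 plus one of {f9, f10}; given a full
flux vector and the steady state, every rate constant follows by
dividing the flux by its mass-action monomial at control signals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .model import (
    CONTROL_SIGNALS,
    N_FLUXES,
    N_STATES,
    evaluate_fluxes,
    time_derivative,
    _as_array,
)


class InfeasibleBasisError(ValueError):
    """An independent-flux basis whose completion needs a negative flux."""


class DegenerateStateError(ValueError):
    """A nonzero flux paired with a zero-valued mass-action monomial."""


@dataclass(frozen=True)
class IndependentFluxes:
    """The eight-flux basis of the steady-state balance.

    ``eighth`` holds the sampled member of {f9, f10} and ``selector``
    says which one it is; the partner is derived from
    ``f9 + f2 = f10 + f16``.
    """

    f2: float
    f3: float
    f4: float
    f6: float
    f8: float
    f14: float
    f16: float
    eighth: float
    selector: str = "f9"

    def __post_init__(self):
        if self.selector not in ("f9", "f10"):
            raise ValueError("selector must be 'f9' or 'f10'")
        for name in ("f2", "f3", "f4", "f6", "f8", "f14", "f16", "eighth"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")


def select_eighth_flux(f2: float, f16: float) -> str:
    """Choose which of f9/f10 to sample so its partner is always feasible.

    The NoxA1 balance gives f10 = f9 + (f2 - f16) and
    f9 = f10 + (f16 - f2).  Sampling f9 when f2 >= f16 (and f10
    otherwise) makes the derived partner the sampled value plus a
    non-negative offset, so any non-negative sample yields a feasible
    steady flux distribution.
    """
    if f2 < 0 or f16 < 0:
        raise ValueError("fluxes must be non-negative")
    return "f9" if f2 >= f16 else "f10"


def complete_fluxes(ind: IndependentFluxes) -> np.ndarray:
    """Expand an eight-flux basis into the full 16-flux steady vector."""
    f = np.zeros(N_FLUXES)
    f[1], f[2], f[3] = ind.f2, ind.f3, ind.f4
    f[5], f[7] = ind.f6, ind.f8
    f[13], f[15] = ind.f14, ind.f16
    f[0] = ind.f2 + ind.f3 + ind.f4 + ind.f14
    f[4] = ind.f3 + ind.f6 + ind.f14
    f[6] = ind.f4 + ind.f8 + ind.f14
    f[10] = f[11] = f[12] = ind.f14
    f[14] = ind.f14 + ind.f16
    if ind.selector == "f9":
        f[8] = ind.eighth
        f[9] = ind.eighth + ind.f2 - ind.f16
        if f[9] < 0:
            raise InfeasibleBasisError(
                f"derived f10 = {f[9]:.6g} < 0 (f9={ind.eighth:.6g}, "
                f"f2={ind.f2:.6g}, f16={ind.f16:.6g})"
            )
    else:
        f[9] = ind.eighth
        f[8] = ind.eighth + ind.f16 - ind.f2
        if f[8] < 0:
            raise InfeasibleBasisError(
                f"derived f9 = {f[8]:.6g} < 0 (f10={ind.eighth:.6g}, "
                f"f2={ind.f2:.6g}, f16={ind.f16:.6g})"
            )
    return f


# mass-action monomial of each flux at unit signals; constant influxes -> 1
def _monomials(state) -> np.ndarray:
    x1, x2, x3, x4, x5, x6, x7, x8 = state
    return np.array(
        [
            x2 * x4 * x6 * x7,
            x1, x1, x1,
            x3, x4, x5, x6, x7, x8,
            1.0, 1.0, 1.0,
            x1,
            1.0,
            x8,
        ]
    )


def derive_rate_constants(flux_ss, state_ss) -> np.ndarray:
    """Rate constants making ``state_ss`` an exact control steady state.

    gamma_i = f_i / monomial_i(state_ss) at S = (1, 1, 1); constant
    influxes take gamma = f directly.
    """
    f = _as_array(flux_ss, N_FLUXES, "flux_ss")
    x = _as_array(state_ss, N_STATES, "state_ss")
    if np.any(f < 0):
        raise ValueError("fluxes must be non-negative")
    mono = _monomials(x)
    gamma = np.zeros(N_FLUXES)
    for i in range(N_FLUXES):
        if f[i] == 0.0:
            continue
        if mono[i] == 0.0:
            raise DegenerateStateError(
                f"flux f{i + 1}={f[i]:.6g} requires a nonzero monomial "
                f"but the state factor is zero"
            )
        gamma[i] = f[i] / mono[i]
    return gamma


@dataclass
class SteadyStateParameterization:
    """A control steady state with its rate constants and fluxes."""

    state_ss: np.ndarray
    gamma: np.ndarray
    flux_ss: np.ndarray
    provenance: dict = None

    def __post_init__(self):
        self.state_ss = _as_array(self.state_ss, N_STATES, "state_ss")
        self.gamma = _as_array(self.gamma, N_FLUXES, "gamma")
        self.flux_ss = _as_array(self.flux_ss, N_FLUXES, "flux_ss")

    def to_json(self) -> str:
        return json.dumps(
            {
                "state_ss": self.state_ss.tolist(),
                "gamma": self.gamma.tolist(),
                "flux_ss": self.flux_ss.tolist(),
                "provenance": self.provenance or {},
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SteadyStateParameterization":
        d = json.loads(text)
        return cls(
            state_ss=d["state_ss"],
            gamma=d["gamma"],
            flux_ss=d["flux_ss"],
            provenance=d.get("provenance") or None,
        )


def verify_steady(
    param: SteadyStateParameterization, floor: float = 1e-6
) -> float:
    """Max relative derivative magnitude at the stored steady state."""
    dx = time_derivative(param.state_ss, CONTROL_SIGNALS, param.gamma)
    denom = np.maximum(np.abs(param.state_ss), floor)
    return float(np.max(np.abs(dx) / denom))


def parameterize(
    ind: IndependentFluxes, state_ss, provenance: dict | None = None
) -> SteadyStateParameterization:
    """Basis + state -> a verified steady-state parameterization."""
    flux = complete_fluxes(ind)
    gamma = derive_rate_constants(flux, state_ss)
    param = SteadyStateParameterization(
        state_ss=state_ss, gamma=gamma, flux_ss=flux, provenance=provenance
    )
    # round trip must close: the rate laws reproduce the target fluxes
    back = evaluate_fluxes(param.state_ss, CONTROL_SIGNALS, gamma)
    if not np.allclose(back, flux, rtol=1e-12, atol=1e-12):
        raise RuntimeError("rate-constant derivation failed to round-trip")
    return param
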