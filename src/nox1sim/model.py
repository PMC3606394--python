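"""Mass-action reaction network for Nox1 assembly/disassembly in VSMCs.

The model tracks eight species:

==== ==================================================
x1   active Nox1 complex (Nox1_active)
x2   membrane-bound Nox1/p22phox
x3   free p47phox
x4   phosphorylated p47phox (p47phox_P)
x5   GDP-bound Rac1 (Rac1_GDP)
x6   GTP-bound Rac1 (Rac1_GTP)
x7   NoxA1
x8   phosphorylated NoxA1 (NoxA1_P)
==== ==================================================

connected by sixteen mass-action fluxes: complex assembly (f1), three
subunit-recycling disassembly routes (f2 returns NoxA1_P, f3 returns
unphosphorylated p47phox, f4 returns Rac1_GDP), the reversible
activation/deactivation reactions of the three cytosolic subunits
(f5/f6, f7/f8, f9/f10), constant influxes (f11, f12, f13, f15),
proteolytic degradation of the active complex (f14) and degradation of
NoxA1_P (f16).  Three dimensionless signals drive the activating
reactions: S1 (p47phox phosphorylation, e.g. PKC), S2 (Rac1 activation
via GEFs) and S3 (NoxA1 phosphorylation, e.g. PKA).  All signals sit at
1 under control conditions; a value above 1 is a stimulus.

The dynamics are ``dx/dt = N @ F(x, S, gamma)`` with ``N`` the fixed
8x16 stoichiometry matrix and ``F`` the vector of mass-action rate laws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import odeint

N_STATES = 8
N_FLUXES = 16

STATE_NAMES = (
    "Nox1_active",
    "Nox1_p22",
    "p47",
    "p47_P",
    "Rac1_GDP",
    "Rac1_GTP",
    "NoxA1",
    "NoxA1_P",
)

#: indices (0-based) of the exchange fluxes that open the system
EXCHANGE_FLUXES = (10, 11, 12, 13, 14, 15)  # f11, f12, f13, f14, f15, f16

#: moiety pools conserved when the system is closed: each row collects
#: the species sharing one subunit moiety (Nox1/p22, p47, Rac1, NoxA1)
MOIETY_MATRIX = np.array(
    [
        [1, 1, 0, 0, 0, 0, 0, 0],
        [1, 0, 1, 1, 0, 0, 0, 0],
        [1, 0, 0, 0, 1, 1, 0, 0],
        [1, 0, 0, 0, 0, 0, 1, 1],
    ],
    dtype=float,
)

CONTROL_SIGNALS = (1.0, 1.0, 1.0)


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the solver diagnostics."""


def build_stoichiometry() -> np.ndarray:
    """Return the fixed 8x16 stoichiometry matrix.

    Columns are fluxes f1..f16, rows are species x1..x8.  Assembly (f1)
    consumes Nox1/p22, p47_P, Rac1_GTP and NoxA1; each recycling route
    (f2, f3, f4) dissociates the complex back into Nox1/p22 plus the
    three cytosolic subunits, returning exactly one of them in its
    inactive form (f2 -> NoxA1_P, f3 -> p47, f4 -> Rac1_GDP) and the
    other two in the forms that entered the complex.
    """
    N = np.zeros((N_STATES, N_FLUXES), dtype=int)

    def rxn(j, consumed=(), produced=()):
        for i in consumed:
            N[i - 1, j - 1] -= 1
        for i in produced:
            N[i - 1, j - 1] += 1

    rxn(1, consumed=(2, 4, 6, 7), produced=(1,))     # assembly
    rxn(2, consumed=(1,), produced=(2, 4, 6, 8))     # recycle, NoxA1_P out
    rxn(3, consumed=(1,), produced=(2, 3, 6, 7))     # recycle, p47 out
    rxn(4, consumed=(1,), produced=(2, 4, 5, 7))     # recycle, Rac1_GDP out
    rxn(5, consumed=(3,), produced=(4,))             # p47 phosphorylation (S1)
    rxn(6, consumed=(4,), produced=(3,))             # p47_P dephosphorylation
    rxn(7, consumed=(5,), produced=(6,))             # Rac1 activation (S2)
    rxn(8, consumed=(6,), produced=(5,))             # Rac1_GTP deactivation
    rxn(9, consumed=(7,), produced=(8,))             # NoxA1 phosphorylation (S3)
    rxn(10, consumed=(8,), produced=(7,))            # NoxA1_P dephosphorylation
    rxn(11, produced=(2,))                           # Nox1/p22 influx
    rxn(12, produced=(3,))                           # p47 influx
    rxn(13, produced=(5,))                           # Rac1_GDP influx
    rxn(14, consumed=(1,))                           # proteolysis of complex
    rxn(15, produced=(7,))                           # NoxA1 influx
    rxn(16, consumed=(8,))                           # NoxA1_P degradation
    return N


_N = build_stoichiometry()
_N_FLOAT = _N.astype(float)


def _as_array(x, n, name):
    arr = np.asarray(x, dtype=float).reshape(-1)
    if arr.size != n:
        raise ValueError(f"{name} must have {n} entries, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


def evaluate_fluxes(state, signals, gamma) -> np.ndarray:
    """Evaluate the sixteen mass-action rate laws.

    f1 = g1*x2*x4*x6*x7, f2..f4 and f14 are first order in x1, the
    reversible pairs are first order in their substrate (the forward
    reactions scaled by their signal), f11/f12/f13/f15 are constant
    influxes and f16 = g16*x8.
    """
    x = _as_array(state, N_STATES, "state")
    g = _as_array(gamma, N_FLUXES, "gamma")
    s = _as_array(signals, 3, "signals")
    if np.any(s <= 0):
        raise ValueError("signals must be positive")
    x1, x2, x3, x4, x5, x6, x7, x8 = x
    s1, s2, s3 = s
    return np.array(
        [
            g[0] * x2 * x4 * x6 * x7,
            g[1] * x1,
            g[2] * x1,
            g[3] * x1,
            g[4] * x3 * s1,
            g[5] * x4,
            g[6] * x5 * s2,
            g[7] * x6,
            g[8] * x7 * s3,
            g[9] * x8,
            g[10],
            g[11],
            g[12],
            g[13] * x1,
            g[14],
            g[15] * x8,
        ]
    )


def time_derivative(state, signals, gamma) -> np.ndarray:
    """Right-hand side of the ODE system, ``N @ F``."""
    return _N_FLOAT @ evaluate_fluxes(state, signals, gamma)


def make_rhs(gamma, signals):
    """Build a fast scalar-arithmetic RHS closure ``f(t, x)``.

    Algebraically identical to :func:`time_derivative`; used by the
    integrator and root finder where per-call overhead matters.
    """
    g = _as_array(gamma, N_FLUXES, "gamma")
    s = _as_array(signals, 3, "signals")
    g1, g2, g3, g4, g5, g6, g7, g8, g9, g10, g11, g12, g13, g14, g15, g16 = g
    s1, s2, s3 = s
    g5s, g7s, g9s = g5 * s1, g7 * s2, g9 * s3

    def rhs(t, x):
        x1, x2, x3, x4, x5, x6, x7, x8 = x
        f1 = g1 * x2 * x4 * x6 * x7
        f2 = g2 * x1
        f3 = g3 * x1
        f4 = g4 * x1
        f5 = g5s * x3
        f6 = g6 * x4
        f7 = g7s * x5
        f8 = g8 * x6
        f9 = g9s * x7
        f10 = g10 * x8
        f14 = g14 * x1
        f16 = g16 * x8
        return (
            f1 - f2 - f3 - f4 - f14,
            -f1 + f2 + f3 + f4 + g11,
            f3 - f5 + f6 + g12,
            -f1 + f2 + f4 + f5 - f6,
            f4 - f7 + f8 + g13,
            -f1 + f2 + f3 + f7 - f8,
            -f1 + f3 + f4 - f9 + f10 + g15,
            f2 + f9 - f10 - f16,
        )

    return rhs


def make_jacobian(gamma, signals):
    """Analytic Jacobian ``J(t, x)`` of the RHS (8x8)."""
    g = _as_array(gamma, N_FLUXES, "gamma")
    s = _as_array(signals, 3, "signals")

    def jac(t, x):
        x1, x2, x3, x4, x5, x6, x7, x8 = x
        JF = np.zeros((N_FLUXES, N_STATES))
        JF[0, 1] = g[0] * x4 * x6 * x7
        JF[0, 3] = g[0] * x2 * x6 * x7
        JF[0, 5] = g[0] * x2 * x4 * x7
        JF[0, 6] = g[0] * x2 * x4 * x6
        JF[1, 0] = g[1]
        JF[2, 0] = g[2]
        JF[3, 0] = g[3]
        JF[4, 2] = g[4] * s[0]
        JF[5, 3] = g[5]
        JF[6, 4] = g[6] * s[1]
        JF[7, 5] = g[7]
        JF[8, 6] = g[8] * s[2]
        JF[9, 7] = g[9]
        JF[13, 0] = g[13]
        JF[15, 7] = g[15]
        return _N_FLOAT @ JF

    return jac


def conservation_laws(gamma) -> np.ndarray:
    """Conserved linear combinations of the states for given rates.

    Returns a (k, 8) matrix whose rows span the left null space of the
    stoichiometry restricted to reactions with nonzero rate constants:
    v @ dx/dt = 0 identically for every row v.  In the fully closed
    system these are the four subunit-moiety totals; with proteolysis
    off but NoxA1_P degradation on, three of them survive.
    """
    from scipy.linalg import null_space

    g = np.asarray(gamma, dtype=float)
    active = np.nonzero(g != 0)[0]
    if active.size == 0:
        return np.eye(N_STATES)
    ns = null_space(_N_FLOAT[:, active].T)
    return ns.T


def is_closed(gamma, tol: float = 0.0) -> bool:
    """True when every exchange flux constant (g11..g16) is (near) zero."""
    g = np.asarray(gamma, dtype=float)
    return bool(np.all(np.abs(g[list(EXCHANGE_FLUXES)]) <= tol))


def moiety_totals(state) -> np.ndarray:
    """The four subunit-pool totals conserved in the closed system."""
    return MOIETY_MATRIX @ np.asarray(state, dtype=float)


@dataclass
class Trajectory:
    """Time grid plus states from a single integration."""

    t: np.ndarray
    states: np.ndarray  # shape (len(t), 8)
    success: bool = True
    message: str = ""

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]

    def __post_init__(self):
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")


def integrate(
    state0,
    signals,
    gamma,
    t_end: float,
    t_grid=None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    neg_tol: float = 1e-6,
) -> Trajectory:
    """Integrate the network ODE with LSODA (stiffness-switching).

    Parameters
    ----------
    state0, signals, gamma
        Initial state, signal intensities and rate constants.
    t_end
        Final time (one model time unit is interpreted as one minute).
    t_grid
        Optional explicit output grid (must start at 0).
    neg_tol
        Integrated states more negative than ``-neg_tol`` (relative to
        the state scale) raise; smaller undershoots are clipped to 0.
    """
    x0 = _as_array(state0, N_STATES, "state0")
    if np.any(x0 < 0):
        raise ValueError("state0 must be non-negative")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if t_grid is None:
        t_grid = np.array([0.0, float(t_end)])
    else:
        t_grid = np.asarray(t_grid, dtype=float)
        if t_grid[0] != 0.0:
            raise ValueError("t_grid must start at 0")

    rhs = make_rhs(gamma, signals)
    jac = make_jacobian(gamma, signals)
    states, info = odeint(
        rhs,
        x0,
        t_grid,
        Dfun=jac,
        tfirst=True,
        rtol=rtol,
        atol=atol,
        full_output=True,
        mxstep=100000,
    )
    if info["message"] != "Integration successful.":
        raise IntegrationError(
            f"ODE integration failed: {info['message']} "
            f"(reached t={info['tcur'][-1]:.4g} of {t_end:.4g})"
        )
    scale = max(np.max(np.abs(x0)), 1.0)
    if np.min(states) < -neg_tol * scale:
        raise IntegrationError(
            f"integrated state fell below tolerance: min={np.min(states):.3g}"
        )
    np.clip(states, 0.0, None, out=states)
    return Trajectory(t=t_grid, states=states)
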