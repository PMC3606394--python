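"""Seeded Monte-Carlo sampling of initial conditions, fluxes and rates.

Initial subunit distributions
-----------------------------
Each cytosolic subunit pair (p47phox/p47phox_P, Rac1_GDP/Rac1_GTP,
NoxA1/NoxA1_P) sums to a fixed total of 100 (arbitrary units).  The
active-form amount is drawn from one of two truncated Gaussians:

* code bit 0 ("inactive dominant"): N(25, 5), draws <= 5 set to 5 and
  draws > 50 set to 50, so the support is [5, 50];
* code bit 1 ("active dominant"): N(75, 5), draws <= 50 set to 50 and
  draws > 95 set to 95, so the support is [50, 95].

The bit triple (p47_P, Rac1_GTP, NoxA1_P) indexes eight initial-
condition combinations, numbered 1..8 in binary order (1 = 000,
8 = 111).

Fluxes and rate constants
-------------------------
Independent steady-state fluxes are sampled log10-uniformly (U(0, 2)
for the responsiveness analysis, U(-2, 2) for the experimental-
observation screens).  The reversible-reaction rate constants gamma6,
gamma8, gamma9 used in the module-design comparisons are uniform on
(0, 1) ("slow") or (10, 100) ("fast").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .balance import IndependentFluxes, select_eighth_flux

PAIR_TOTAL = 100.0
X1_NOMINAL = 10.0
X2_NOMINAL = 100.0
SIGNAL_MAGNITUDE = 10.0

#: truncated-Gaussian parameters per code bit: (mean, lower, upper)
_BIT_PARAMS = {0: (25.0, 5.0, 50.0), 1: (75.0, 50.0, 95.0)}
_SIGMA = 5.0


def code_bits(index: int) -> tuple[int, int, int]:
    """Bit triple (p47_P, Rac1_GTP, NoxA1_P) for combination 1..8."""
    if not 1 <= index <= 8:
        raise ValueError("combination index must be in 1..8")
    b = index - 1
    return ((b >> 2) & 1, (b >> 1) & 1, b & 1)


def sample_active_fraction(bit: int, rng: np.random.Generator,
                           sigma: float = _SIGMA) -> float:
    """One clamped truncated-Gaussian draw of an active-form amount."""
    mean, lo, hi = _BIT_PARAMS[bit]
    x = rng.normal(mean, sigma)
    if x <= lo:
        return lo
    if x > hi:
        return hi
    return float(x)


def sample_initial_state(
    index: int,
    rng: np.random.Generator,
    x1_ss: float = X1_NOMINAL,
    x2_ss: float = X2_NOMINAL,
    pair_total: float = PAIR_TOTAL,
) -> np.ndarray:
    """Draw a full 8-species state for one combination code.

    The active forms x4, x6, x8 follow the code bits; their partners
    x3, x5, x7 complete each pair to ``pair_total``; the complex pools
    x1, x2 sit at their configured nominal values.
    """
    b4, b6, b8 = code_bits(index)
    x4 = sample_active_fraction(b4, rng)
    x6 = sample_active_fraction(b6, rng)
    x8 = sample_active_fraction(b8, rng)
    return np.array(
        [x1_ss, x2_ss,
         pair_total - x4, x4,
         pair_total - x6, x6,
         pair_total - x8, x8]
    )


def sample_flux_basis(
    rng: np.random.Generator,
    log10_range: tuple[float, float] = (0.0, 2.0),
    f14_zero: bool = False,
) -> IndependentFluxes:
    """Draw the eight independent fluxes log10-uniformly.

    The eighth flux is f9 or f10 per :func:`select_eighth_flux`, which
    guarantees a feasible (fully non-negative) completion for every
    draw.  With ``f14_zero`` the proteolytic flux is pinned to 0 (the
    regime that sensitizes the system's responsiveness); the influxes
    f11..f13 then vanish with it through the balance identities.
    """
    lo, hi = log10_range
    if not lo < hi:
        raise ValueError("log10_range must satisfy lo < hi")
    u = rng.uniform(lo, hi, size=8)
    vals = 10.0 ** u
    f2, f3, f4, f6, f8 = vals[0], vals[1], vals[2], vals[3], vals[4]
    f14 = 0.0 if f14_zero else vals[5]
    f16 = vals[6]
    selector = select_eighth_flux(f2, f16)
    return IndependentFluxes(
        f2=f2, f3=f3, f4=f4, f6=f6, f8=f8, f14=f14, f16=f16,
        eighth=vals[7], selector=selector,
    )


def sample_rate_constants(
    mode: str, rng: np.random.Generator
) -> tuple[float, float, float]:
    """Draw (gamma6, gamma8, gamma9): slow ~ U(0,1), fast ~ U(10,100)."""
    if mode == "slow":
        lo, hi = 0.0, 1.0
    elif mode == "fast":
        lo, hi = 10.0, 100.0
    else:
        raise ValueError("mode must be 'slow' or 'fast'")
    g = rng.uniform(lo, hi, size=3)
    return float(g[0]), float(g[1]), float(g[2])


@dataclass
class SamplingConfig:
    """Ensemble-level sampling settings."""

    n_samples: int = 2000
    seed: int = 0
    flux_log10_range: tuple[float, float] = (0.0, 2.0)
    rate_mode: str = "slow"
    pair_total: float = PAIR_TOTAL
    x1_ss: float = X1_NOMINAL
    x2_ss: float = X2_NOMINAL
    signal_magnitude: float = SIGNAL_MAGNITUDE

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic per-sample substreams from one root seed.

    Substreams depend only on (seed, sample index), so ensembles are
    reproducible regardless of execution order or worker count.
    """
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]
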