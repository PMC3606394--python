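import numpy as np
import pytest

from nox1sim import (
    parameterize,
    sample_flux_basis,
    sample_initial_state,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def make_param(rng):
    """Factory for random flux-balance parameterizations."""

    def _make(code=1, log10_range=(0.0, 2.0), f14_zero=False, closed=False):
        state = sample_initial_state(code, rng)
        basis = sample_flux_basis(rng, log10_range, f14_zero=f14_zero)
        if closed:
            from nox1sim import IndependentFluxes

            basis = IndependentFluxes(
                f2=basis.f2, f3=basis.f3, f4=basis.f4,
                f6=basis.f6, f8=basis.f8, f14=0.0, f16=0.0,
                eighth=basis.eighth, selector="f9",
            )
        return parameterize(basis, state)

    return _make
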