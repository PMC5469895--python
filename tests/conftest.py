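import numpy as np
import pytest

from spindlesim.model_core import FiberParameters


def random_fiber_params(rng: np.random.Generator, a_exp: float | None = None
                        ) -> FiberParameters:
    """Draw a fiber parameter set from documented physiological ranges."""
    return FiberParameters(
        k_sr=rng.uniform(5.0, 15.0),
        k_pr=rng.uniform(0.1, 0.5),
        beta0=rng.uniform(0.05, 0.3),
        beta1=rng.uniform(0.0, 0.3),
        beta2=0.0,
        gamma1=rng.uniform(0.0, 0.1),
        gamma2=rng.uniform(0.0, 0.1),
        c_damp=1.0,
        r_thresh=0.46,
        a_exp=a_exp if a_exp is not None else rng.uniform(0.3, 1.0),
        l0_sr=0.04,
        l0_pr=0.76,
        ln_sr=rng.uniform(0.04, 0.06),
        ln_pr=rng.uniform(0.85, 0.92),
        g_gain=rng.uniform(50.0, 20000.0),
        x_frac=rng.uniform(0.0, 1.0),
        l_secondary=0.04,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)
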