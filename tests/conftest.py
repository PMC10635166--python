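import numpy as np
import pytest

import flashspheroid as fs


@pytest.fixture(scope="session")
def fig1_bundle():
    """Canonical spheroid parameterization (S_ROD = 160 mmHg/s, tumor Sm)."""
    return fs.preset("fig1")


@pytest.fixture(scope="session")
def fig1_profile(fig1_bundle):
    model, _, _ = fig1_bundle
    return fs.solve_steady_oxygen(model)


@pytest.fixture()
def flat_profile():
    """Synthetic uniform-tension profile (100 mmHg everywhere, no core).

    Not a solution of the diffusion problem; used to exercise the depletion,
    ROS and survival layers with a known, simple oxygen field.
    """
    def make(ps_value: float = 100.0, H: float = 6.0, R: float = 0.5):
        r = np.linspace(0.0, H, 601)
        return fs.OxygenProfile(r_grid=r, ps=np.full_like(r, ps_value),
                                r0=0.0, R=R, H=H)
    return make
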