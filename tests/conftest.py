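import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cholbench import MembraneGeometry
from cholbench.synthetic import gen_finite_size_series, gen_sdp_density

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geometry() -> MembraneGeometry:
    """Pure-POPC-like box geometry: L_z = 10 nm, h = 4 nm, so H = 3 nm."""
    return MembraneGeometry(L_z=10.0, h=4.0, T=298.0, mu_f=0.3228)


@pytest.fixture(scope="session")
def noiseless_series(geometry):
    """Noise-free D_PBC(L) series generated with d_inf = 10, mu_m = 80."""
    series, truth = gen_finite_size_series(
        d_inf=10.0, mu_m=80.0, geom=geometry, L_list=[4.5, 9.2, 18.3]
    )
    return series, truth


@pytest.fixture(scope="session")
def sdp_profile():
    """Default SDP-style synthetic density (headgroup peaks at +-1.9 nm)."""
    return gen_sdp_density()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
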