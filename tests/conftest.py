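import numpy as np
import pytest

from bmgrowth.beta_estimators import ThreePointRecord
from bmgrowth.growth_laws import VonBertalanffyParams, vb_volume


@pytest.fixture
def exponential_record() -> ThreePointRecord:
    """Exact exponential doubling: beta = 1."""
    return ThreePointRecord(t0=0, t1=1, t2=2, V0=1, V1=2, V2=4)


@pytest.fixture
def cubic_record() -> ThreePointRecord:
    """V = t^3 sampled at t = 1, 2, 3: beta = 2/3."""
    return ThreePointRecord(t0=1, t1=2, t2=3, V0=1, V1=8, V2=27)


def record_from_params(params: VonBertalanffyParams, times) -> ThreePointRecord:
    t = np.asarray(times, dtype=float)
    v = vb_volume(params, t)
    return ThreePointRecord(t0=t[0], t1=t[1], t2=t[2], V0=v[0], V1=v[1], V2=v[2])


@pytest.fixture
def superexponential_record() -> ThreePointRecord:
    """Noiseless record from the closed form with beta = 1.5."""
    return record_from_params(
        VonBertalanffyParams(V0=0.5, t0=0.0, alpha=0.01, beta=1.5), [0.0, 90.0, 180.0]
    )
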