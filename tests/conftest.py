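import numpy as np
import pytest

from rknmpc.ring import RingSpec
from rknmpc.runtime import Session, SessionConfig


@pytest.fixture
def spec64() -> RingSpec:
    return RingSpec(64, 20)


@pytest.fixture
def spec8() -> RingSpec:
    return RingSpec(8, 2)


@pytest.fixture
def run_mpc():
    """Run a circuit on an in-process three-party session.

    Returns ``(out0, out1, session)``; seeds default to fixed values so
    every test is reproducible.
    """

    def _run(circuit, n=64, f=20, *, common_seed=101, p0_seed=102,
             p1_seed=103, helper_seed=104, record=False, transport="inprocess",
             endpoints=None):
        config = SessionConfig(
            n=n, f=f, transport=transport, endpoints=endpoints or {},
            common_seed=common_seed, p0_seed=p0_seed, p1_seed=p1_seed,
            helper_seed=helper_seed, record=record,
        )
        session = Session(config)
        out0, out1 = session.run(circuit)
        return out0, out1, session

    return _run


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
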