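import numpy as np
import pytest

from contranet.connectors import ConnectorType, SubunitKind, SystemSpec


@pytest.fixture
def motor_type() -> ConnectorType:
    return ConnectorType((SubunitKind.PLUS_MOTOR, SubunitKind.PLUS_MOTOR), name="motor")


@pytest.fixture
def crosslinker_type() -> ConnectorType:
    return ConnectorType((SubunitKind.SIDE_BINDER, SubunitKind.SIDE_BINDER), name="crosslinker")


@pytest.fixture
def actomyosin_system(motor_type, crosslinker_type) -> SystemSpec:
    """Bifunctional motors + passive crosslinkers, the canonical gel."""
    return SystemSpec((motor_type, crosslinker_type))


@pytest.fixture
def end_binder_system() -> SystemSpec:
    """Two motor/end-binder connector types (six-configuration census)."""
    a = ConnectorType((SubunitKind.PLUS_MOTOR, SubunitKind.MINUS_END_BINDER))
    b = ConnectorType((SubunitKind.PLUS_MOTOR, SubunitKind.PLUS_END_BINDER))
    return SystemSpec((a, b))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
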