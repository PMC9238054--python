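import numpy as np
import pytest

from lsfg_superpix import LSFGScan
from lsfg_superpix.synthetic import CohortGeometry, EffectModel


@pytest.fixture(scope="session")
def small_geometry() -> CohortGeometry:
    """Reduced frame preserving the full-frame scan composition."""
    return CohortGeometry.for_shape((64, 128))


@pytest.fixture(scope="session")
def effect() -> EffectModel:
    return EffectModel()


def make_scan(mbr, valid=None, **kwargs) -> LSFGScan:
    mbr = np.asarray(mbr, dtype=float)
    if valid is None:
        valid = np.isfinite(mbr)
    return LSFGScan(mbr=mbr, valid=np.asarray(valid, dtype=bool), **kwargs)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
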