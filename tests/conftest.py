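import numpy as np
import pytest

from auricolor.core import Haplotype, HaplotypeClass, MatingType
from auricolor.simulate import Monokaryon
from auricolor.synth import StudyConfig, generate_study


def mk(hclass: str, mating: str | None = None, sid: str = "S1") -> Monokaryon:
    """Shorthand monokaryon constructor for tests."""
    m = MatingType(mating) if mating else None
    return Monokaryon(sid, Haplotype.from_class(HaplotypeClass(hclass), m))


@pytest.fixture(scope="session")
def default_bundle():
    """One synthetic study under the default (study-condition) config."""
    return generate_study(StudyConfig(seed=11))


@pytest.fixture(scope="session")
def ideal_bundle():
    """Fully observed study: every compatible cross fruits, no missing data."""
    return generate_study(StudyConfig(seed=5, fruiting_rate=1.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
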