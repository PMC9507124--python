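import pytest

from ploidyscan import build_layout, preset_karyotype


@pytest.fixture(scope="session")
def default_layout():
    """Full-size default layout (100 kb arms, 1 kb genes)."""
    return build_layout(100_000, 1_000, seed=0)


@pytest.fixture(scope="session")
def small_layout():
    """Cheap layout for property tests (6 kb arms, 1 kb genes)."""
    return build_layout(6_000, 1_000, seed=0)


@pytest.fixture
def diploid_xy():
    return preset_karyotype("diploid_XY")


@pytest.fixture
def diploid_xx():
    return preset_karyotype("diploid_XX")


@pytest.fixture
def haploid_maternal():
    return preset_karyotype("haploid_maternal")
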