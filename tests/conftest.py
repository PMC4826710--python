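"""Shared fixtures: the published Aplectus antarcticus example and helpers."""

import math

import pytest
from hypothesis import settings

from nemasize import ClassicalShapeParams, CobbRatios, NematodeSizeModel, cobb_to_profile

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

#: Published Cobb measurements for Aplectus antarcticus: landmark positions
#: and diameters in percent of L, with L = 0.6 mm.
ANTARCTICUS_L = [0.1, 12.6, 21.0, 51.0, 87.0]
ANTARCTICUS_D = [0.8, 2.2, 2.3, 2.4, 1.9]
ANTARCTICUS_LENGTH = 0.6e-3


@pytest.fixture(scope="session")
def antarcticus_cobb():
    return CobbRatios(
        length=ANTARCTICUS_LENGTH,
        l=ANTARCTICUS_L,
        d=ANTARCTICUS_D,
        label="Aplectus antarcticus",
    )


@pytest.fixture(scope="session")
def antarcticus_profile(antarcticus_cobb):
    return cobb_to_profile(antarcticus_cobb)


@pytest.fixture(scope="session")
def antarcticus_params(antarcticus_profile):
    params = antarcticus_profile.classical_params()
    assert isinstance(params, ClassicalShapeParams)
    return params


@pytest.fixture(scope="session")
def antarcticus_results(antarcticus_profile):
    return NematodeSizeModel(antarcticus_profile).fit()


def _round_sig(value: float, sig: int) -> float:
    if value == 0:
        return 0.0
    k = sig - 1 - math.floor(math.log10(abs(value)))
    return round(value, k)


def _trunc_sig(value: float, sig: int) -> float:
    if value == 0:
        return 0.0
    k = sig - 1 - math.floor(math.log10(abs(value)))
    scaled = round(value * 10**k, 6)  # shed float representation noise
    return math.trunc(scaled) / 10**k


def matches_printed(value: float, printed: float, sig: int) -> bool:
    """Whether ``printed`` is ``value`` reported to ``sig`` significant figures.

    Published tables are not always consistent about round-half versus
    truncation toward zero, so either convention is accepted; both agree
    except when the dropped digits begin with 5.
    """
    return any(
        math.isclose(candidate, printed, rel_tol=1e-9)
        for candidate in (_round_sig(value, sig), _trunc_sig(value, sig))
    )
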