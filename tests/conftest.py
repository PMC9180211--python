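"""Shared fixtures.

The solver physics benchmarks are expensive (tens of seconds each), so they
run once per session and are shared between the unit tests and the
acceptance tests.
"""

import pytest

from quakeloss.synthetic import gen_hdi_table
from quakeloss.wavesim import verification


@pytest.fixture(scope="session")
def hdi():
    return gen_hdi_table()


@pytest.fixture(scope="session")
def plane_p():
    return verification.plane_wave_speed("P")


@pytest.fixture(scope="session")
def plane_s():
    return verification.plane_wave_speed("S")


@pytest.fixture(scope="session")
def tt_homog():
    return verification.travel_time_homogeneous()


@pytest.fixture(scope="session")
def tt_layer():
    return verification.travel_time_two_layer()


@pytest.fixture(scope="session")
def radiation():
    return verification.radiation_pattern()
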