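"""Shared fixtures: small synthetic sheets and calibrations.

Unit tests use a reduced sheet (300x200 with a 200x120 tape rectangle)
so the whole suite stays fast; the acceptance tests use the generator
defaults.
"""

import numpy as np
import pytest

from hairtube import Region, TapeSpec, default_calibration, generate_sheet


SMALL_TAPE = Region("tape", 50, 40, 250, 160)


def small_spec(**kwargs) -> TapeSpec:
    base = dict(
        width=300,
        height=200,
        tape_regions=(SMALL_TAPE,),
        dust_count=6,
        target_density=2.0,
        seed=0,
    )
    base.update(kwargs)
    return TapeSpec(**base)


@pytest.fixture(scope="session")
def calibration():
    return default_calibration()


@pytest.fixture(scope="session")
def small_sheet():
    return generate_sheet(small_spec(seed=11))


@pytest.fixture(scope="session")
def clean_sheet():
    """Noise-free, gradient-free, dust-free sheet: image classes exact."""
    return generate_sheet(
        small_spec(noise_sd=0.0, gradient_amplitude=0.0, dust_count=0, seed=4)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240843)
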