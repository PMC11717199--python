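import numpy as np
import pytest

from polygompertz import (
    GompertzParams,
    PlateDesign,
    TreatmentSchedule,
    gen_invitro_plate,
)


@pytest.fixture(scope="session")
def noise_free_plate():
    """A small noise-free plate with ground truth (one replicate per combo)."""
    design = PlateDesign(noise_sigma=0.0, replicates=1, seed=5)
    return gen_invitro_plate(design)


@pytest.fixture
def step_schedule():
    return TreatmentSchedule.step(20.0, 0.0, 1.0)


@pytest.fixture
def typical_params():
    return GompertzParams(rho=0.04, K=6000.0, lam=1.1)


def rel_err(a, b):
    return abs(a / b - 1.0)


@pytest.fixture(scope="session")
def relerr():
    return rel_err
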