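import numpy as np
import pytest

import bindloop as bl


@pytest.fixture(scope="session")
def sched():
    """The reference two-phase acquisition: 25 x 0.5 s + 160 x 4 s, bleach after frame 8."""
    return bl.reference_schedule()


@pytest.fixture(scope="session")
def kin():
    """Reference kinetics: 20% transient + 30% stable binding, rates in 1/min."""
    return bl.TwoStateKinetics(c_eq_fast=0.2, c_eq_slow=0.3, k_off_fast=2.0, k_off_slow=0.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_curves(kinetics, schedule, n, noise_sd, seed0):
    return [
        bl.simulate_normalized_recovery(kinetics, schedule, noise_sd, seed=seed0 + i)
        for i in range(n)
    ]
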