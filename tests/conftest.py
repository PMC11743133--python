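import numpy as np
import pytest

import thermofoot as tf


@pytest.fixture(scope="session")
def run_config():
    return tf.load_config()


@pytest.fixture(scope="session")
def params(run_config):
    return run_config.model


@pytest.fixture(scope="session")
def opt_cfg(run_config):
    return run_config.optimizer


@pytest.fixture(scope="session")
def effects():
    return tf.EffectSpec.default()


@pytest.fixture()
def design():
    return tf.DesignSpec(seed=11)


@pytest.fixture()
def simple_traits():
    est = tf.TraitEstimate
    return tf.LineTraits(
        line_id="L1",
        origin="Brazil",
        regime="hot",
        assay_temp=35.0,
        omega=est(60.0, 3.0),
        mass_M=est(6.0, 0.3),
        d1=est(20.0, 1.0),
        psi=est(45.0, 2.0),
        d2=est(18.0, 0.9),
    )


def brute_force_r_prime(T, M, p, q, params):
    """Independent scalar evaluation of the growth-rate product.

    Deliberately re-derives every factor from the closed forms rather than
    calling the package, so optimizer and model tests have a second route.
    """
    R = 8.314
    if p <= 0 or q <= 0 or p + q >= 1 or M <= 0:
        # boundary cases are zero by the limits of the factors
        if p == 0 or q == 0 or p + q == 1:
            return 0.0
    surv = (1.0 - params.c) ** M
    B = (M * (1.0 - p - q)) ** params.b
    rate = params.a_B * p * M * np.exp(-params.Ea_B / (R * T))
    dG = params.dH_m * (1.0 - T / params.T_m) - params.dCp * (
        (params.T_m - T) + T * np.log(T / params.T_m)
    )
    Ku = np.exp(-dG / (R * T))
    stab = 0.0 if q * M == 0 else 1.0 / (1.0 + params.kappa_D * Ku / (q * M))
    return surv * B * rate * stab


@pytest.fixture(scope="session")
def oracle_r_prime():
    return brute_force_r_prime
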