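import numpy as np
import pytest
from hypothesis import settings

from exposcreen import (
    FishParameters,
    SyntheticConfig,
    default_environment,
    generate_reference_fixture,
    generate_screening_set,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def env():
    return default_environment()


@pytest.fixture(scope="session")
def fish():
    return FishParameters()


@pytest.fixture(scope="session")
def reference(env, fish):
    ref, _ = generate_reference_fixture(n=148, seed=42, env=env, fish=fish)
    return ref


@pytest.fixture(scope="session")
def reference_records(env, fish):
    _, records = generate_reference_fixture(n=148, seed=42, env=env, fish=fish)
    return records


@pytest.fixture(scope="session")
def screening_records():
    return generate_screening_set(SyntheticConfig(n_chemicals=200), seed=7)


def random_records(n, seed, rng_bounds=((-4, 10), (-12, 3))):
    """Random valid chemical records spanning the clipped property domain."""
    from exposcreen import ChemicalRecord

    rng = np.random.default_rng(seed)
    (kow_lo, kow_hi), (kaw_lo, kaw_hi) = rng_bounds
    out = []
    for i in range(n):
        out.append(
            ChemicalRecord(
                chem_id=f"RND-{seed}-{i}",
                log_kow=float(rng.uniform(kow_lo, kow_hi)),
                log_kaw=float(rng.uniform(kaw_lo, kaw_hi)),
                t_half_air=float(np.exp(rng.uniform(np.log(5), np.log(5e4)))),
                t_half_water=float(np.exp(rng.uniform(np.log(5), np.log(5e4)))),
                t_half_soil=float(np.exp(rng.uniform(np.log(5), np.log(5e4)))),
            )
        )
    return out
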