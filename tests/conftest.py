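import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vfnorm.cohort import default_config, simulate_cohort
from vfnorm.normative import build_reference_database
from vfnorm.patterns import build_pattern
from vfnorm.records import PatternId

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def p24():
    return build_pattern(PatternId.P24_2)


@pytest.fixture(scope="session")
def p10():
    return build_pattern(PatternId.P10_2)


@pytest.fixture(scope="session")
def cohort1():
    """The default study cohort at seed 1 (356 included, 376 enrolled)."""
    return simulate_cohort(default_config(seed=1))


@pytest.fixture(scope="session")
def model24(cohort1):
    """24-2 normative model built from the seed-1 default cohort."""
    return build_reference_database(
        cohort1, PatternId.P24_2, rng=np.random.default_rng(11)
    )


def scaled_config(seed: int, n_per_bin: int = 6, **overrides):
    """A small-cohort config for speed-sensitive tests: equal bins, no
    enrollment screen extras."""
    return default_config(
        seed=seed,
        age_bin_counts=(n_per_bin,) * 7,
        n_excluded_by_reason={},
        monocular_only_count=0,
        **overrides,
    )


def noise_free_truths():
    """Truth maps with all noise sources silenced."""
    out = {}
    for pid in PatternId:
        t = default_config().truths[pid]
        out[pid] = dataclasses.replace(
            t,
            sigma_map=tuple(0.0 for _ in t.sigma_map),
            gh_sd=0.0,
            foveal_sd=0.0,
            skew_shape=0.0,
        )
    return out
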