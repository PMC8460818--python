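"""Shared fixtures: small synthetic cohorts and reduced-scale configs.

Unit tests run on deliberately small problem sizes (few regions, short
recordings, reduced sampling rates) so the whole suite stays fast; the
acceptance tests exercise the documented larger settings.
"""

import numpy as np
import pytest

from periglioma.cohort import CohortConfig, generate_cohort


def small_config(**overrides) -> CohortConfig:
    """A fast cohort configuration for unit tests."""
    base = dict(n_patients=6, n_controls=4, n_regions=20,
                sampling_rate=128.0, recording_duration=3 * 13.1 + 0.1,
                artifact_rate=0.0, seed=123)
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
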