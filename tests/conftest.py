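import numpy as np
import pytest

from naqms.synthetic_data import (DP_TRUTH, HV_TRUTH, AcquisitionTimeline,
                                  SubjectTruth)


@pytest.fixture
def hv_truth() -> SubjectTruth:
    return HV_TRUTH


@pytest.fixture
def dp_truth() -> SubjectTruth:
    return DP_TRUTH


@pytest.fixture
def timeline_60min() -> AcquisitionTimeline:
    """Interleaved cadence covering one hour post-exercise."""
    return AcquisitionTimeline(post_exercise_span=3600.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def seeds(n: int, entropy: int = 1) -> list[int]:
    """Deterministic stream of sub-2^31 seeds for replicate simulations."""
    return [int(s) % (2**31) for s in np.random.SeedSequence(entropy).generate_state(n)]
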