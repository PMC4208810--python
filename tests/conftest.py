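import numpy as np
import pandas as pd
import pytest

from icpipe import CohortSpec, PipelineConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared by read-only tests."""
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture()
def config():
    return PipelineConfig()


@pytest.fixture()
def small_calls():
    """Tiny hand-built call matrix used across io/aberration tests."""
    from icpipe.types import GAIN, LOSS, NEUTRAL, CopyNumberCalls

    state = pd.DataFrame(
        [[GAIN, NEUTRAL, LOSS], [LOSS, LOSS, NEUTRAL], [NEUTRAL, GAIN, GAIN]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3"],
    )
    loh = pd.DataFrame(
        [[False, True, True], [False, False, False], [True, False, False]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3"],
    )
    return CopyNumberCalls(state, loh)
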