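import numpy as np
import pandas as pd
import pytest

from aneuscope.genome import GenomeModel, toy_genome


@pytest.fixture(scope="session")
def genome():
    return toy_genome()


@pytest.fixture(scope="session")
def two_arm_genome():
    """Minimal two-arm genome: 50 Mb p arm + 30 Mb q arm on one chromosome."""
    return GenomeModel(
        pd.DataFrame(
            [("1", "p", 1, 50_000_000), ("1", "q", 50_000_001, 80_000_000)],
            columns=["chrom", "arm", "start_bp", "end_bp"],
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
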