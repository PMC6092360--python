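import numpy as np
import pandas as pd
import pytest

from planktos import OtuTable, SampleFrame, default_sample_frame


@pytest.fixture
def toy_table() -> OtuTable:
    """4 OTUs x 3 samples with easy hand-checkable counts."""
    df = pd.DataFrame(
        [[10, 0, 3], [5, 5, 2], [0, 10, 1], [0, 0, 4]],
        index=pd.Index([f"O{i}" for i in range(1, 5)], name="otu_id"),
        columns=["s1", "s2", "s3"],
    )
    return OtuTable(df)


@pytest.fixture
def random_table() -> OtuTable:
    rng = np.random.default_rng(42)
    counts = rng.poisson(5.0, size=(30, 12)) + rng.integers(0, 2, (30, 12))
    counts[0] += 50  # make sure no zero-total column
    df = pd.DataFrame(counts,
                      index=[f"O{i:02d}" for i in range(30)],
                      columns=[f"s{j:02d}" for j in range(12)])
    return OtuTable(df)


@pytest.fixture
def meta18() -> SampleFrame:
    return default_sample_frame(18)
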