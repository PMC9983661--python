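import numpy as np
import pandas as pd
import pytest

from liberality.io import CountMatrix, SampleSheet


@pytest.fixture
def small_matrix() -> CountMatrix:
    """3 genes x 2 samples, the literal fixture used across IO tests."""
    return CountMatrix(
        ("g1", "g2", "g3"),
        ("A", "B"),
        np.array([[10.0, 0.0], [30.0, 5.0], [60.0, 5.0]]),
    )


@pytest.fixture
def dose_sheet() -> SampleSheet:
    """Control + two extract dilutions x 3 replicates, one strain."""
    rows = []
    for i, dose in enumerate([0.0] * 3 + [0.001] * 3 + [0.01] * 3, start=1):
        rows.append(
            {
                "sample_id": f"S{i:02d}",
                "strain": "p50",
                "treatment": "control" if dose == 0 else "mulberry",
                "dose": dose,
                "time_h": 90.0,
            }
        )
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230210)
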