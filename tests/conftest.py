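import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from silkshift.quantify import ExpressionMatrix  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20140611)


@pytest.fixture
def small_matrix():
    """Six transcripts covering every specificity class."""
    counts = pd.DataFrame(
        {
            "silk": [5000.0, 900.0, 100.0, 100.0, 0.2, 0.0, 994000.0],
            "venom": [0.0, 1.0, 100.0, 120.0, 0.1, 50.0, 999000.0],
            "cephalothorax": [0.0, 1.0, 100.0, 90.0, 0.1, 60.0, 999000.0],
        },
        # PAD keeps column totals near 1e6 so eCPM values track raw counts
        index=[f"T{i}" for i in range(1, 7)] + ["PAD"],
    )
    lengths = pd.Series([500, 1000, 1500, 2000, 800, 900, 1200], index=counts.index)
    return ExpressionMatrix(counts=counts, lengths=lengths)
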