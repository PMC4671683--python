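import sys
from pathlib import Path

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def toy_counts() -> tuple[pd.DataFrame, dict[str, str]]:
    """4 genes x 4 samples, two groups, hand-checkable numbers."""
    counts = pd.DataFrame(
        {
            "A_1": [100, 0, 50, 850],
            "A_2": [120, 2, 40, 838],
            "B_1": [400, 1, 45, 554],
            "B_2": [380, 0, 55, 565],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    groups = {"A_1": "A", "A_2": "A", "B_1": "B", "B_2": "B"}
    return counts, groups
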