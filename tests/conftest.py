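import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from surfmap.mapping import MapCoordinates
from surfmap.synthetic import generate_table, paper_shape_config

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

FIXTURE_SEED = 0


@pytest.fixture(scope="session")
def paper_table_truth():
    """The canonical 100 × 25 paper-shaped table and its ground truth."""
    return generate_table(paper_shape_config(FIXTURE_SEED))


@pytest.fixture(scope="session")
def paper_table(paper_table_truth):
    return paper_table_truth[0]


def make_map(points: np.ndarray, ids=None, classes=None) -> MapCoordinates:
    """Helper: wrap an (n, 3) array as MapCoordinates."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    frame = pd.DataFrame(
        {
            "id": ids if ids is not None else [f"S{i:03d}" for i in range(n)],
            "charge_class": classes if classes is not None else ["neutral"] * n,
            "designer": [False] * n,
            "pc1": points[:, 0],
            "pc2": points[:, 1],
            "pc3": points[:, 2],
        }
    )
    return MapCoordinates(frame)
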