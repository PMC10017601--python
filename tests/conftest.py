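import numpy as np
import pytest

from fcdscore.diagnostics import GroupScoreDistribution


# Published 4x4 two-observer cross-tabs (rows = observer 2, cols = observer 1)
LATERAL_CROSSTAB = np.array([
    [0, 0, 0, 0],
    [2, 20, 1, 1],
    [0, 4, 1, 1],
    [0, 1, 3, 6],
])

INFERIOR_CROSSTAB = np.array([
    [7, 3, 0, 0],
    [1, 15, 1, 0],
    [0, 2, 8, 0],
    [0, 0, 1, 2],
])

# Published per-wall per-group consensus counts (control n=11, FCD n=29)
LATERAL_BY_GROUP = {"control": (0, 1, 4, 6), "fcd": (2, 22, 3, 2)}
INFERIOR_BY_GROUP = {"control": (0, 4, 5, 2), "fcd": (10, 15, 4, 0)}

# Per-group composite-score counts recovered from the per-cutoff rate table
RECONSTRUCTED_FCD = (2, 7, 12, 6, 2, 0, 0)
RECONSTRUCTED_CONTROL = (0, 0, 1, 1, 4, 4, 1)

MARGINAL_SCORES = (2, 7, 13, 7, 6, 4, 1)


@pytest.fixture
def dist_fcd():
    return GroupScoreDistribution("FCD", np.array(RECONSTRUCTED_FCD))


@pytest.fixture
def dist_control():
    return GroupScoreDistribution("control", np.array(RECONSTRUCTED_CONTROL))


def random_distribution(rng, n_max=30):
    """A random non-empty composite-score distribution for property tests."""
    n = rng.integers(1, n_max + 1)
    counts = np.bincount(rng.integers(0, 7, size=n), minlength=7)
    return GroupScoreDistribution("g", counts)


@pytest.fixture
def ratings_csv(tmp_path):
    """A tiny hand-written ratings CSV in the long-format schema."""
    path = tmp_path / "ratings.csv"
    path.write_text(
        "ear_id,laterality,observer,lateral_score,inferior_score\n"
        "e1,left,1,1,0\n"
        "e1,left,2,1,0\n"
        "e2,right,1,3,2\n"
        "e2,right,2,2,2\n"
        "e2,right,consensus,3,2\n"
        "e3,left,1,0,1\n"
        "e3,left,2,0,1\n"
    )
    return path


@pytest.fixture
def gold_csv(tmp_path):
    path = tmp_path / "gold.csv"
    path.write_text(
        "ear_id,surgical_finding\n"
        "e1,dehiscent\n"
        "e2,intact\n"
        "e3,unknown\n"
    )
    return path
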