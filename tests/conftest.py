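import numpy as np
import pandas as pd
import pytest

from dollomap import PresenceMatrix, TimeTree, load_fixture_timetree


@pytest.fixture
def quartet_tree() -> TimeTree:
    """((A,B),(C,D)) with tips at 0 Ma, cherries at 1 Ma, root at 2 Ma,
    stem to 3 Ma."""
    return TimeTree.from_newick("((A:1,B:1):1,(C:1,D:1):1):1;")


@pytest.fixture
def quartet_matrix() -> PresenceMatrix:
    data = pd.DataFrame(
        {
            "A": [1, 1, 1, 1, 1],
            "B": [0, 1, 1, 0, 1],
            "C": [0, 0, 1, 0, 1],
            "D": [0, 0, 1, 1, 1],
        },
        index=["f_singleton", "f_cherry", "f_all", "f_span", "f_span2"],
        dtype=np.int8,
    )
    # f_span2 differs from f_all only in name; keep distinct pattern
    data.loc["f_span2", "B"] = 0
    return PresenceMatrix(data)


@pytest.fixture(scope="session")
def fixture_tree() -> TimeTree:
    return load_fixture_timetree()
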