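import numpy as np
import pandas as pd
import pytest

from paa.screen_io import MeasurementKind, ScreenMatrix, SequenceMap
from paa.substrate_db import build_database


@pytest.fixture
def toy_screen() -> ScreenMatrix:
    """3x3 screen with one dominant cell: S2 is cleaved far more strongly by
    P2 than anything else; every other cell is equal."""
    values = pd.DataFrame(
        [[1.0, 1.0, 1.0], [1.0, 100.0, 1.0], [1.0, 1.0, 1.0]],
        index=["S1", "S2", "S3"],
        columns=["P1", "P2", "P3"],
    )
    return ScreenMatrix("toy", values, MeasurementKind.fold_change)


@pytest.fixture
def toy_sequences() -> SequenceMap:
    return SequenceMap(
        {
            "S1": "GGPLGLGG",
            "S2": "GGVPLSGG",
            "S3": "AAAAAAAA",
            "S4": "GGPLGLGS",
            "S5": "WYHKFDEC",
        }
    )


@pytest.fixture
def toy_db(toy_screen, toy_sequences):
    return build_database([toy_screen], toy_sequences)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
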