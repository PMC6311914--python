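import numpy as np
import pandas as pd
import pytest

from betacell.data_io import CellAnnotation, ExpressionMatrix


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    """4 genes x 6 cells raw matrix with hand-set values."""
    data = pd.DataFrame(
        [[0.0, 1.5, 3.0, 0.0, 7.0, 15.0],
         [2.0, 0.0, 5.0, 1.0, 0.0, 3.0],
         [1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
         [0.0, 0.0, 0.0, 10.0, 20.0, 30.0]],
        index=["INS", "CASP3", "FLAT", "JNK"],
        columns=[f"c{i}" for i in range(1, 7)],
    )
    return ExpressionMatrix(data, scale="raw")


@pytest.fixture
def small_ann() -> CellAnnotation:
    return CellAnnotation(pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(1, 7)],
        "donor_id": ["d1", "d1", "d2", "d3", "d3", "d3"],
        "condition": ["healthy", "healthy", "healthy", "T2D", "T2D", "T2D"],
        "cohort": ["demo"] * 6,
    }))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
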