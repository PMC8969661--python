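import numpy as np
import pandas as pd
import pytest

from th2axis.io import ExpressionMatrix


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """3-probe x 4-sample matrix, two groups."""
    values = pd.DataFrame(
        np.arange(12, dtype=float).reshape(3, 4),
        index=["p1", "p2", "p3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    values.index.name = "probe_id"
    groups = {"s1": "AR", "s2": "AR", "s3": "control", "s4": "control"}
    return ExpressionMatrix(values=values, sample_groups=groups)


def make_matrix(values: np.ndarray, group: str = "G") -> ExpressionMatrix:
    """Single-group matrix from a raw array, probes r1..rn, samples c1..cm."""
    n, m = values.shape
    frame = pd.DataFrame(
        np.asarray(values, float),
        index=[f"r{i+1}" for i in range(n)],
        columns=[f"c{j+1}" for j in range(m)],
    )
    frame.index.name = "probe_id"
    return ExpressionMatrix(
        values=frame, sample_groups={c: group for c in frame.columns}
    )
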