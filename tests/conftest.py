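import numpy as np
import pytest

from srpnet import FeatureTable, LabelVector


@pytest.fixture
def toy_table() -> FeatureTable:
    return FeatureTable(
        values=np.array(
            [
                [2.0, 0.0, 1.0],
                [4.0, 0.5, 0.0],
                [6.0, 1.0, 1.0],
            ]
        ),
        feature_names=["a", "b", "c"],
        feature_kinds=["continuous", "continuous", "binary"],
    )


@pytest.fixture
def worked_labels() -> tuple[LabelVector, np.ndarray]:
    """The hand-derived 4-sample example: diag (1,1,1), one (1 -> 2) slip."""
    y_true = LabelVector(codes=np.array([0, 1, 1, 2]), category_names=["a", "b", "c"])
    y_pred = np.array([0, 1, 2, 2])
    return y_true, y_pred
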