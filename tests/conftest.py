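import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from vesselmark import ExpressionMatrix, SampleAnnotation

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """4 genes x 4 samples, one missing value."""
    values = pd.DataFrame(
        {
            "s1": [1.0, 5.0, 2.0, 0.0],
            "s2": [2.0, 5.0, np.nan, 0.0],
            "s3": [3.0, 5.0, 4.0, 3.0],
            "s4": [4.0, 5.0, 6.0, 4.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    return ExpressionMatrix(values)


@pytest.fixture
def two_class_annotations():
    anns = []
    for i in range(2):
        anns.append(SampleAnnotation(f"s{i + 1}", "GPL570", "BEC", frozenset("AB"), "study"))
    for i in range(2, 4):
        anns.append(SampleAnnotation(f"s{i + 1}", "GPL570", "LEC", frozenset("AB"), "study"))
    return anns
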