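import numpy as np
import pytest

from ctephperf import LOBE_NAMES, generate_lobe_labelmap, make_truth

PLANTED_FRACTIONS = {"RUL": 0.40, "RML": 0.55, "RLL": 0.70, "LUL": 0.45, "LLL": 0.60}


@pytest.fixture(scope="session")
def seg64():
    return generate_lobe_labelmap((64, 64, 64), (3.0, 3.0, 3.0), seed=1)


@pytest.fixture(scope="session")
def seg40():
    """Smaller grid for fast tests."""
    return generate_lobe_labelmap((40, 40, 40), (3.0, 3.0, 3.0), seed=1)


@pytest.fixture(scope="session")
def truth64(seg64):
    return make_truth(seg64, PLANTED_FRACTIONS, subject_id="T1", seed=7)


@pytest.fixture(scope="session")
def truth40(seg40):
    return make_truth(seg40, PLANTED_FRACTIONS, subject_id="T1", seed=7)


def random_defect_pair(rng, shape=(10, 10, 10)):
    """Two random defect maps on a common random ROI, for oracle checks."""
    from ctephperf.defects import DefectMap

    roi = rng.random(shape) < 0.8
    a = (rng.random(shape) < 0.4) & roi
    b = (rng.random(shape) < 0.4) & roi
    return (
        DefectMap(qdm=a, mask=roi, threshold=1.0),
        DefectMap(qdm=b, mask=roi, threshold=1.0),
        roi,
    )
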