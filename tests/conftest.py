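"""Shared fixtures: deterministic RNGs and the published validation matrix."""

from __future__ import annotations

import numpy as np
import pytest

from mossquad.accuracy import ErrorMatrix

# Published 7x7 error matrix (percent of 21,608 grid points) from a
# semi-automated vs expert-manual classification of a moss quadrat test
# mosaic: rows = semi-automated prediction, columns = manual reference.
# Cells are printed rounded to 2 dp; the overall accuracy rounds to 84%
# and the overall kappa to 0.76.
VALIDATION_CLASSES = [
    "healthy_moss", "stressed_moss", "moribund_moss", "lichen", "rock", "snow", "shadow",
]
VALIDATION_MATRIX_PCT = np.array([
    [38.03, 2.13, 5.16, 0.00, 0.25, 0.00, 0.00],
    [3.24, 17.54, 2.89, 0.00, 0.06, 0.00, 0.00],
    [1.14, 0.67, 24.27, 0.00, 0.12, 0.00, 0.00],
    [0.01, 0.00, 0.01, 0.15, 0.00, 0.00, 0.00],
    [0.12, 0.03, 0.06, 0.00, 3.78, 0.00, 0.00],
    [0.01, 0.00, 0.00, 0.00, 0.00, 0.08, 0.00],
    [0.12, 0.05, 0.08, 0.00, 0.02, 0.00, 0.00],
])


@pytest.fixture
def validation_matrix() -> ErrorMatrix:
    return ErrorMatrix(classes=list(VALIDATION_CLASSES), p=VALIDATION_MATRIX_PCT,
                       n_points=21608)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
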