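"""Shared fixtures: small rendered arrays reused across test modules."""

import numpy as np
import pytest

from arrayquant.blob_detection import detect
from arrayquant.grid_processing import build_grid
from arrayquant.synthetic_array import SyntheticArraySpec, render_array


@pytest.fixture(scope="session")
def clean_spec():
    """Noiseless axis-aligned 8x10 grid, pitch 30, spot sigma 4.5."""
    return SyntheticArraySpec(n_rows=8, n_cols=10, pitch=30.0, seed=11)


@pytest.fixture(scope="session")
def clean_render(clean_spec):
    return render_array(clean_spec)


@pytest.fixture(scope="session")
def clean_image(clean_render):
    return clean_render[0]


@pytest.fixture(scope="session")
def clean_truth(clean_render):
    return clean_render[1]


@pytest.fixture(scope="session")
def clean_blobs(clean_image):
    return detect(clean_image)


@pytest.fixture(scope="session")
def clean_template(clean_blobs):
    template, _ = build_grid(clean_blobs)
    return template


@pytest.fixture(scope="session")
def wide_margin_template():
    """Template on a generous canvas, for transformed-fixture alignment."""
    spec = SyntheticArraySpec(n_rows=8, n_cols=10, pitch=30.0, seed=1, margin=140)
    image, _ = render_array(spec)
    template, _ = build_grid(detect(image))
    return template


def truth_order(truth):
    """Index array sorting ground-truth wells by (row, col), the template order."""
    return np.lexsort((truth.cols, truth.rows))
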