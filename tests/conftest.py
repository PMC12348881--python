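import numpy as np
import pytest

from nichequant.phenotype import (
    extract_mask_intensities,
    normalize_intensities,
    pool_and_threshold,
)
from nichequant.simdata import SimParams, generate_coculture_stack

MARKERS = ["CD19", "CD3", "CASP3"]


@pytest.fixture(scope="session")
def small_params():
    """Default-composition parameters on a small grid (40 cells)."""
    return SimParams(
        shape=(32, 64, 64), n_b_cells=24, n_t_cells=2, n_other_cells=14, seed=11
    )


@pytest.fixture(scope="session")
def coculture(small_params):
    """One generated small co-culture: (stack, labels, truth)."""
    return generate_coculture_stack(small_params)


@pytest.fixture(scope="session")
def default_run():
    """Three default-size stacks with pooled thresholds, as a realistic run.

    Returns (stacks, labels, truths, normalized tables, thresholds).
    """
    stacks, labels, truths, tables = [], [], [], []
    for i in range(3):
        stack, lab, truth = generate_coculture_stack(SimParams(seed=300 + i))
        table = extract_mask_intensities(lab, stack, MARKERS, stack_id=f"s{i}")
        stacks.append(stack)
        labels.append(lab)
        truths.append(truth)
        tables.append(normalize_intensities(table, MARKERS))
    thresholds = pool_and_threshold(tables)
    return stacks, labels, truths, tables, thresholds


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
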