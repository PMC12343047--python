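import numpy as np
import pandas as pd
import pytest

from spatialccm.io_data import CellDataset


def make_dataset(coords, types, expression, image_id="img1", patient_id="pt1",
                 markers=None) -> CellDataset:
    """Build a one-image dataset from plain arrays."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    cells = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "image_id": image_id,
        "patient_id": patient_id,
        "x": coords[:, 0],
        "y": coords[:, 1],
        "cell_type": list(types),
    })
    expression = np.asarray(expression, dtype=float)
    if markers is None:
        markers = [f"m{j}" for j in range(expression.shape[1])]
    expr = pd.DataFrame(expression, index=pd.Index(cells["cell_id"],
                                                   name="cell_id"),
                        columns=markers)
    return CellDataset(cells, expr)


@pytest.fixture
def random_image():
    """A 200-cell, 3-type random image for oracle comparisons."""
    rng = np.random.default_rng(7)
    coords = rng.uniform(0, 400, size=(200, 2))
    types = rng.choice(["A", "B", "C"], size=200, p=[0.5, 0.3, 0.2])
    expr = rng.gamma(2.0, 1.0, size=(200, 2))
    return make_dataset(coords, types, expr)


@pytest.fixture
def small_cohort():
    """Deterministic 4-patient cohort from the synthetic generator."""
    from spatialccm import synthetic_data as synth
    cfg = synth.SyntheticConfig(
        n_patients=4, images_per_patient=2, cells_per_image=300,
        image_side=800.0, seed=11)
    dataset, truth = synth.generate_cohort(cfg)
    return dataset, truth, cfg
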