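import numpy as np
import pandas as pd
import pytest

from lesionmap.core import LesionMask, ReferenceGrid


@pytest.fixture
def grid():
    return ReferenceGrid(shape=(10, 12, 10), voxel_size_mm=(4.0, 4.0, 4.0))


@pytest.fixture
def unit_grid():
    return ReferenceGrid(shape=(12, 12, 12), voxel_size_mm=(1.0, 1.0, 1.0))


def make_mask(grid, indices, patient_id="P1"):
    vox = np.zeros(grid.shape, dtype=np.uint8)
    for idx in indices:
        vox[tuple(idx)] = 1
    return LesionMask(patient_id=patient_id, grid=grid, voxels=vox)


@pytest.fixture
def make_mask_fn():
    return make_mask


def make_clinical(n, seed=0, subgroup="GBM"):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:04d}" for i in range(n)],
            "age": rng.uniform(25, 80, n).round(2),
            "sex": rng.choice(["male", "female"], n),
            "kps": rng.choice(np.arange(40, 101, 10), n),
            "time": rng.exponential(14.0, n).round(4) + 0.01,
            "event": rng.integers(0, 2, n),
            "subgroup": subgroup,
            "tumor_volume_cm3": rng.uniform(5, 80, n).round(3),
        }
    )


@pytest.fixture
def make_clinical_fn():
    return make_clinical
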