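import numpy as np
import pytest

from dlcoradiomics import (
    CohortConfig,
    delta_features,
    extract_cohort_features,
    generate_cohort,
)
from dlcoradiomics.features import ExtractionConfig
from dlcoradiomics.modeling import EvaluationData
from dlcoradiomics.volumes import ImageVolume, MaskVolume


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def random_image(rng):
    voxels = rng.normal(-800, 80, size=(12, 10, 8))
    return ImageVolume(voxels, (1.0, 1.0, 2.5))


@pytest.fixture
def full_mask():
    return MaskVolume(np.ones((12, 10, 8), dtype=bool), (1.0, 1.0, 2.5))


def random_level_grid(rng, shape=(4, 4, 4), n_levels=4, p_mask=0.8):
    """A random discretized grid + mask guaranteed non-degenerate."""
    while True:
        mask = rng.random(shape) < p_mask
        if mask.sum() < 3:
            continue
        levels = np.zeros(shape, dtype=np.int32)
        levels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
        if levels.max() >= 1:
            return levels, mask


def small_eval_data(n=60, seed=7, texture_effect=2.0, clinical_effect=1.0,
                    grid=(32, 32, 20), filters=("original", "wavelet"),
                    phases=("phase0", "phase50")):
    """Compact cohort + feature tables for modeling tests."""
    cfg = CohortConfig(
        n_patients=n, seed=seed, grid_shape=grid,
        texture_effect=texture_effect, clinical_effect=clinical_effect,
        lesion_radius_mm_range=(3.0, 6.0),
    )
    patients, table = generate_cohort(cfg)
    from dlcoradiomics.filters import FilterConfig

    extraction = ExtractionConfig(filters=FilterConfig(enabled=filters))
    tables = {ph: extract_cohort_features(patients, ph, extraction) for ph in phases}
    if "phase0" in tables and "phase50" in tables:
        tables["delta"] = delta_features(tables["phase0"], tables["phase50"])
    data = EvaluationData(tables, table.set_index("patient_id", drop=False))
    return patients, table, data


@pytest.fixture(scope="session")
def signal_eval_small():
    """Planted-signal cohort shared by the modeling tests."""
    return small_eval_data(n=60, seed=7)
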