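"""Texture-matrix and first-order features against hand computations and
brute-force enumeration oracles."""

import numpy as np
import pandas as pd
import pytest

from dlcoradiomics.features import (
    ExtractionConfig,
    delta_features,
    extract_features,
    first_order,
    glcm_build,
    glcm_correlation,
    glcm_imc1,
    gldm_build,
    gldm_lgle,
    glszm_build,
    glszm_sznn,
)
from dlcoradiomics.filters import FilterConfig
from dlcoradiomics.preprocess import DiscretizedVolume
from dlcoradiomics.volumes import ImageVolume, MaskVolume

from conftest import random_level_grid
from oracle_textures import (
    brute_first_order,
    brute_glcm,
    brute_glcm_correlation,
    brute_glcm_imc1,
    brute_gldm,
    brute_gldm_lgle,
    brute_glszm,
    brute_glszm_sznn,
)

SPACING = (1.0, 1.0, 1.0)


def _disc(levels):
    levels = np.asarray(levels, dtype=np.int32)
    return DiscretizedVolume(levels, 25.0, max(int(levels.max()), 1))


def _mask(arr):
    return MaskVolume(np.asarray(arr, dtype=bool), SPACING)


class TestGLCM:
    def test_constant_region_all_mass_at_origin(self):
        levels = np.ones((2, 2, 2), dtype=np.int32)
        g = glcm_build(_disc(levels), _mask(np.ones((2, 2, 2))))
        assert g.matrix[0, 0] == pytest.approx(1.0)
        assert glcm_correlation(g) == 1.0
        assert glcm_imc1(g) == 0.0

    def test_alternating_axis_off_diagonal(self):
        # levels alternate 1/2 along axis 0; pairs along that axis are all (1,2)
        levels = np.zeros((4, 1, 2), dtype=np.int32)
        levels[:, 0, :] = np.array([1, 2, 1, 2])[:, None]
        mask = np.zeros((4, 1, 2), dtype=bool)
        mask[:, 0, 0] = True  # single column: only the (1,0,0) direction pairs
        g = glcm_build(_disc(levels), _mask(mask))
        assert g.matrix[0, 0] == 0 and g.matrix[1, 1] == 0
        assert g.matrix[0, 1] == pytest.approx(0.5)
        assert g.matrix[1, 0] == pytest.approx(0.5)

    def test_hand_computed_correlation_two_cells(self):
        p = np.zeros((2, 2))
        p[0, 1] = p[1, 0] = 0.5
        from dlcoradiomics.features import GLCM

        g = GLCM(p, 1, ())
        # mu = 1.5, var = 0.25, E[ij] = 2 -> (2 - 2.25)/0.25 = -1
        assert glcm_correlation(g) == pytest.approx(-1.0)

    def test_independent_matrix_imc1_zero(self):
        px = np.array([0.3, 0.7])
        p = np.outer(px, px)
        from dlcoradiomics.features import GLCM

        g = GLCM(p, 1, ())
        assert glcm_imc1(g) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_random_grids(self, rng):
        for _ in range(10):
            levels, mask = random_level_grid(rng)
            d = _disc(levels)
            g = glcm_build(d, _mask(mask))
            ref = brute_glcm(levels, mask)
            assert np.allclose(g.matrix, ref, atol=1e-12)
            assert glcm_correlation(g) == pytest.approx(brute_glcm_correlation(ref), abs=1e-9)
            assert glcm_imc1(g) == pytest.approx(brute_glcm_imc1(ref), abs=1e-9)

    def test_rotation_invariance_pooled_directions(self, rng):
        levels, mask = random_level_grid(rng, shape=(5, 5, 5))
        base = glcm_build(_disc(levels), _mask(mask))
        feats = (glcm_correlation(base), glcm_imc1(base))
        for axes in ((0, 1), (0, 2), (1, 2)):
            rl = np.rot90(levels, k=1, axes=axes)
            rm = np.rot90(mask, k=1, axes=axes)
            rot = glcm_build(_disc(rl), _mask(rm))
            assert glcm_correlation(rot) == pytest.approx(feats[0], abs=1e-9)
            assert glcm_imc1(rot) == pytest.approx(feats[1], abs=1e-9)

    def test_too_few_voxels_rejected(self):
        mask = np.zeros((2, 2, 2), dtype=bool)
        mask[0, 0, 0] = True
        with pytest.raises(ValueError):
            glcm_build(_disc(np.ones((2, 2, 2))), _mask(mask))


class TestGLDM:
    def test_constant_region_lgle_one(self):
        g = gldm_build(_disc(np.ones((3, 3, 3))), _mask(np.ones((3, 3, 3))))
        assert gldm_lgle(g) == pytest.approx(1.0)

    def test_level_two_region_lgle_quarter(self):
        levels = np.full((3, 3, 3), 2, dtype=np.int32)
        g = gldm_build(_disc(levels), _mask(np.ones((3, 3, 3))))
        assert gldm_lgle(g) == pytest.approx(0.25)

    def test_count_conservation(self, rng):
        levels, mask = random_level_grid(rng)
        g = gldm_build(_disc(levels), _mask(mask))
        assert g.matrix.sum() == mask.sum()

    def test_matches_brute_force(self, rng):
        for alpha in (0, 1):
            for _ in range(5):
                levels, mask = random_level_grid(rng)
                g = gldm_build(_disc(levels), _mask(mask), alpha=alpha)
                ref = brute_gldm(levels, mask, alpha=alpha)
                assert np.allclose(g.matrix[:, : ref.shape[1]], ref, atol=1e-12)
                assert gldm_lgle(g) == pytest.approx(brute_gldm_lgle(ref), abs=1e-9)


class TestGLSZM:
    def test_single_zone(self):
        g = glszm_build(_disc(np.ones((3, 3, 3))), _mask(np.ones((3, 3, 3))))
        assert g.n_zones == 1
        assert glszm_sznn(g) == pytest.approx(1.0)

    def test_two_singleton_size_bins(self):
        # two zones of different sizes -> SZNN = (1^2 + 1^2) / 2^2
        levels = np.zeros((4, 1, 1), dtype=np.int32)
        levels[:, 0, 0] = [1, 1, 2, 2]
        levels[3, 0, 0] = 0
        mask = levels > 0
        g = glszm_build(_disc(np.where(mask, levels, 0)), _mask(mask))
        assert g.n_zones == 2
        assert glszm_sznn(g) == pytest.approx(0.5)

    def test_matches_brute_force_flood_fill(self, rng):
        for _ in range(10):
            levels, mask = random_level_grid(rng)
            g = glszm_build(_disc(levels), _mask(mask))
            ref = brute_glszm(levels, mask)
            assert np.allclose(g.matrix[:, : ref.shape[1]], ref, atol=1e-12)
            assert glszm_sznn(g) == pytest.approx(brute_glszm_sznn(ref), abs=1e-9)
            # voxel conservation invariant
            sizes = np.arange(1, g.matrix.shape[1] + 1)
            assert (g.matrix.sum(axis=0) * sizes).sum() == mask.sum()


class TestFirstOrder:
    def test_small_examples(self):
        fo = first_order(np.array([1.0, 2.0, 3.0]))
        assert fo["Maximum"] == 3.0 and fo["Median"] == 2.0
        fo = first_order(np.full(10, 4.2))
        assert fo["Variance"] == pytest.approx(0.0, abs=1e-24)
        assert fo["Range"] == 0.0

    def test_matches_sort_based_oracle(self, rng):
        vals = rng.normal(size=37)
        got = first_order(vals)
        ref = brute_first_order(vals)
        for k, v in ref.items():
            assert got[k] == pytest.approx(v, abs=1e-9), k


def _tiny_patient(rng, shape=(12, 12, 10)):
    lung = np.zeros(shape, dtype=bool)
    lung[1:-1, 1:-1, 1:-1] = True
    gtv = np.zeros(shape, dtype=bool)
    gtv[4:6, 4:6, 4:6] = True
    vox = rng.normal(-820, 60, size=shape)
    img = ImageVolume(vox, (1.0, 1.0, 2.5))
    return img, MaskVolume(lung, img.spacing_mm), [MaskVolume(gtv, img.spacing_mm)]


class TestExtractFeatures:
    CONFIG = ExtractionConfig(filters=FilterConfig(enabled=("original",)))

    def test_original_prefix_naming_contract(self, rng):
        img, lung, gtvs = _tiny_patient(rng)
        row = extract_features(img, lung, gtvs, self.CONFIG)
        assert row
        assert all(name.startswith("original_") for name in row)
        classes = {name.split("_")[1] for name in row}
        assert classes == {"firstorder", "glcm", "gldm", "glszm"}

    def test_mask_locality(self, rng):
        img, lung, gtvs = _tiny_patient(rng)
        row = extract_features(img, lung, gtvs, self.CONFIG)
        perturbed = img.voxels.copy()
        region = lung.voxels & ~gtvs[0].voxels
        perturbed[~region] += rng.normal(0, 500, size=img.shape)[~region]
        row2 = extract_features(ImageVolume(perturbed, img.spacing_mm), lung, gtvs, self.CONFIG)
        for k in row:
            assert row2[k] == pytest.approx(row[k], rel=1e-12), k

    def test_composition_of_verified_operations(self, rng):
        """The extracted row equals manually chaining the oracle-checked steps."""
        from dlcoradiomics.features import parenchyma_mask
        from dlcoradiomics.preprocess import discretize

        img, lung, gtvs = _tiny_patient(rng)
        row = extract_features(img, lung, gtvs, self.CONFIG)
        region = parenchyma_mask(lung, gtvs, 0.5)
        vals = img.voxels[region.voxels]
        ref_fo = brute_first_order(vals)
        assert row["original_firstorder_Median"] == pytest.approx(ref_fo["Median"])
        disc = discretize(img, region, 25.0)
        ref = brute_glcm(disc.levels, region.voxels)
        assert row["original_glcm_Correlation"] == pytest.approx(
            brute_glcm_correlation(ref), abs=1e-9
        )
        assert row["original_gldm_LowGrayLevelEmphasis"] == pytest.approx(
            brute_gldm_lgle(brute_gldm(disc.levels, region.voxels)), abs=1e-9
        )
        assert row["original_glszm_SizeZoneNonUniformityNormalized"] == pytest.approx(
            brute_glszm_sznn(brute_glszm(disc.levels, region.voxels)), abs=1e-9
        )


class TestDeltaFeatures:
    def test_identities_and_subtraction(self, rng):
        cols = ["a", "b", "c"]
        ids = ["p1", "p2"]
        t0 = pd.DataFrame(rng.normal(size=(2, 3)), index=ids, columns=cols)
        assert np.all(delta_features(t0, t0).to_numpy() == 0)
        zeros = pd.DataFrame(np.zeros((2, 3)), index=ids, columns=cols)
        assert delta_features(t0, zeros).equals(t0)
        t50 = pd.DataFrame(rng.normal(size=(2, 3)), index=ids, columns=cols)
        assert np.allclose(
            delta_features(t0, t50).to_numpy(), t0.to_numpy() - t50.to_numpy()
        )

    def test_mismatched_columns_rejected(self, rng):
        t0 = pd.DataFrame(np.zeros((2, 2)), columns=["a", "b"])
        t50 = pd.DataFrame(np.zeros((2, 2)), columns=["a", "c"])
        with pytest.raises(ValueError):
            delta_features(t0, t50)
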