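"""First-order and texture-matrix (GLCM / GLDM / GLSZM) radiomic features.

All texture matrices are computed on absolutely discretized gray levels
(see :mod:`dlcoradiomics.preprocess`) restricted to a binary region mask,
with 26-connectivity neighborhoods:

* **GLCM** — gray level co-occurrence matrix over the 13 unique 3-D
  direction offsets at a Chebyshev distance, symmetrized and pooled
  (summed) across directions before normalization.  Features: Correlation
  and Imc1 (informational measure of correlation 1, log base 2).
* **GLDM** — gray level dependence matrix: for each in-mask voxel of level
  *i*, the dependence count *j* is 1 plus the number of in-mask
  26-neighbors whose level differs by at most ``alpha``.  Feature: Low
  Gray Level Emphasis.
* **GLSZM** — gray level size zone matrix: 26-connected components of
  equal level within the mask, binned by zone size.  Feature: Size Zone
  Non-Uniformity Normalized.

First-order statistics (maximum, median, mean, minimum, range, variance,
skewness, energy) are computed on the *continuous* masked filtered
intensities, not on gray levels.  Variance and skewness use the biased
(population) estimators conventional in radiomics; energy is the plain sum
of squared intensities.

Degenerate-region conventions: a single-gray-level region has GLCM
Correlation 1 and Imc1 0.

Feature names follow the ``<filter>_<class>_<Name>`` convention, e.g.
``wavelet-HHH_glcm_Correlation``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from skimage.measure import label as cc_label

from .filters import FilterConfig, apply_filter_bank
from .preprocess import (
    DiscretizedVolume,
    NormalizationMap,
    apply_normalization,
    discretize,
    expand_mask,
    subtract_mask,
)
from .volumes import ImageVolume, MaskVolume

__all__ = [
    "GLCM",
    "GLDM",
    "GLSZM",
    "ExtractionConfig",
    "glcm_build",
    "glcm_correlation",
    "glcm_imc1",
    "gldm_build",
    "gldm_lgle",
    "glszm_build",
    "glszm_sznn",
    "first_order",
    "extract_features",
    "delta_features",
    "FIRST_ORDER_NAMES",
]

# The 13 unique direction offsets of the 26-neighborhood (one per
# antipodal pair), lexicographically the "positive" half.
OFFSETS_13: tuple[tuple[int, int, int], ...] = tuple(
    off
    for off in product((-1, 0, 1), repeat=3)
    if off > (0, 0, 0)
)

# All 26 neighbor offsets.
OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    off for off in product((-1, 0, 1), repeat=3) if off != (0, 0, 0)
)

FIRST_ORDER_NAMES = (
    "Maximum",
    "Median",
    "Mean",
    "Minimum",
    "Range",
    "Variance",
    "Skewness",
    "Energy",
)


@dataclass(frozen=True)
class GLCM:
    matrix: np.ndarray  # Ng x Ng, normalized, symmetric
    distance: int
    directions: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        s = self.matrix.sum()
        if not np.isclose(s, 1.0):
            raise ValueError(f"GLCM must be normalized (sum={s})")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("GLCM must be symmetric")


@dataclass(frozen=True)
class GLDM:
    matrix: np.ndarray  # Ng x Nd counts
    alpha: int
    n_dependences: int  # Nz

    def __post_init__(self) -> None:
        if int(self.matrix.sum()) != self.n_dependences:
            raise ValueError("GLDM counts must sum to Nz")


@dataclass(frozen=True)
class GLSZM:
    matrix: np.ndarray  # Ng x Ns counts (column j-1 = zones of size j)
    n_zones: int  # Nz
    n_voxels: int

    def __post_init__(self) -> None:
        if int(self.matrix.sum()) != self.n_zones:
            raise ValueError("GLSZM counts must sum to the zone count")
        sizes = np.arange(1, self.matrix.shape[1] + 1)
        if int((self.matrix.sum(axis=0) * sizes).sum()) != self.n_voxels:
            raise ValueError("GLSZM size-weighted counts must sum to the voxel count")


def _shift_pairs(levels: np.ndarray, offset: tuple[int, int, int]):
    """Aligned views (source, destination) of `levels` under an offset."""
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, d in enumerate(offset):
        if d > 0:
            src[ax] = slice(0, levels.shape[ax] - d)
            dst[ax] = slice(d, levels.shape[ax])
        elif d < 0:
            src[ax] = slice(-d, levels.shape[ax])
            dst[ax] = slice(0, levels.shape[ax] + d)
    return levels[tuple(src)], levels[tuple(dst)]


def glcm_build(
    levels: DiscretizedVolume,
    mask: MaskVolume,
    distance: int = 1,
    pooling: str = "sum",
) -> GLCM:
    """Co-occurrence matrix pooled over the 13 unique 3-D directions.

    ``pooling='sum'`` sums raw co-occurrence counts across directions
    before normalizing; ``'average'`` normalizes each direction first and
    averages the probability matrices.
    """
    grid = np.where(mask.voxels, levels.levels, 0)
    if (grid > 0).sum() < 2:
        raise ValueError("need at least 2 in-mask voxels for a GLCM")
    ng = levels.n_levels
    offsets = tuple(tuple(distance * d for d in off) for off in OFFSETS_13)
    if pooling not in ("sum", "average"):
        raise ValueError("pooling must be 'sum' or 'average'")
    pooled = np.zeros((ng, ng))
    n_used = 0
    for off in offsets:
        a, b = _shift_pairs(grid, off)
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        idx = (a[valid].astype(np.int64) - 1) * ng + (b[valid].astype(np.int64) - 1)
        counts = np.bincount(idx, minlength=ng * ng).reshape(ng, ng).astype(float)
        counts = counts + counts.T  # symmetrize
        if pooling == "average":
            pooled += counts / counts.sum()
        else:
            pooled += counts
        n_used += 1
    total = pooled.sum()
    if total == 0:
        raise ValueError("no valid voxel pairs at this distance")
    return GLCM(pooled / total, distance, OFFSETS_13)


def glcm_correlation(m: GLCM) -> float:
    """Correlation between the paired gray levels; 1 for a single level."""
    p = m.matrix
    i = np.arange(1, p.shape[0] + 1, dtype=float)
    px = p.sum(axis=1)
    mu = float(i @ px)  # symmetric: mu_x == mu_y
    var = float(((i - mu) ** 2) @ px)
    if var <= 0:
        return 1.0
    cov = float(i @ p @ i) - mu * mu
    return cov / var


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def glcm_imc1(m: GLCM) -> float:
    """Informational measure of correlation 1; 0 when max(HX, HY) = 0."""
    p = m.matrix
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    hx = _entropy(px)
    hy = _entropy(py)
    hxy = _entropy(p.ravel())
    outer = np.outer(px, py)
    with np.errstate(divide="ignore"):
        logq = np.where(outer > 0, np.log2(np.where(outer > 0, outer, 1.0)), 0.0)
    hxy1 = float(-(p * logq).sum())
    denom = max(hx, hy)
    if denom == 0:
        return 0.0
    return (hxy - hxy1) / denom


def gldm_build(
    levels: DiscretizedVolume, mask: MaskVolume, alpha: int = 0, distance: int = 1
) -> GLDM:
    """Dependence matrix: j = 1 + #{26-neighbors with |level diff| <= alpha}."""
    m = mask.voxels
    if not m.any():
        raise ValueError("empty mask")
    grid = np.where(m, levels.levels, 0)
    dep = np.zeros(grid.shape, dtype=np.int32)
    offsets = tuple(tuple(distance * d for d in off) for off in OFFSETS_26)
    for off in offsets:
        a, b = _shift_pairs(grid, off)
        contrib = (a > 0) & (b > 0) & (np.abs(a.astype(np.int64) - b) <= alpha)
        src_slices, _ = _shift_pairs(dep, off)
        src_slices += contrib
    ng = levels.n_levels
    nd = int(dep[m].max()) + 1
    lv = grid[m].astype(np.int64) - 1
    dp = dep[m].astype(np.int64)  # dependence j-1 (0-based)
    counts = np.bincount(lv * nd + dp, minlength=ng * nd).reshape(ng, nd).astype(float)
    return GLDM(counts, alpha, int(counts.sum()))


def gldm_lgle(m: GLDM) -> float:
    """Low Gray Level Emphasis: mean of 1/i^2 over dependences."""
    i = np.arange(1, m.matrix.shape[0] + 1, dtype=float)
    return float((m.matrix.sum(axis=1) / i**2).sum() / m.n_dependences)


def glszm_build(levels: DiscretizedVolume, mask: MaskVolume) -> GLSZM:
    """Size-zone matrix: 26-connected equal-level zones within the mask."""
    m = mask.voxels
    if not m.any():
        raise ValueError("empty mask")
    grid = np.where(m, levels.levels, 0)
    # skimage labels equal-valued connected regions in one pass; background=0
    # (out-of-mask) is excluded.
    lab = cc_label(grid, background=0, connectivity=3)
    n_zones = int(lab.max())
    if n_zones == 0:
        raise ValueError("no zones found")
    flat_lab = lab.ravel()
    zone_sizes = np.bincount(flat_lab)[1:]  # drop background
    # first occurrence of each zone id gives its gray level
    order = np.argsort(flat_lab, kind="stable")
    sorted_lab = flat_lab[order]
    starts = np.searchsorted(sorted_lab, np.arange(1, n_zones + 1))
    zone_levels = grid.ravel()[order[starts]]
    ng = levels.n_levels
    ns = int(zone_sizes.max())
    counts = np.zeros((ng, ns))
    np.add.at(counts, (zone_levels - 1, zone_sizes - 1), 1.0)
    return GLSZM(counts, n_zones, int((grid > 0).sum()))


def glszm_sznn(m: GLSZM) -> float:
    """Size Zone Non-Uniformity Normalized: sum_j (zones of size j)^2 / Nz^2."""
    per_size = m.matrix.sum(axis=0)
    return float((per_size**2).sum() / m.n_zones**2)


def first_order(values: np.ndarray) -> dict[str, float]:
    """Order statistics and moments of masked (continuous) intensities."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty region")
    return {
        "Maximum": float(v.max()),
        "Median": float(np.median(v)),
        "Mean": float(v.mean()),
        "Minimum": float(v.min()),
        "Range": float(v.max() - v.min()),
        "Variance": float(v.var()),
        "Skewness": float(stats.skew(v)) if v.var() > 0 else 0.0,
        "Energy": float((v**2).sum()),
    }


@dataclass(frozen=True)
class ExtractionConfig:
    """Everything that parameterizes a feature-extraction run."""

    filters: FilterConfig = FilterConfig()
    bin_width_hu: float = 25.0
    gtv_margin_mm: float = 0.5
    glcm_distance: int = 1
    glcm_pooling: str = "sum"
    gldm_alpha: int = 0
    normalization: NormalizationMap | None = None

    def to_dict(self) -> dict:
        return {
            "filters": {
                "enabled": list(self.filters.enabled),
                "wavelet_family": self.filters.wavelet_family,
                "log_sigmas_mm": list(self.filters.log_sigmas_mm),
            },
            "bin_width_hu": self.bin_width_hu,
            "gtv_margin_mm": self.gtv_margin_mm,
            "glcm_distance": self.glcm_distance,
            "glcm_pooling": self.glcm_pooling,
            "gldm_alpha": self.gldm_alpha,
            "normalization": None
            if self.normalization is None
            else {
                "anchor_percentiles": list(self.normalization.anchor_percentiles),
                "reference_values": list(self.normalization.reference_values),
            },
        }


def parenchyma_mask(
    lung_mask: MaskVolume, gtv_masks: list[MaskVolume], margin_mm: float = 0.5
) -> MaskVolume:
    """Lungs minus the union of margin-expanded tumor masks."""
    if not gtv_masks:
        return lung_mask
    union = np.zeros(lung_mask.shape, dtype=bool)
    for g in gtv_masks:
        union |= expand_mask(g, margin_mm).voxels
    return subtract_mask(
        lung_mask, MaskVolume(union, lung_mask.spacing_mm, lung_mask.origin_mm)
    )


def extract_features(
    image: ImageVolume,
    lung_mask: MaskVolume,
    gtv_masks: list[MaskVolume],
    config: ExtractionConfig = ExtractionConfig(),
) -> dict[str, float]:
    """One patient-phase feature row on the healthy-parenchyma region.

    Pipeline: (optional) histogram normalization -> filter bank -> per
    filtered image: first-order on masked intensities, then absolute
    re-discretization of the filtered intensities (same bin width) for the
    GLCM / GLDM / GLSZM features.
    """
    region = parenchyma_mask(lung_mask, gtv_masks, config.gtv_margin_mm)
    if config.normalization is not None:
        image = apply_normalization(image, config.normalization)
    row: dict[str, float] = {}
    for filt in apply_filter_bank(image, config.filters):
        fimg = filt.as_image(image.origin_mm)
        vals = fimg.voxels[region.voxels]
        for name, value in first_order(vals).items():
            row[f"{filt.label}_firstorder_{name}"] = value
        disc = discretize(fimg, region, config.bin_width_hu)
        glcm = glcm_build(disc, region, config.glcm_distance, config.glcm_pooling)
        row[f"{filt.label}_glcm_Correlation"] = glcm_correlation(glcm)
        row[f"{filt.label}_glcm_Imc1"] = glcm_imc1(glcm)
        gldm = gldm_build(disc, region, config.gldm_alpha)
        row[f"{filt.label}_gldm_LowGrayLevelEmphasis"] = gldm_lgle(gldm)
        glszm = glszm_build(disc, region)
        row[f"{filt.label}_glszm_SizeZoneNonUniformityNormalized"] = glszm_sznn(glszm)
    return row


def extract_cohort_features(
    patients, phase: str, config: ExtractionConfig = ExtractionConfig()
) -> pd.DataFrame:
    """Patients x features table for one respiratory phase ('phase0'/'phase50')."""
    rows = {}
    for p in patients:
        image = getattr(p, phase)
        rows[p.patient_id] = extract_features(image, p.lung_mask, p.gtv_masks, config)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "patient_id"
    return table


def delta_features(t0: pd.DataFrame, t50: pd.DataFrame) -> pd.DataFrame:
    """Per-feature Phase 0 minus Phase 50 difference table."""
    if list(t0.columns) != list(t50.columns):
        raise ValueError("feature tables have mismatched columns")
    if list(t0.index) != list(t50.index):
        raise ValueError("feature tables have mismatched patients")
    return t0 - t50
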