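"""Intensity normalization, absolute discretization and mask algebra.

The preprocessing chain mirrors common radiomics practice on CT:

1. *Histogram-based intensity normalization.*  A reference scan defines the
   target intensity distribution via its values at a fixed set of anchor
   percentiles.  Each input scan is then mapped by the piecewise-linear
   monotone transform that carries its own anchor-percentile values onto the
   reference values (terminal-segment slopes extrapolate beyond the outer
   anchors).
2. *Absolute discretization.*  In-mask intensities are binned with a fixed
   bin width (default 25 HU), referenced to the in-mask minimum, yielding
   integer gray levels ``1..n_levels`` (0 outside the mask).
3. *Mask algebra.*  Tumor masks are geometrically expanded by a physical
   margin (default 0.5 mm) and subtracted from the lung mask, leaving the
   healthy parenchyma that all features are computed on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import ImageVolume, MaskVolume

__all__ = [
    "NormalizationMap",
    "DiscretizedVolume",
    "fit_reference_histogram",
    "apply_normalization",
    "discretize",
    "expand_mask",
    "subtract_mask",
    "DEFAULT_ANCHORS",
]

#: Default anchor percentiles; deliberately avoids the extreme order
#: statistics so single outlier voxels cannot skew the mapping.
DEFAULT_ANCHORS: tuple[float, ...] = (1.0, 5.0, 25.0, 50.0, 75.0, 95.0, 99.0)


@dataclass(frozen=True)
class NormalizationMap:
    """Anchor percentiles and the reference values they map onto."""

    anchor_percentiles: tuple[float, ...]
    reference_values: tuple[float, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.anchor_percentiles, dtype=float)
        r = np.asarray(self.reference_values, dtype=float)
        if a.size < 2:
            raise ValueError("need at least 2 anchor percentiles")
        if a.size != r.size:
            raise ValueError("anchors and reference values must pair up")
        if np.any(np.diff(a) <= 0) or a[0] < 0 or a[-1] > 100:
            raise ValueError("anchors must be strictly increasing within [0, 100]")
        if np.any(np.diff(r) < 0):
            raise ValueError("reference values must be non-decreasing")
        object.__setattr__(self, "anchor_percentiles", tuple(a))
        object.__setattr__(self, "reference_values", tuple(r))


@dataclass(frozen=True)
class DiscretizedVolume:
    """Integer gray-level grid: 0 outside the mask, ``1..n_levels`` inside."""

    levels: np.ndarray
    bin_width_hu: float
    n_levels: int

    def __post_init__(self) -> None:
        if self.bin_width_hu <= 0:
            raise ValueError("bin width must be positive")
        if self.n_levels < 1:
            raise ValueError("need at least one gray level")


def fit_reference_histogram(
    reference: ImageVolume,
    mask: MaskVolume | None = None,
    anchors: tuple[float, ...] = DEFAULT_ANCHORS,
) -> NormalizationMap:
    """Empirical anchor-percentile values of the reference scan.

    When ``mask`` is given the histogram is restricted to in-mask voxels.
    """
    if mask is not None:
        mask.check_aligned(reference)
        values = reference.voxels[mask.voxels]
        if values.size == 0:
            raise ValueError("mask selects no voxels to build the reference histogram")
    else:
        values = reference.voxels.ravel()
    anchors_arr = np.asarray(anchors, dtype=float)
    if anchors_arr.size < 2:
        raise ValueError("need at least 2 anchor percentiles")
    ref_values = np.percentile(values, anchors_arr)
    return NormalizationMap(tuple(anchors_arr), tuple(ref_values))


def apply_normalization(image: ImageVolume, norm: NormalizationMap) -> ImageVolume:
    """Piecewise-linear monotone intensity mapping onto the reference histogram.

    The image's own values at the anchor percentiles map exactly onto the
    reference values; between anchors the map is linear, beyond the outermost
    anchors it extrapolates with the terminal-segment slope.  A degenerate
    (constant) image cannot define a mapping and is returned unchanged with
    a warning.
    """
    anchors = np.asarray(norm.anchor_percentiles)
    ref = np.asarray(norm.reference_values)
    src = np.percentile(image.voxels, anchors)

    if src[-1] == src[0]:
        warnings.warn(
            "degenerate (constant) image: normalization is undefined, returning input",
            RuntimeWarning,
            stacklevel=2,
        )
        return image.with_voxels(image.voxels.copy())

    # Collapse duplicate source anchors (flat histogram stretches) so the
    # interpolation grid is strictly increasing; duplicates take the mean
    # reference value, preserving monotonicity.
    xs, inverse = np.unique(src, return_inverse=True)
    ys = np.zeros_like(xs)
    counts = np.bincount(inverse)
    np.add.at(ys, inverse, ref)
    ys /= counts

    out = np.interp(image.voxels, xs, ys)
    # np.interp clamps outside [xs[0], xs[-1]]; replace by terminal-slope
    # linear extrapolation so ordering is preserved in the tails.
    if xs.size >= 2:
        lo_slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
        hi_slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        below = image.voxels < xs[0]
        above = image.voxels > xs[-1]
        out[below] = ys[0] + (image.voxels[below] - xs[0]) * lo_slope
        out[above] = ys[-1] + (image.voxels[above] - xs[-1]) * hi_slope
    return image.with_voxels(out)


def discretize(
    image: ImageVolume, mask: MaskVolume, bin_width_hu: float = 25.0
) -> DiscretizedVolume:
    """Absolute (fixed-bin-width) discretization of in-mask intensities.

    ``level(v) = floor(v / W) - floor(min_mask / W) + 1`` inside the mask and
    0 outside, so levels are invariant to shifting all intensities by an
    exact multiple of the bin width.
    """
    if bin_width_hu <= 0:
        raise ValueError("bin width must be positive")
    mask.check_aligned(image)
    m = mask.voxels
    if not m.any():
        raise ValueError("empty mask: nothing to discretize")
    vals = image.voxels[m]
    floors = np.floor(vals / bin_width_hu).astype(np.int64)
    offset = np.floor(vals.min() / bin_width_hu).astype(np.int64)
    levels = np.zeros(image.shape, dtype=np.int32)
    levels[m] = (floors - offset + 1).astype(np.int32)
    return DiscretizedVolume(levels, float(bin_width_hu), int(levels.max()))


def expand_mask(mask: MaskVolume, margin_mm: float = 0.5) -> MaskVolume:
    """Geometric expansion by a Euclidean margin in physical millimetres.

    A voxel belongs to the output iff its center lies within ``margin_mm``
    of some input foreground voxel center (anisotropic spacing respected).
    Always a superset of the input; ``margin_mm = 0`` is the identity.
    """
    if margin_mm < 0:
        raise ValueError("margin must be non-negative")
    if not mask.voxels.any() or margin_mm == 0:
        return MaskVolume(mask.voxels.copy(), mask.spacing_mm, mask.origin_mm)
    dist = ndimage.distance_transform_edt(~mask.voxels, sampling=mask.spacing_mm)
    return MaskVolume(dist <= margin_mm, mask.spacing_mm, mask.origin_mm)


def subtract_mask(lungs: MaskVolume, gtv_expanded: MaskVolume) -> MaskVolume:
    """Set difference lungs ∖ GTV: the healthy-parenchyma region.

    Raises if nothing survives — a patient whose tumor mask swallows the
    lungs has no parenchyma to featurize.
    """
    lungs.check_aligned(gtv_expanded)
    out = lungs.voxels & ~gtv_expanded.voxels
    if not out.any():
        raise ValueError("lungs minus GTV is empty: no parenchyma region left")
    return MaskVolume(out, lungs.spacing_mm, lungs.origin_mm)
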