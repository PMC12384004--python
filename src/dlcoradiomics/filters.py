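"""Filter bank producing the derived images features are computed on.

Implemented filters and their labels (labels follow the common radiomics
``filter`` prefix convention so feature names are comparable across tools):

* ``original`` — the unfiltered image.
* ``wavelet-LLL`` … ``wavelet-HHH`` — single-level undecimated separable
  3-D wavelet subbands (default family ``coif1``).  The transform is
  computed by circular convolution in the Fourier domain with the 1-D
  analysis taps scaled by 1/sqrt(2) per axis, which makes the 8-subband
  bank exactly energy preserving for orthogonal families and invertible by
  its adjoint (see :func:`wavelet_reconstruct`).  Subband letters map to
  array axes in order: the first letter filters axis 0.
* ``log-sigma-<s>-mm-3D`` — Laplacian of Gaussian at physical scale
  ``sigma_mm`` (per-axis voxel sigma = sigma_mm / spacing).
* ``gradient`` — Euclidean norm of the central-difference gradient with
  physical spacing in the denominators.
* ``square``, ``squareroot``, ``logarithm``, ``exponential`` — monotone
  per-voxel intensity transforms, shifted/scaled so every transform's
  domain is respected and outputs stay within the input magnitude range
  ``M = max|x|``:

  ====================  =======================================
  square                ``z**2 / max(z)`` with ``z = x - min(x)``
  squareroot            ``sign(x) * sqrt(|x| * M)``
  logarithm             ``sign(x) * log(|x| + 1) * M / log(M + 1)``
  exponential           ``exp(x * log(M) / M)``
  ====================  =======================================

  The min-shift keeps ``square`` monotone on signed HU; all four
  transforms are monotone non-decreasing.  For a constant input the
  square/squareroot/logarithm outputs are zeros and exponential ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

from .volumes import ImageVolume

__all__ = [
    "FilteredImage",
    "FilterConfig",
    "wavelet_subbands",
    "wavelet_reconstruct",
    "log_filter",
    "log_sigma_label",
    "gradient_magnitude",
    "intensity_transforms",
    "apply_filter_bank",
]

WAVELET_SUBBAND_ORDER = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
INTENSITY_TRANSFORMS = ("square", "squareroot", "logarithm", "exponential")


@dataclass(frozen=True)
class FilteredImage:
    """A derived image plus the label used as feature-name prefix."""

    voxels: np.ndarray
    label: str
    spacing_mm: tuple[float, float, float]

    def as_image(self, origin_mm=(0.0, 0.0, 0.0)) -> ImageVolume:
        return ImageVolume(self.voxels, self.spacing_mm, origin_mm)


@dataclass(frozen=True)
class FilterConfig:
    """Registry of enabled filters.

    ``enabled`` may contain ``original``, ``wavelet``, ``log``, ``gradient``
    and any of the intensity transforms; ``wavelet`` expands to all 8
    subbands and ``log`` to one image per sigma.
    """

    enabled: tuple[str, ...] = (
        "original",
        "wavelet",
        "log",
        "gradient",
        "square",
        "squareroot",
        "logarithm",
        "exponential",
    )
    wavelet_family: str = "coif1"
    log_sigmas_mm: tuple[float, ...] = (2.0, 4.0)


def _axis_responses(taps: np.ndarray, shape: tuple[int, ...]) -> list[np.ndarray]:
    """Per-axis DFT of the zero-padded filter, for circular convolution."""
    responses = []
    for n in shape:
        if n < taps.size:
            raise ValueError(
                f"volume axis of length {n} is shorter than the {taps.size}-tap filter"
            )
        padded = np.zeros(n)
        padded[: taps.size] = taps
        responses.append(np.fft.fft(padded))
    return responses


def _subband_response(lo_r, hi_r, code: str) -> np.ndarray:
    axes_r = [lo_r[i] if c == "L" else hi_r[i] for i, c in enumerate(code)]
    return (
        axes_r[0][:, None, None] * axes_r[1][None, :, None] * axes_r[2][None, None, :]
    )


def wavelet_subbands(image: ImageVolume, family: str = "coif1") -> list[FilteredImage]:
    """Single-level undecimated 3-D wavelet decomposition, all 8 subbands.

    Same shape as the input; exactly energy preserving for orthogonal
    families (circular boundary, taps scaled by 1/sqrt(2) per axis).
    """
    wav = pywt.Wavelet(family)
    lo = np.asarray(wav.dec_lo) / np.sqrt(2.0)
    hi = np.asarray(wav.dec_hi) / np.sqrt(2.0)
    lo_r = _axis_responses(lo, image.shape)
    hi_r = _axis_responses(hi, image.shape)
    spectrum = np.fft.fftn(image.voxels)
    out = []
    for code in WAVELET_SUBBAND_ORDER:
        resp = _subband_response(lo_r, hi_r, code)
        sub = np.fft.ifftn(spectrum * resp).real
        out.append(FilteredImage(sub, f"wavelet-{code}", image.spacing_mm))
    return out


def wavelet_reconstruct(subbands: list[FilteredImage], family: str = "coif1") -> np.ndarray:
    """Invert :func:`wavelet_subbands` by summing the adjoint of each branch."""
    wav = pywt.Wavelet(family)
    lo = np.asarray(wav.dec_lo) / np.sqrt(2.0)
    hi = np.asarray(wav.dec_hi) / np.sqrt(2.0)
    by_code = {f.label.split("-")[1]: f for f in subbands}
    shape = subbands[0].voxels.shape
    lo_r = _axis_responses(lo, shape)
    hi_r = _axis_responses(hi, shape)
    acc = np.zeros(shape, dtype=complex)
    for code in WAVELET_SUBBAND_ORDER:
        resp = _subband_response(lo_r, hi_r, code)
        acc += np.fft.fftn(by_code[code].voxels) * np.conj(resp)
    return np.fft.ifftn(acc).real


def log_sigma_label(sigma_mm: float) -> str:
    """Canonical label, e.g. 2.0 -> ``log-sigma-2-0-mm-3D``."""
    txt = f"{sigma_mm:g}"
    if "." not in txt:
        txt += ".0"
    return f"log-sigma-{txt.replace('.', '-')}-mm-3D"


def _log_kernels_1d(sigma: float, truncate: float = 4.0):
    """Sampled Gaussian and its second derivative, DC-corrected to zero sum.

    The zero-sum correction guarantees the Laplacian of a constant volume is
    exactly zero despite kernel truncation.
    """
    radius = max(int(truncate * sigma + 0.5), 1)
    x = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    g /= g.sum()
    g2 = g * ((x / sigma**2) ** 2 - 1.0 / sigma**2)
    g2 -= g2.sum() / g2.size
    return g, g2


def log_filter(image: ImageVolume, sigma_mm: float) -> FilteredImage:
    """Laplacian-of-Gaussian response at a physical scale in millimetres."""
    if sigma_mm <= 0:
        raise ValueError("sigma must be positive")
    sigma_vox = np.asarray(sigma_mm) / np.asarray(image.spacing_mm)
    if np.all(sigma_vox < 0.5):
        warnings.warn(
            f"sigma {sigma_mm} mm is sub-voxel on every axis; response is "
            "dominated by discretization",
            RuntimeWarning,
            stacklevel=2,
        )
    out = np.zeros_like(image.voxels)
    smooth_kernels = [_log_kernels_1d(s)[0] for s in sigma_vox]
    deriv_kernels = [_log_kernels_1d(s)[1] for s in sigma_vox]
    for deriv_axis in range(3):
        part = image.voxels
        for axis in range(3):
            kernel = deriv_kernels[axis] if axis == deriv_axis else smooth_kernels[axis]
            part = ndimage.correlate1d(part, kernel, axis=axis, mode="nearest")
        out += part
    return FilteredImage(out, log_sigma_label(sigma_mm), image.spacing_mm)


def gradient_magnitude(image: ImageVolume) -> FilteredImage:
    """Euclidean norm of the central-difference gradient (physical spacing)."""
    grads = np.gradient(image.voxels, *image.spacing_mm)
    mag = np.sqrt(sum(g * g for g in grads))
    return FilteredImage(mag, "gradient", image.spacing_mm)


def intensity_transforms(
    image: ImageVolume, which: tuple[str, ...] = INTENSITY_TRANSFORMS
) -> list[FilteredImage]:
    """Monotone per-voxel transforms (see module docstring for formulas)."""
    x = image.voxels
    m = float(np.abs(x).max())
    out = []
    for name in which:
        if name not in INTENSITY_TRANSFORMS:
            raise ValueError(f"unknown intensity transform {name!r}")
        if m == 0.0:
            y = np.ones_like(x) if name == "exponential" else np.zeros_like(x)
        elif name == "square":
            z = x - x.min()
            y = z * z / z.max() if z.max() > 0 else np.zeros_like(x)
        elif name == "squareroot":
            y = np.sign(x) * np.sqrt(np.abs(x) * m)
        elif name == "logarithm":
            scale = m / np.log(m + 1.0) if m > 0 else 1.0
            y = np.sign(x) * np.log(np.abs(x) + 1.0) * scale
        else:  # exponential
            y = np.exp(x * (np.log(m) / m)) if m != 1.0 else np.exp(x)
        out.append(FilteredImage(y, name, image.spacing_mm))
    return out


def apply_filter_bank(image: ImageVolume, config: FilterConfig = FilterConfig()) -> list[FilteredImage]:
    """All enabled derived images, ``original`` first when enabled."""
    out: list[FilteredImage] = []
    for name in config.enabled:
        if name == "original":
            out.append(FilteredImage(image.voxels.copy(), "original", image.spacing_mm))
        elif name == "wavelet":
            out.extend(wavelet_subbands(image, config.wavelet_family))
        elif name == "log":
            out.extend(log_filter(image, s) for s in config.log_sigmas_mm)
        elif name == "gradient":
            out.append(gradient_magnitude(image))
        elif name in INTENSITY_TRANSFORMS:
            out.extend(intensity_transforms(image, (name,)))
        else:
            raise ValueError(f"unknown filter {name!r}")
    return out
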