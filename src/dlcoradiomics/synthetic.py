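"""Self-contained synthetic 4DCT cohort generator.

Emulates the statistical structure the DLCO-prediction analysis assumes,
without any real imaging data:

* **Parenchyma.**  A Gaussian random field: white noise smoothed with a
  Gaussian kernel and rescaled to a fixed marginal SD around a baseline of
  about −850 HU (air-dominated lung tissue).  The abnormal-DLCO class uses
  a longer correlation length (larger smoothing kernel) and an additional
  negatively skewed low-intensity component; ``texture_effect`` scales both
  separations, so gray-level co-occurrence correlation and low-gray-level
  statistics carry class signal that vanishes exactly at
  ``texture_effect = 0``.
* **Lungs and lesions.**  The lung is an axis-aligned ellipsoid; lesions
  are soft-tissue spheres (≈ +20 HU) placed uniformly inside it, so the
  lungs-minus-GTV subtraction is always exercised.
* **Respiratory phases.**  Phase 50 (max exhalation) is Phase 0 compressed
  craniocaudally (slice axis) by ``phase_compression`` about the volume
  center, plus independent acquisition noise — phase-difference features
  are non-zero and class-informative whenever ``texture_effect > 0``.
* **Clinical covariates.**  Charlson Comorbidity Index (Poisson, mean
  shifted by ``clinical_effect`` in the abnormal class), COPD and smoking
  flags mildly coupled to the label through the same knob, and age.
* **DLCO.**  Baseline percent-predicted values drawn from two truncated
  normals (normal class centered at 95%, abnormal at 60%); the binary
  label is re-derived from the 75–140% normality rule so value and label
  are always consistent.  A configurable fraction of patients receives a
  post-treatment DLCO (baseline minus a positive reduction).

Every patient also records ``latent_texture``, the generator's own planted
texture parameter (per-patient smoothing length), which serves as the
oracle covariate for calibration tests: its class separation is exactly
proportional to ``texture_effect``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volumes import ImageVolume, MaskVolume, read_mask, read_volume, write_mask, write_volume

__all__ = [
    "CohortConfig",
    "SyntheticPatient",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "CLINICAL_COLUMNS",
]

CLINICAL_COLUMNS = (
    "patient_id",
    "cci",
    "copd",
    "smoking",
    "age",
    "dlco_baseline_pct",
    "dlco_post_pct",
)

_LUNG_HU = -850.0
_LESION_HU = 20.0
_BODY_HU = 30.0
_FIELD_SD_HU = 60.0
_BASE_SMOOTH_VOX = 1.2  # normal-class correlation length (voxels)
_SMOOTH_PER_EFFECT = 0.5  # added abnormal-class smoothing per unit effect
_SKEW_HU_PER_EFFECT = 15.0  # low-intensity emphasis component per unit effect
_LATENT_JITTER = 0.15


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int
    grid_shape: tuple[int, int, int] = (48, 48, 32)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 2.5)
    frac_abnormal: float = 0.4
    texture_effect: float = 1.0
    clinical_effect: float = 1.0
    n_lesions_range: tuple[int, int] = (1, 3)
    lesion_radius_mm_range: tuple[float, float] = (4.0, 10.0)
    phase_compression: float = 0.85
    noise_sd_hu: float = 20.0
    frac_with_post: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if len(self.grid_shape) != 3 or any(g < 8 for g in self.grid_shape):
            raise ValueError("grid_shape must be 3 dims of at least 8 voxels")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        for name in ("frac_abnormal", "frac_with_post"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.texture_effect < 0 or self.clinical_effect < 0:
            raise ValueError("effect sizes must be non-negative")
        lo, hi = self.n_lesions_range
        if not (1 <= lo <= hi):
            raise ValueError("n_lesions_range must be a non-empty interval >= 1")
        rlo, rhi = self.lesion_radius_mm_range
        if not (0 < rlo <= rhi):
            raise ValueError("lesion_radius_mm_range must be positive and non-empty")
        if not (0 < self.phase_compression <= 1):
            raise ValueError("phase_compression must lie in (0, 1]")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be non-negative")
        # lungs must be able to contain the largest lesion
        semi = self._lung_semi_axes_mm()
        if rhi >= 0.6 * min(semi):
            raise ValueError(
                f"largest lesion radius {rhi} mm does not fit inside the lung "
                f"(semi-axes {tuple(round(s, 1) for s in semi)} mm)"
            )

    def _lung_semi_axes_mm(self) -> tuple[float, float, float]:
        return tuple(
            0.42 * n * s for n, s in zip(self.grid_shape, self.spacing_mm)
        )


@dataclass
class SyntheticPatient:
    patient_id: str
    phase0: ImageVolume
    phase50: ImageVolume
    lung_mask: MaskVolume
    gtv_masks: list[MaskVolume]
    clinical: dict
    dlco_baseline_pct: float
    dlco_post_pct: float | None
    latent_texture: float = 0.0


def _ellipsoid_mask(shape, spacing, semi_axes_mm) -> np.ndarray:
    coords = [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
    ]
    xx = coords[0][:, None, None] / semi_axes_mm[0]
    yy = coords[1][None, :, None] / semi_axes_mm[1]
    zz = coords[2][None, None, :] / semi_axes_mm[2]
    return xx**2 + yy**2 + zz**2 <= 1.0


def _gaussian_field(rng, shape, sigma_vox) -> np.ndarray:
    """Smoothed white noise rescaled to unit SD (correlation length sigma)."""
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _draw_dlco_baseline(rng, abnormal: bool) -> float:
    if abnormal:
        a, b = (20 - 60) / 12, (74.9 - 60) / 12
        return float(stats.truncnorm.rvs(a, b, loc=60, scale=12, random_state=rng))
    a, b = (75.1 - 95) / 12, (140 - 95) / 12
    return float(stats.truncnorm.rvs(a, b, loc=95, scale=12, random_state=rng))


def _place_lesions(rng, config: CohortConfig, lung: np.ndarray):
    """Spheres fully inside the ellipsoidal lung, uniform centers."""
    shape, spacing = config.grid_shape, config.spacing_mm
    semi = np.array(config._lung_semi_axes_mm())
    coords = [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
    ]
    n_lesions = int(rng.integers(config.n_lesions_range[0], config.n_lesions_range[1] + 1))
    masks = []
    for _ in range(n_lesions):
        radius = float(rng.uniform(*config.lesion_radius_mm_range))
        for _attempt in range(200):
            # uniform in the shrunken ellipsoid that keeps the sphere inside
            u = rng.uniform(-1, 1, size=3)
            if (u**2).sum() > 1:
                continue
            center = u * (semi - radius)
            if np.any(semi - radius <= 0):
                raise ValueError("lesion too large for the lung")
            # containment check in ellipsoid coordinates
            if ((center / (semi - radius)) ** 2).sum() <= 1.0:
                break
        dist2 = (
            ((coords[0][:, None, None] - center[0]) / 1.0) ** 2
            + ((coords[1][None, :, None] - center[1]) / 1.0) ** 2
            + ((coords[2][None, None, :] - center[2]) / 1.0) ** 2
        )
        sphere = dist2 <= radius**2
        sphere &= lung  # numerical safety at the boundary
        if sphere.any():
            masks.append(sphere)
    return masks


def _compress_slices(voxels: np.ndarray, compression: float) -> np.ndarray:
    """Craniocaudal (axis 2) scaling about the volume center."""
    if compression == 1.0:
        return voxels.copy()
    nz = voxels.shape[2]
    center = (nz - 1) / 2.0
    z_out = np.arange(nz, dtype=float)
    z_src = center + (z_out - center) / compression
    z_src = np.clip(z_src, 0, nz - 1)
    idx = np.broadcast_to(z_src, voxels.shape).copy()
    base = np.indices(voxels.shape).astype(float)
    coords = np.stack([base[0], base[1], idx])
    return ndimage.map_coordinates(voxels, coords, order=1, mode="nearest")


def generate_cohort(config: CohortConfig) -> tuple[list[SyntheticPatient], pd.DataFrame]:
    """Generate patients and their clinical table; fully seeded."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    shape, spacing = config.grid_shape, config.spacing_mm
    lung = _ellipsoid_mask(shape, spacing, config._lung_semi_axes_mm())
    sigma_iso = np.array([_BASE_SMOOTH_VOX] * 3)

    patients: list[SyntheticPatient] = []
    rows = []
    for k in range(config.n_patients):
        pid = f"SYN{k:04d}"
        abnormal = bool(rng.random() < config.frac_abnormal)

        # planted texture parameter: smoothing length (class-separated)
        latent = (
            _BASE_SMOOTH_VOX
            + (config.texture_effect * _SMOOTH_PER_EFFECT if abnormal else 0.0)
            + float(rng.normal(0.0, _LATENT_JITTER))
        )
        latent = max(latent, 0.4)
        field = _gaussian_field(rng, shape, latent * sigma_iso / _BASE_SMOOTH_VOX)
        voxels = np.full(shape, _BODY_HU)
        parenchyma = _LUNG_HU + _FIELD_SD_HU * field
        if abnormal and config.texture_effect > 0:
            lowtail = _gaussian_field(rng, shape, sigma_iso)
            parenchyma = parenchyma - (
                _SKEW_HU_PER_EFFECT * config.texture_effect * np.abs(lowtail)
            )
        voxels = np.where(lung, parenchyma, voxels)

        gtv_arrays = _place_lesions(rng, config, lung)
        for sphere in gtv_arrays:
            voxels = np.where(sphere, _LESION_HU + 5.0 * rng.standard_normal(shape), voxels)

        noise0 = rng.normal(0.0, config.noise_sd_hu, size=shape)
        phase0_vox = voxels + noise0
        noise50 = rng.normal(0.0, config.noise_sd_hu, size=shape)
        phase50_vox = _compress_slices(voxels, config.phase_compression) + noise50

        phase0 = ImageVolume(phase0_vox, spacing)
        phase50 = ImageVolume(phase50_vox, spacing)
        lung_mask = MaskVolume(lung.copy(), spacing)
        gtv_masks = [MaskVolume(g, spacing) for g in gtv_arrays]

        cci = int(rng.poisson(2.0 + (config.clinical_effect if abnormal else 0.0)))
        p_copd = 1.0 / (1.0 + np.exp(-(-1.1 + 0.8 * config.clinical_effect * abnormal)))
        copd = int(rng.random() < p_copd)
        p_smoke = min(0.5 + 0.15 * config.clinical_effect * abnormal, 0.95)
        smoking = int(rng.random() < p_smoke)
        age = float(np.clip(rng.normal(72.0, 8.0), 40.0, 90.0))

        dlco_baseline = _draw_dlco_baseline(rng, abnormal)
        dlco_post = None
        if rng.random() < config.frac_with_post:
            reduction = abs(rng.normal(8.0, 6.0))
            dlco_post = float(max(dlco_baseline - reduction, 20.0))

        clinical = {
            "patient_id": pid,
            "cci": cci,
            "copd": copd,
            "smoking": smoking,
            "age": age,
            "dlco_baseline_pct": dlco_baseline,
            "dlco_post_pct": dlco_post,
        }
        patients.append(
            SyntheticPatient(
                pid, phase0, phase50, lung_mask, gtv_masks, clinical,
                dlco_baseline, dlco_post, latent,
            )
        )
        rows.append(clinical)

    table = pd.DataFrame(rows, columns=list(CLINICAL_COLUMNS))
    if table.empty:
        table = pd.DataFrame(columns=list(CLINICAL_COLUMNS))
    return patients, table


def write_cohort(
    patients: list[SyntheticPatient],
    table: pd.DataFrame,
    directory: str | Path,
    image_format: str = "nrrd",
) -> dict:
    """Serialize a cohort; returns a manifest of every written path.

    Volumes and masks go to NRRD (default) or NIfTI-1; masks are stored as
    unsigned 8-bit {0, 1}; the clinical table becomes a CSV with an empty
    field for a missing post-treatment DLCO.
    """
    if image_format not in ("nrrd", "nii.gz", "nii"):
        raise ValueError(f"unsupported image format {image_format!r}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = image_format
    manifest: dict = {"patients": {}, "clinical_table": str(directory / "clinical.csv")}
    for p in patients:
        pdir = directory / p.patient_id
        pdir.mkdir(exist_ok=True)
        entry = {
            "phase0": str(write_volume(p.phase0, pdir / f"phase0.{ext}")),
            "phase50": str(write_volume(p.phase50, pdir / f"phase50.{ext}")),
            "lung_mask": str(write_mask(p.lung_mask, pdir / f"lung_mask.{ext}")),
            "gtv_masks": [
                str(write_mask(g, pdir / f"gtv_{i}.{ext}"))
                for i, g in enumerate(p.gtv_masks)
            ],
        }
        manifest["patients"][p.patient_id] = entry
    out = table.copy()
    out.to_csv(directory / "clinical.csv", index=False, float_format="%.6f")
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["manifest_path"] = str(directory / "manifest.json")
    return manifest


def read_cohort(directory: str | Path) -> tuple[list[SyntheticPatient], pd.DataFrame]:
    """Load a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    table = pd.read_csv(manifest["clinical_table"])
    by_id = table.set_index("patient_id", drop=False)
    patients = []
    for pid in sorted(manifest["patients"]):
        entry = manifest["patients"][pid]
        row = by_id.loc[pid]
        post = row["dlco_post_pct"]
        post = None if pd.isna(post) else float(post)
        patients.append(
            SyntheticPatient(
                pid,
                read_volume(entry["phase0"]),
                read_volume(entry["phase50"]),
                read_mask(entry["lung_mask"]),
                [read_mask(g) for g in entry["gtv_masks"]],
                {c: row[c] for c in CLINICAL_COLUMNS},
                float(row["dlco_baseline_pct"]),
                post,
            )
        )
    return patients, table
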