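"""Synthetic CT study generator: dose/kernel condition grids, water phantom
and lung-nodule volumes with dose- and kernel-dependent correlated noise.

The generator emulates the statistical structure the robustness analysis
assumes, not a particular scanner:

* A reconstruction kernel is modelled by a Gaussian point-spread scale
  ``psf_sigma`` (voxels), which sets the spatial correlation of the noise,
  and a ``noise_gain``, the relative noise magnitude at fixed dose.  Within
  each family (FBP, IR) sharper kernels have larger gains; IR kernels carry a
  noise discount relative to comparably sharp FBP kernels.  These parameters
  are qualitative surrogates, not scanner measurements.
* Quantum noise scales as 1 / sqrt(dose fraction): the in-water noise level
  is ``sigma_ref * noise_gain / sqrt(fraction)``.
* Reduced-dose images are simulated in the image domain by adding correlated
  Gaussian noise with variance ``sigma_ref^2 * gain^2 * (1/to - 1/from)`` so
  the total variance matches a direct acquisition at the target dose.  (The
  sinogram-domain noise-injection used with real scanner raw data is out of
  scope; this is an image-domain surrogate.)
* Nodules are ellipsoids with a smooth correlated internal texture field,
  embedded in textured lung background; the analytic ellipsoid membership is
  returned as the ground-truth mask.

Noise fields are white Gaussian noise convolved with the kernel PSF and
rescaled by the exact L2 norm of the smoothing kernel, so the field has unit
variance before scaling regardless of ``psf_sigma``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import ROIMask, VolumeGrid, save_mask, save_volume
from .robustness import ConditionGrid

__all__ = [
    "KernelModel",
    "DoseLevel",
    "NoduleCaseParams",
    "FBP_KERNELS",
    "IR_KERNELS",
    "PHANTOM_KERNELS",
    "NODULE_KERNELS",
    "PHANTOM_DOSES",
    "NODULE_DOSES",
    "phantom_condition_grid",
    "nodule_condition_grid",
    "condition_label",
    "parse_condition",
    "ctdivol_from_mas",
    "derive_seed",
    "correlated_noise",
    "water_cylinder_mask",
    "generate_water_phantom",
    "generate_nodule_volume",
    "simulate_dose_reduction",
    "sample_nodule_cases",
    "generate_study",
]


@dataclass(frozen=True)
class KernelModel:
    """Surrogate reconstruction kernel: PSF scale and relative noise gain.

    The kernel acts in the axial plane, so ``psf_sigma`` sets the in-plane
    (y, x) noise correlation; the through-plane correlation ``psf_sigma_z``
    is governed by the slice profile and is kernel-independent.  CT noise is
    therefore anisotropic, increasingly so for smooth kernels.
    """

    name: str
    psf_sigma: float  # in-plane, voxels
    noise_gain: float  # relative noise magnitude at fixed dose
    psf_sigma_z: float = 0.3  # through-plane (slice profile), voxels

    def __post_init__(self) -> None:
        if self.psf_sigma < 0 or self.psf_sigma_z < 0:
            raise ValueError("psf sigmas must be >= 0")
        if self.noise_gain <= 0:
            raise ValueError("noise_gain must be > 0")

    @property
    def noise_psf(self) -> tuple[float, float, float]:
        return (self.psf_sigma_z, self.psf_sigma, self.psf_sigma)


@dataclass(frozen=True)
class DoseLevel:
    """A dose level as a fraction of the reference dose."""

    label: str
    fraction: float

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError("dose fraction must be in (0, 1]")


# Kernel catalogs: smooth -> sharp, with noise gain rising as sharpness rises.
FBP_KERNELS = (
    KernelModel("B10f", 2.0, 0.50),
    KernelModel("B30f", 1.2, 0.75),
    KernelModel("B45f", 0.8, 1.00),
    KernelModel("B70f", 0.3, 2.00),
)
IR_KERNELS = (
    KernelModel("I26f\\5", 1.6, 0.45),
    KernelModel("I44f\\3", 0.9, 0.80),
    KernelModel("I50f\\3", 0.7, 0.95),
    KernelModel("I70f\\1", 0.35, 1.60),
)
PHANTOM_KERNELS = FBP_KERNELS + IR_KERNELS
NODULE_KERNELS = (FBP_KERNELS[2], IR_KERNELS[1], IR_KERNELS[2])  # B45f, I44f\3, I50f\3

# Phantom dose grid in CTDIvol (mGy); 17.1 mGy is the reference acquisition.
PHANTOM_DOSES = (
    DoseLevel("17.1", 1.0),
    DoseLevel("7.6", 7.6 / 17.1),
    DoseLevel("3.8", 3.8 / 17.1),
)
# Nodule dose grid in percent of clinical dose.
NODULE_DOSES = (
    DoseLevel("100", 1.0),
    DoseLevel("25", 0.25),
    DoseLevel("10", 0.10),
    DoseLevel("3", 0.03),
)


def condition_label(kernel: KernelModel, dose: DoseLevel) -> str:
    return f"{kernel.name}@{dose.label}"


def parse_condition(
    label: str,
    kernels: tuple[KernelModel, ...],
    doses: tuple[DoseLevel, ...],
) -> tuple[KernelModel, DoseLevel]:
    name, _, dose_label = label.rpartition("@")
    kernel = next((k for k in kernels if k.name == name), None)
    dose = next((d for d in doses if d.label == dose_label), None)
    if kernel is None or dose is None:
        raise KeyError(f"unknown condition label {label!r}")
    return kernel, dose


def phantom_condition_grid() -> ConditionGrid:
    """3 dose levels x 8 kernels = 24 phantom conditions; reference B45f@17.1."""
    labels = tuple(
        condition_label(k, d) for d in PHANTOM_DOSES for k in PHANTOM_KERNELS
    )
    return ConditionGrid(labels, condition_label(FBP_KERNELS[2], PHANTOM_DOSES[0]))


def nodule_condition_grid() -> ConditionGrid:
    """4 dose levels x 3 kernels = 12 nodule conditions; reference B45f@100."""
    labels = tuple(
        condition_label(k, d) for d in NODULE_DOSES for k in NODULE_KERNELS
    )
    return ConditionGrid(labels, condition_label(FBP_KERNELS[2], NODULE_DOSES[0]))


def ctdivol_from_mas(
    mas: float, ref_mas: float = 225.0, ref_ctdivol_mgy: float = 17.1
) -> float:
    """CTDIvol at a tube-current-time product, by linear scaling from an anchor.

    Dose output scales linearly with effective mAs at fixed kV; the default
    anchor is 225 mAs -> 17.1 mGy (32 cm body phantom).
    """
    if mas <= 0 or ref_mas <= 0:
        raise ValueError("mAs values must be positive")
    return ref_ctdivol_mgy * mas / ref_mas


def derive_seed(master_seed: int, *parts: object) -> int:
    """Deterministic per-volume seed from a master seed and identifying parts."""
    h = hashlib.sha256(repr((int(master_seed),) + parts).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


@lru_cache(maxsize=256)
def _axis_l2_norm(sigma: float) -> float:
    """L2 norm of a 1D Gaussian smoothing kernel."""
    if sigma == 0:
        return 1.0
    half = max(1, int(np.ceil(4 * sigma)))
    impulse = np.zeros(2 * half + 1)
    impulse[half] = 1.0
    w = gaussian_filter(impulse, sigma, mode="constant")
    return float(np.sqrt((w**2).sum()))


def correlated_noise(
    shape: tuple[int, int, int],
    psf_sigma: float | tuple[float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance Gaussian noise field with PSF-scale spatial correlation.

    ``psf_sigma`` may be a scalar (isotropic) or a per-axis triple.
    """
    white = rng.standard_normal(shape)
    sigmas = (
        (psf_sigma,) * 3 if np.isscalar(psf_sigma) else tuple(psf_sigma)
    )
    if all(s == 0 for s in sigmas):
        return white
    norm = float(np.prod([_axis_l2_norm(float(s)) for s in sigmas]))
    # periodic boundaries keep the per-voxel variance exactly sum(w^2);
    # reflection would inflate it near the edges
    return gaussian_filter(white, sigmas, mode="wrap") / norm


def _nodule_texture(
    shape: tuple[int, int, int],
    corr: float,
    anisotropy: tuple[float, float, float],
    coarse_fraction: float,
    skew: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance internal texture field of one nodule.

    A mixture of a fine and a coarse (3x scale) correlated field, optionally
    anisotropic (per-axis correlation scale factors) and skewed by a
    quadratic transform ``x + skew * (x^2 - 1)`` (variance-renormalised).
    Real nodules are heterogeneous at several scales and their HU histograms
    are rarely symmetric; these per-case properties give each case its own
    response to acquisition noise.
    """
    sig = tuple(corr * a for a in anisotropy)
    fine = correlated_noise(shape, sig, rng)
    if coarse_fraction > 0:
        coarse = correlated_noise(shape, tuple(3 * s for s in sig), rng)
        f = np.sqrt(1 - coarse_fraction) * fine + np.sqrt(coarse_fraction) * coarse
    else:
        f = fine
    if skew != 0:
        # var(x + a(x^2 - 1)) = 1 + 2 a^2 for x ~ N(0, 1)
        f = (f + skew * (f**2 - 1)) / np.sqrt(1 + 2 * skew**2)
    return f


def _add_noise(
    values: np.ndarray,
    sigma: float,
    kernel: KernelModel,
    rng: np.random.Generator,
) -> np.ndarray:
    if sigma == 0:
        return values
    return values + sigma * correlated_noise(values.shape, kernel.noise_psf, rng)


def water_cylinder_mask(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    radius_mm: float,
    margin_mm: float = 0.0,
) -> ROIMask:
    """Voxels inside the water cylinder (axis along z), optionally shrunk."""
    nz, ny, nx = shape
    y = (np.arange(ny) - (ny - 1) / 2) * spacing[1]
    x = (np.arange(nx) - (nx - 1) / 2) * spacing[2]
    r2 = y[:, None] ** 2 + x[None, :] ** 2
    disk = r2 <= (radius_mm - margin_mm) ** 2
    return ROIMask(np.broadcast_to(disk, shape).copy(), spacing)


def generate_water_phantom(
    shape: tuple[int, int, int] = (24, 72, 72),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    dose: DoseLevel = PHANTOM_DOSES[0],
    kernel: KernelModel = FBP_KERNELS[2],
    sigma_ref: float = 10.0,
    seed: int = 0,
    radius_mm: float | None = None,
) -> VolumeGrid:
    """Homogeneous water cylinder (0 HU) in air (-1000 HU) plus noise.

    The correlated noise field is scaled to standard deviation
    ``sigma_ref * kernel.noise_gain / sqrt(dose.fraction)`` (the in-water
    noise level).  Deterministic for a fixed seed.
    """
    if sigma_ref < 0:
        raise ValueError("sigma_ref must be >= 0")
    if radius_mm is None:
        radius_mm = 0.45 * min(shape[1] * spacing[1], shape[2] * spacing[2])
    if radius_mm <= 0:
        raise ValueError("invalid phantom geometry: nonpositive radius")
    water = water_cylinder_mask(shape, spacing, radius_mm)
    values = np.where(water.data, 0.0, -1000.0)
    sigma = sigma_ref * kernel.noise_gain / np.sqrt(dose.fraction)
    rng = np.random.default_rng(seed)
    return VolumeGrid(_add_noise(values, sigma, kernel, rng), spacing)


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center: tuple[float, float, float],
    semi_axes_mm: tuple[float, float, float],
) -> np.ndarray:
    coords = [
        (np.arange(n) - c) * s for n, c, s in zip(shape, center, spacing)
    ]
    zz = (coords[0] / semi_axes_mm[0])[:, None, None] ** 2
    yy = (coords[1] / semi_axes_mm[1])[None, :, None] ** 2
    xx = (coords[2] / semi_axes_mm[2])[None, None, :] ** 2
    return zz + yy + xx <= 1.0


def generate_nodule_volume(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center: tuple[float, float, float],
    semi_axes_mm: tuple[float, float, float],
    nodule_hu: float = 40.0,
    texture_sigma: float = 50.0,
    texture_corr: float = 2.0,
    texture_anisotropy: tuple[float, float, float] = (1.0, 1.0, 1.0),
    texture_coarse_fraction: float = 0.0,
    texture_skew: float = 0.0,
    background_hu: float = -800.0,
    background_texture_sigma: float = 40.0,
    background_corr: float = 2.0,
    edge_blur_voxels: float = 0.0,
    dose: DoseLevel = NODULE_DOSES[0],
    kernel: KernelModel = FBP_KERNELS[2],
    sigma_ref: float = 10.0,
    noise_scale: float = 1.0,
    seed: int = 0,
    anatomy_seed: int | None = None,
) -> tuple[VolumeGrid, ROIMask]:
    """Heterogeneous ellipsoidal nodule in lung background plus noise.

    The nodule interior carries a smooth correlated texture field (standard
    deviation ``texture_sigma``, correlation scale ``texture_corr`` voxels),
    the background its own texture; ``edge_blur_voxels > 0`` applies a
    partial-volume ramp to the nodule boundary.  Acquisition noise is added
    as in :func:`generate_water_phantom`, scaled by the per-case
    ``noise_scale``.  The returned mask is the analytic ellipsoid membership.

    ``anatomy_seed`` (default: ``seed``) controls the deterministic anatomy;
    ``seed`` controls the acquisition noise, so the same case can be imaged
    under several conditions.
    """
    semi_vox = [a / s for a, s in zip(semi_axes_mm, spacing)]
    if any(a <= 0 for a in semi_axes_mm):
        raise ValueError("semi-axes must be positive")
    if any(
        c - a < 0 or c + a >= n
        for c, a, n in zip(center, semi_vox, shape)
    ):
        raise ValueError("nodule does not fit inside the volume")
    if anatomy_seed is None:
        anatomy_seed = seed
    rng_anat = np.random.default_rng(anatomy_seed)
    inside = _ellipsoid_mask(shape, spacing, center, semi_axes_mm)
    alpha = inside.astype(float)
    if edge_blur_voxels > 0:
        alpha = gaussian_filter(alpha, edge_blur_voxels)
    nodule_field = nodule_hu + (
        texture_sigma
        * _nodule_texture(
            shape, texture_corr, texture_anisotropy,
            texture_coarse_fraction, texture_skew, rng_anat,
        )
        if texture_sigma > 0
        else 0.0
    )
    bg_field = background_hu + (
        background_texture_sigma * correlated_noise(shape, background_corr, rng_anat)
        if background_texture_sigma > 0
        else 0.0
    )
    values = alpha * nodule_field + (1.0 - alpha) * bg_field
    sigma = sigma_ref * kernel.noise_gain * noise_scale / np.sqrt(dose.fraction)
    rng_noise = np.random.default_rng(seed)
    values = _add_noise(values, sigma, kernel, rng_noise)
    return VolumeGrid(values, spacing), ROIMask(inside, spacing)


def simulate_dose_reduction(
    volume: VolumeGrid,
    from_fraction: float,
    to_fraction: float,
    kernel: KernelModel,
    sigma_ref: float = 10.0,
    seed: int = 0,
    noise_scale: float = 1.0,
) -> VolumeGrid:
    """Image-domain reduced-dose surrogate: add correlated noise.

    The added field has in-water standard deviation
    ``sigma_ref * gain * noise_scale * sqrt(1/to - 1/from)`` so the total
    noise variance equals a direct acquisition at ``to_fraction``.
    """
    if not 0 < to_fraction < from_fraction <= 1:
        raise ValueError(
            f"need 0 < to_fraction < from_fraction <= 1, got "
            f"{to_fraction} and {from_fraction}"
        )
    sigma_add = (
        sigma_ref
        * kernel.noise_gain
        * noise_scale
        * np.sqrt(1.0 / to_fraction - 1.0 / from_fraction)
    )
    rng = np.random.default_rng(seed)
    return VolumeGrid(
        _add_noise(volume.values.copy(), sigma_add, kernel, rng), volume.spacing
    )


@dataclass(frozen=True)
class NoduleCaseParams:
    """Per-case anatomy parameters of one synthetic nodule."""

    case_id: str
    diameter_mm: float  # longest in-plane diameter
    aspect_y: float  # in-plane minor/major axis ratio
    aspect_z: float  # through-plane/major axis ratio
    nodule_hu: float
    texture_sigma: float
    noise_scale: float  # per-patient noise magnitude factor
    texture_anisotropy: tuple[float, float, float] = (1.0, 1.0, 1.0)
    texture_coarse_fraction: float = 0.0
    texture_skew: float = 0.0

    @property
    def semi_axes_mm(self) -> tuple[float, float, float]:
        a = self.diameter_mm / 2.0
        return (a * self.aspect_z, a * self.aspect_y, a)


def sample_nodule_cases(
    n_cases: int = 33,
    seed: int = 0,
    diameter_median_mm: float = 16.0,
    diameter_log_sigma: float = 0.45,
    diameter_range_mm: tuple[float, float] = (7.0, 46.0),
    nodule_hu_mean: float = 40.0,
    nodule_hu_sd: float = 25.0,
    texture_sigma_range: tuple[float, float] = (30.0, 70.0),
    noise_scale_log_sigma: float = 0.25,
) -> list[NoduleCaseParams]:
    """Draw a nodule population matching the study demographics.

    Longest in-plane diameters are lognormal (median 16 mm, mean ~18 mm),
    clipped to 7-46 mm; nodule density, internal heterogeneity (texture
    magnitude, anisotropy, scale mixture, skew) and the per-patient noise
    magnitude all vary across cases.
    """
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        d = float(
            np.clip(
                diameter_median_mm * np.exp(diameter_log_sigma * rng.standard_normal()),
                *diameter_range_mm,
            )
        )
        cases.append(
            NoduleCaseParams(
                case_id=f"case{i:02d}",
                diameter_mm=d,
                aspect_y=float(rng.uniform(0.7, 1.0)),
                aspect_z=float(rng.uniform(0.7, 1.0)),
                nodule_hu=float(rng.normal(nodule_hu_mean, nodule_hu_sd)),
                texture_sigma=float(rng.uniform(*texture_sigma_range)),
                noise_scale=float(np.exp(noise_scale_log_sigma * rng.standard_normal())),
                texture_anisotropy=tuple(rng.uniform(0.6, 1.6, size=3)),
                texture_coarse_fraction=float(rng.uniform(0.2, 0.6)),
                texture_skew=float(rng.uniform(0.0, 0.6)),
            )
        )
    return cases


def generate_study(config: "StudyConfig", out_dir: str | Path) -> Path:
    """Write a full synthetic study to disk.

    Layout: ``<root>/<case>/<condition>/volume.nii.gz`` plus
    ``mask.nii.gz`` (reference contour) and ``mask_repeat.nii.gz`` (repeat
    contour, reference condition of repeat-subset cases only) under the
    reference condition directory, and a ``manifest.json`` at the root.
    """
    from .pipeline import StudyConfig, simulate_case_volumes  # cycle-free at call time

    if not isinstance(config, StudyConfig):
        raise TypeError("config must be a StudyConfig")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {
        "mode": config.mode,
        "seed": config.seed,
        "reference": config.grid.reference,
        "conditions": list(config.grid.conditions),
        "cases": [],
    }
    for case in config.iter_cases():
        volumes, mask, repeat_mask = simulate_case_volumes(config, case)
        case_dir = out / case.case_id
        for cond, vol in volumes.items():
            cond_dir = case_dir / cond.replace("\\", "_").replace("@", "_at_")
            cond_dir.mkdir(parents=True, exist_ok=True)
            save_volume(vol, cond_dir / "volume.nii.gz")
            if cond == config.grid.reference:
                if isinstance(mask, list):
                    for i, m in enumerate(mask):
                        save_mask(m, cond_dir / f"mask_roi{i}.nii.gz")
                else:
                    save_mask(mask, cond_dir / "mask.nii.gz")
                    if repeat_mask is not None:
                        save_mask(repeat_mask, cond_dir / "mask_repeat.nii.gz")
        manifest["cases"].append(  # type: ignore[union-attr]
            {"case_id": case.case_id, "has_repeat": repeat_mask is not None}
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
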