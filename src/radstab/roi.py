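"""ROI placement, segmentation and repeat-contour perturbation.

Covers the region-of-interest operations of the study design: seeded random
placement of non-overlapping spherical ROIs inside a phantom, Otsu-initialised
semiautomatic nodule segmentation (threshold + 26-connected component), and a
seeded boundary-flip surrogate for human repeat contouring.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .grid import ROIMask, VolumeGrid

__all__ = [
    "PlacementError",
    "DegenerateInputError",
    "EmptySegmentationError",
    "place_spherical_rois",
    "otsu_threshold",
    "segment_nodule",
    "perturb_mask",
    "boundary_voxels",
    "adjacent_background",
    "symmetric_difference_fraction",
]

# 26-connectivity structuring element, shared by segmentation and perturbation
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


class PlacementError(RuntimeError):
    """Requested ROIs could not be placed without overlap."""


class DegenerateInputError(ValueError):
    """Input has no contrast (all values identical)."""


class EmptySegmentationError(RuntimeError):
    """Seed point fell below the local Otsu threshold."""


def _sphere_offsets(diameter_mm: float, spacing: tuple[float, float, float]) -> np.ndarray:
    """Voxel offsets whose centers lie within radius d/2 of a voxel center.

    Membership is the closed ball (distance <= radius), so a 10 mm sphere at
    1 mm spacing contains 515 lattice points.
    """
    r = diameter_mm / 2.0
    half = [int(np.floor(r / s)) for s in spacing]
    axes = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    inside = zz**2 + yy**2 + xx**2 <= r**2
    offs = np.argwhere(inside)
    offs -= np.array(half)
    return offs


def place_spherical_rois(
    volume: VolumeGrid,
    n: int,
    diameter_mm: float,
    interior: ROIMask,
    seed: int,
    max_attempts_per_roi: int = 2000,
) -> list[ROIMask]:
    """Place ``n`` non-overlapping spherical ROIs inside ``interior``.

    Sphere centers are snapped to voxel centers and sampled uniformly from the
    interior by rejection; every member voxel must lie inside ``interior`` and
    spheres must be pairwise voxel-disjoint.  Deterministic for a fixed seed.

    Raises
    ------
    PlacementError
        If a sphere cannot be placed within the attempt budget.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    interior.check_compatible(volume)
    rng = np.random.default_rng(seed)
    offsets = _sphere_offsets(diameter_mm, volume.spacing)
    candidates = np.argwhere(interior.data)
    if len(candidates) == 0:
        raise PlacementError("interior is empty")
    occupied = np.zeros(volume.shape, dtype=bool)
    shape = np.array(volume.shape)
    masks: list[ROIMask] = []
    for _ in range(n):
        for _attempt in range(max_attempts_per_roi):
            center = candidates[rng.integers(len(candidates))]
            vox = center + offsets
            if (vox < 0).any() or (vox >= shape).any():
                continue
            zi, yi, xi = vox[:, 0], vox[:, 1], vox[:, 2]
            if not interior.data[zi, yi, xi].all():
                continue
            if occupied[zi, yi, xi].any():
                continue
            m = np.zeros(volume.shape, dtype=bool)
            m[zi, yi, xi] = True
            occupied |= m
            masks.append(ROIMask(m, volume.spacing))
            break
        else:
            raise PlacementError(
                f"could not place sphere {len(masks) + 1} of {n} "
                f"(diameter {diameter_mm} mm) after {max_attempts_per_roi} attempts"
            )
    return masks


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Between-class-variance-maximising threshold of a value sample.

    A fixed-bin (default 256) histogram is scanned exhaustively; when several
    cut points maximise the between-class variance (a plateau of empty bins
    between well-separated modes), the middle of the plateau is returned, so
    a perfectly bimodal sample yields the midpoint between the modes.

    Raises
    ------
    DegenerateInputError
        If all values are identical.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2 or np.ptp(values) == 0:
        raise DegenerateInputError("Otsu threshold requires at least two distinct values")
    hist, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    w0 = np.cumsum(hist)[:-1].astype(float)  # mass at or below cut k
    w1 = hist.sum() - w0
    s0 = np.cumsum(hist * centers)[:-1]
    total = (hist * centers).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        m0 = s0 / w0
        m1 = (total - s0) / w1
        sb2 = w0 * w1 * (m0 - m1) ** 2
    sb2[(w0 == 0) | (w1 == 0)] = -np.inf
    plateau = np.flatnonzero(sb2 >= sb2.max() - 1e-12 * abs(sb2.max()))
    k = plateau[len(plateau) // 2]
    return float(edges[k + 1])


def segment_nodule(
    volume: VolumeGrid,
    seed_point: tuple[int, int, int],
    box_radius_mm: float = 25.0,
) -> ROIMask:
    """Otsu-initialised nodule segmentation around a seed point.

    An Otsu threshold is computed over a local box around ``seed_point``; the
    returned mask is the 26-connected component of supra-threshold voxels that
    contains the seed.

    Raises
    ------
    EmptySegmentationError
        If the seed voxel falls below the local threshold.
    """
    seed_point = tuple(int(c) for c in seed_point)
    shape = volume.shape
    if any(c < 0 or c >= s for c, s in zip(seed_point, shape)):
        raise ValueError(f"seed point {seed_point} outside volume of shape {shape}")
    lo = [max(0, int(c - box_radius_mm / s)) for c, s in zip(seed_point, volume.spacing)]
    hi = [
        min(n, int(c + box_radius_mm / s) + 1)
        for c, s, n in zip(seed_point, volume.spacing, shape)
    ]
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    local = volume.values[box]
    thr = otsu_threshold(local)
    if volume.values[seed_point] <= thr:
        raise EmptySegmentationError(
            f"seed value {volume.values[seed_point]:.1f} HU is below the local "
            f"Otsu threshold {thr:.1f} HU"
        )
    supra = local > thr
    labels, _ = ndimage.label(supra, structure=_STRUCT26)
    seed_local = tuple(c - a for c, a in zip(seed_point, lo))
    component = labels == labels[seed_local]
    out = np.zeros(shape, dtype=bool)
    out[box] = component
    return ROIMask(out, volume.spacing)


def boundary_voxels(mask: ROIMask) -> np.ndarray:
    """Member voxels with at least one 26-neighbour outside the mask."""
    return mask.data & ~ndimage.binary_erosion(mask.data, structure=_STRUCT26)


def adjacent_background(mask: ROIMask) -> np.ndarray:
    """Background voxels 26-adjacent to the mask."""
    return ~mask.data & ndimage.binary_dilation(mask.data, structure=_STRUCT26)


def perturb_mask(mask: ROIMask, boundary_flip_prob: float, seed: int) -> ROIMask:
    """Stochastic repeat-contour surrogate: independent boundary flips.

    Each boundary voxel of the mask is removed, and each background voxel
    adjacent to the mask is added, independently with probability
    ``boundary_flip_prob``.  Voxels in the eroded core are never removed; when
    the core is empty (e.g. a single-voxel mask) no removals occur at all, so
    the result is always nonempty.  Deterministic for a fixed seed.
    """
    if not 0.0 <= boundary_flip_prob <= 0.5:
        raise ValueError("boundary_flip_prob must be in [0, 0.5]")
    if mask.count == 0:
        raise ValueError("cannot perturb an empty mask")
    rng = np.random.default_rng(seed)
    core = ndimage.binary_erosion(mask.data, structure=_STRUCT26)
    removable = mask.data & ~core
    if not core.any():
        removable[:] = False
    addable = adjacent_background(mask)
    out = mask.data.copy()
    out[removable] &= rng.random(int(removable.sum())) >= boundary_flip_prob
    add_idx = np.argwhere(addable)
    picked = rng.random(len(add_idx)) < boundary_flip_prob
    out[tuple(add_idx[picked].T)] = True
    if not out.any():
        raise RuntimeError("perturbation produced an empty mask")
    return ROIMask(out, mask.spacing)


def symmetric_difference_fraction(a: ROIMask, b: ROIMask) -> float:
    """|A xor B| / |A| — relative disagreement between two contours."""
    if a.count == 0:
        raise ValueError("reference mask is empty")
    return float((a.data ^ b.data).sum() / a.count)
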