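"""3D gray-level co-occurrence matrices and Haralick-style texture features.

A GLCM is the normalised joint distribution P(i, j) of quantized gray levels
of voxel pairs separated by a fixed integer displacement (offset).  In 3D,
26-connectivity yields 13 canonical offsets (one per antipodal pair); each of
the 18 base features is evaluated per offset and summarised by its mean and
range (max - min) across offsets.

Conventions
-----------
* Gray levels are quantized into ``levels`` equal-width bins over the ROI's
  [min, max]; levels are indexed 1..levels in all formulas.
* Matrices are symmetrized (transpose added before normalisation) by default,
  so the marginals satisfy Px = Py and mu_x = mu_y.
* GLCM entropy, sum/difference entropies and the information-measure
  entropies Hx, Hy, Hxy, Hxy1, Hxy2 use the natural log; 0*log(0) := 0.
* Information correlation B is ``1 - exp(-2 (Hxy2 - Hxy))`` and the maximal
  correlation coefficient is the second-largest eigenvalue of
  ``U(i,j) = sum_k P(i,k) P(j,k) / (Px(i) Py(k))``; set ``icb_sqrt`` /
  ``mcc_sqrt`` for the classical square-root variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

from .grid import ROIMask, VolumeGrid
from .histogram import histogram_features

__all__ = [
    "GLCM_FEATURES",
    "GLCMSpec",
    "GLCMMatrix",
    "NoValidPairsError",
    "glcm_offsets",
    "quantize_roi",
    "compute_glcm",
    "glcm_feature",
    "glcm_features_all_offsets",
    "aggregate_directions",
    "extract_all",
]

#: The 18 base GLCM features, in battery order.
GLCM_FEATURES = (
    "Mean",
    "Variance",
    "Energy",
    "Entropy",
    "Contrast",
    "Correlation",
    "Dissimilarity",
    "Homogeneity",
    "Information correlation A",
    "Information correlation B",
    "Maximal correlation coefficient",
    "Diff average",
    "Diff variance",
    "Diff entropy",
    "Sum average",
    "Sum variance",
    "Sum entropy",
    "Angular 2nd moment",
)


class NoValidPairsError(RuntimeError):
    """No voxel pair inside the ROI realises the requested offset."""


def glcm_offsets() -> list[tuple[int, int, int]]:
    """The 13 canonical 3D displacement vectors.

    All nonzero vectors in {-1, 0, 1}^3 with one representative per antipodal
    pair; the canonical sign makes the first nonzero component positive.
    """
    out = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                v = (dz, dy, dx)
                if v == (0, 0, 0):
                    continue
                first = next(c for c in v if c != 0)
                if first > 0:
                    out.append(v)
    assert len(out) == 13
    return out


def quantize_roi(volume: VolumeGrid, mask: ROIMask, levels: int) -> np.ndarray:
    """Quantize ROI intensities into 1..levels equal-width bins.

    Bins span the ROI's [min, max]; the maximum maps to ``levels`` and a
    constant ROI maps everything to level 1.  Returns an integer volume with
    0 outside the mask.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    mask.check_compatible(volume)
    if mask.count == 0:
        raise ValueError("empty mask")
    vals = volume.values[mask.data]
    vmin, vmax = float(vals.min()), float(vals.max())
    labels = np.zeros(volume.shape, dtype=np.int32)
    if vmax == vmin:
        labels[mask.data] = 1
        return labels
    width = (vmax - vmin) / levels
    lab = np.floor((vals - vmin) / width).astype(np.int32) + 1
    np.clip(lab, 1, levels, out=lab)
    labels[mask.data] = lab
    return labels


@dataclass
class GLCMSpec:
    """Configuration of one GLCM feature extraction pass."""

    levels: int
    offsets: list[tuple[int, int, int]] = field(default_factory=glcm_offsets)
    symmetrize: bool = True
    icb_sqrt: bool = False
    mcc_sqrt: bool = False

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        seen: set[tuple[int, int, int]] = set()
        for v in self.offsets:
            if all(c == 0 for c in v):
                raise ValueError("zero offset not allowed")
            if tuple(-c for c in v) in seen:
                raise ValueError(f"offsets contain antipodal pair for {v}")
            seen.add(tuple(v))

    @property
    def family(self) -> str:
        return f"GLCM({self.levels})"


@dataclass
class GLCMMatrix:
    """A normalised co-occurrence distribution and its derived quantities."""

    P: np.ndarray
    symmetrized: bool = True

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.ndim != 2 or self.P.shape[0] != self.P.shape[1]:
            raise ValueError("P must be a square matrix")
        if not np.isclose(self.P.sum(), 1.0, atol=1e-9):
            raise ValueError("P must be normalised to sum 1")

    @property
    def levels(self) -> int:
        return self.P.shape[0]

    @cached_property
    def _i(self) -> np.ndarray:
        # 1-based level index along rows
        return np.arange(1, self.levels + 1, dtype=float)

    @cached_property
    def Px(self) -> np.ndarray:
        return self.P.sum(axis=1)

    @cached_property
    def Py(self) -> np.ndarray:
        return self.P.sum(axis=0)

    @cached_property
    def mu_x(self) -> float:
        return float(self._i @ self.Px)

    @cached_property
    def mu_y(self) -> float:
        return float(self._i @ self.Py)

    @cached_property
    def sigma_x(self) -> float:
        return float(np.sqrt(((self._i - self.mu_x) ** 2) @ self.Px))

    @cached_property
    def sigma_y(self) -> float:
        return float(np.sqrt(((self._i - self.mu_y) ** 2) @ self.Py))

    @cached_property
    def Pxpy(self) -> np.ndarray:
        """Cross-sum distribution Px+y(k), k = 2 .. 2*levels (index 0 => k=2)."""
        L = self.levels
        i = np.arange(1, L + 1)
        k = (i[:, None] + i[None, :]).ravel()
        return np.bincount(k - 2, weights=self.P.ravel(), minlength=2 * L - 1)

    @cached_property
    def Pxmy(self) -> np.ndarray:
        """Cross-difference distribution Px-y(k), k = 0 .. levels-1."""
        L = self.levels
        i = np.arange(1, L + 1)
        k = np.abs(i[:, None] - i[None, :]).ravel()
        return np.bincount(k, weights=self.P.ravel(), minlength=L)

    @cached_property
    def Hx(self) -> float:
        return float(_nat_entropy(self.Px))

    @cached_property
    def Hy(self) -> float:
        return float(_nat_entropy(self.Py))

    @cached_property
    def Hxy(self) -> float:
        return float(_nat_entropy(self.P))

    @cached_property
    def Hxy1(self) -> float:
        outer = np.outer(self.Px, self.Py)
        m = self.P > 0
        return float(-(self.P[m] * np.log(outer[m])).sum())

    @cached_property
    def Hxy2(self) -> float:
        return float(_nat_entropy(np.outer(self.Px, self.Py)))

    @cached_property
    def U(self) -> np.ndarray:
        """Matrix U(i,j) = sum_k P(i,k) P(j,k) / (Px(i) Py(k)).

        Rows/columns with zero marginal are removed before forming U.
        """
        keep_x = self.Px > 0
        keep_y = self.Py > 0
        P = self.P[np.ix_(keep_x, keep_y)]
        Px = self.Px[keep_x]
        Py = self.Py[keep_y]
        # U = diag(1/Px) @ P @ diag(1/Py) @ P.T
        return (P / Px[:, None]) @ (P / Py[None, :]).T


def _nat_entropy(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float)
    m = p > 0
    return float(-(p[m] * np.log(p[m])).sum())


def compute_glcm(
    labels: np.ndarray,
    mask: ROIMask,
    offset: tuple[int, int, int],
    levels: int,
    symmetrize: bool = True,
) -> GLCMMatrix:
    """Count co-occurring label pairs at one offset and normalise.

    Ordered pairs (x, x + offset) with both voxels inside the mask are
    counted; with ``symmetrize`` the transpose is added before normalisation.

    Raises
    ------
    NoValidPairsError
        If the offset exceeds the ROI extent everywhere.
    """
    if labels.shape != mask.shape:
        raise ValueError("labels and mask shapes differ")
    shape = labels.shape
    src = []
    dst = []
    for d, n in zip(offset, shape):
        if abs(d) >= n:
            raise NoValidPairsError(f"offset {offset} exceeds volume shape {shape}")
        if d >= 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    src, dst = tuple(src), tuple(dst)
    valid = mask.data[src] & mask.data[dst]
    a = labels[src][valid]
    b = labels[dst][valid]
    if a.size == 0:
        raise NoValidPairsError(f"no voxel pair inside the ROI for offset {offset}")
    counts = np.bincount(
        (a.astype(np.int64) - 1) * levels + (b.astype(np.int64) - 1),
        minlength=levels * levels,
    ).reshape(levels, levels).astype(float)
    if symmetrize:
        counts = counts + counts.T
    return GLCMMatrix(counts / counts.sum(), symmetrized=symmetrize)


# ---------------------------------------------------------------------------
# base features

def _f_mean(m: GLCMMatrix) -> float:
    return m.mu_x


def _f_variance(m: GLCMMatrix) -> float:
    return m.sigma_x**2


def _f_energy(m: GLCMMatrix) -> float:
    return float((m.P**2).sum())


def _f_entropy(m: GLCMMatrix) -> float:
    return m.Hxy


def _f_contrast(m: GLCMMatrix) -> float:
    i = m._i
    return float((((i[:, None] - i[None, :]) ** 2) * m.P).sum())


def _f_correlation(m: GLCMMatrix) -> float:
    denom = m.sigma_x * m.sigma_y
    if denom == 0:
        return 0.0
    i = m._i
    return float(((i[:, None] * i[None, :] * m.P).sum() - m.mu_x * m.mu_y) / denom)


def _f_dissimilarity(m: GLCMMatrix) -> float:
    i = m._i
    return float((np.abs(i[:, None] - i[None, :]) * m.P).sum())


def _f_homogeneity(m: GLCMMatrix) -> float:
    i = m._i
    return float((m.P / (1.0 + (i[:, None] - i[None, :]) ** 2)).sum())


def _f_info_corr_a(m: GLCMMatrix) -> float:
    denom = max(m.Hx, m.Hy)
    if denom == 0:
        return 0.0
    return (m.Hxy - m.Hxy1) / denom


def _f_info_corr_b(m: GLCMMatrix, sqrt: bool = False) -> float:
    v = 1.0 - np.exp(-2.0 * (m.Hxy2 - m.Hxy))
    if sqrt:
        return float(np.sqrt(max(v, 0.0)))
    return float(v)


def _f_mcc(m: GLCMMatrix, sqrt: bool = False) -> float:
    U = m.U
    if U.shape[0] < 2:
        return 0.0
    ev = np.linalg.eigvals(U)
    # residual imaginary parts are numerical noise
    ev = np.where(np.abs(ev.imag) < 1e-8, ev.real, np.nan)
    ev = np.sort(ev[~np.isnan(ev)])[::-1]
    if len(ev) < 2:
        return 0.0
    second = float(ev[1])
    if sqrt:
        return float(np.sqrt(max(second, 0.0)))
    return second


def _f_diff_average(m: GLCMMatrix) -> float:
    k = np.arange(m.levels, dtype=float)
    return float(k @ m.Pxmy)


def _f_diff_variance(m: GLCMMatrix) -> float:
    k = np.arange(m.levels, dtype=float)
    mu = k @ m.Pxmy
    return float(((k - mu) ** 2) @ m.Pxmy)


def _f_diff_entropy(m: GLCMMatrix) -> float:
    return _nat_entropy(m.Pxmy)


def _f_sum_average(m: GLCMMatrix) -> float:
    k = np.arange(2, 2 * m.levels + 1, dtype=float)
    return float(k @ m.Pxpy)


def _f_sum_variance(m: GLCMMatrix) -> float:
    k = np.arange(2, 2 * m.levels + 1, dtype=float)
    mu = k @ m.Pxpy
    return float(((k - mu) ** 2) @ m.Pxpy)


def _f_sum_entropy(m: GLCMMatrix) -> float:
    return _nat_entropy(m.Pxpy)


_FEATURE_FUNCS = {
    "Mean": _f_mean,
    "Variance": _f_variance,
    "Energy": _f_energy,
    "Entropy": _f_entropy,
    "Contrast": _f_contrast,
    "Correlation": _f_correlation,
    "Dissimilarity": _f_dissimilarity,
    "Homogeneity": _f_homogeneity,
    "Information correlation A": _f_info_corr_a,
    "Diff average": _f_diff_average,
    "Diff variance": _f_diff_variance,
    "Diff entropy": _f_diff_entropy,
    "Sum average": _f_sum_average,
    "Sum variance": _f_sum_variance,
    "Sum entropy": _f_sum_entropy,
    "Angular 2nd moment": _f_energy,  # same alpha = sum P^2
}


def glcm_feature(
    matrix: GLCMMatrix,
    feature: str,
    icb_sqrt: bool = False,
    mcc_sqrt: bool = False,
) -> float:
    """Evaluate one base GLCM feature on a normalised matrix."""
    if feature == "Information correlation B":
        return _f_info_corr_b(matrix, sqrt=icb_sqrt)
    if feature == "Maximal correlation coefficient":
        return _f_mcc(matrix, sqrt=mcc_sqrt)
    try:
        return float(_FEATURE_FUNCS[feature](matrix))
    except KeyError:
        raise ValueError(f"unknown GLCM feature {feature!r}") from None


def glcm_features_all_offsets(
    volume: VolumeGrid,
    mask: ROIMask,
    spec: GLCMSpec,
) -> dict[str, list[float]]:
    """Per-offset values of every base feature; excluded offsets are dropped.

    Offsets with no valid pair are skipped (and the exclusion logged via a
    RuntimeWarning); at least one offset must survive.
    """
    import warnings

    labels = quantize_roi(volume, mask, spec.levels)
    per_feature: dict[str, list[float]] = {f: [] for f in GLCM_FEATURES}
    n_ok = 0
    for off in spec.offsets:
        try:
            m = compute_glcm(labels, mask, off, spec.levels, spec.symmetrize)
        except NoValidPairsError:
            warnings.warn(
                f"offset {off} excluded: no valid pair in ROI", RuntimeWarning
            )
            continue
        n_ok += 1
        for f in GLCM_FEATURES:
            per_feature[f].append(
                glcm_feature(m, f, icb_sqrt=spec.icb_sqrt, mcc_sqrt=spec.mcc_sqrt)
            )
    if n_ok == 0:
        raise NoValidPairsError("all offsets excluded for this ROI")
    return per_feature


def aggregate_directions(values: list[float]) -> tuple[float, float]:
    """Mean and range (max - min) of a feature's per-offset values."""
    if len(values) == 0:
        raise ValueError("no directional values to aggregate")
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.max() - arr.min())


def extract_all(
    volume: VolumeGrid,
    mask: ROIMask,
    specs: list[GLCMSpec] | None = None,
    case_id: str = "case",
    condition: str = "condition",
    contour_id: str = "orig",
    kurtosis_denominator: str = "sigma4",
) -> pd.DataFrame:
    """Full feature battery for one (case, condition, contour).

    Emits 8 histogram rows plus, per quantization level, 18 base GLCM
    features x {mean, range} = 36 rows; with levels {25, 32} that is 80 rows.
    Columns: case_id, condition, contour_id, family, feature, value.
    """
    if specs is None:
        specs = [GLCMSpec(25), GLCMSpec(32)]
    rows: list[tuple[str, str, str, str, str, float]] = []
    hist = histogram_features(volume, mask, kurtosis_denominator=kurtosis_denominator)
    for name, value in hist.as_dict().items():
        rows.append((case_id, condition, contour_id, "Histogram", name, value))
    for spec in specs:
        per_feature = glcm_features_all_offsets(volume, mask, spec)
        for f in GLCM_FEATURES:
            mean, rng = aggregate_directions(per_feature[f])
            rows.append((case_id, condition, contour_id, f"{spec.family} mean", f, mean))
            rows.append((case_id, condition, contour_id, f"{spec.family} range", f, rng))
    return pd.DataFrame(
        rows,
        columns=["case_id", "condition", "contour_id", "family", "feature", "value"],
    )
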