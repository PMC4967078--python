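"""End-to-end study orchestration.

A :class:`StudyConfig` describes one synthetic study (phantom or nodule
mode): the condition grid, generator parameters, GLCM settings and the Q
conventions.  :func:`run_study` simulates the volumes, extracts the feature
battery and runs the robustness analysis, returning a :class:`StudyResult`
whose tables can be written as CSV.  Two runs with the same config and seed
produce identical tables.

Study design, mirroring the source experiment: contours are drawn once at
the reference condition and applied unchanged to every other condition;
repeat contours exist for a subset of cases and only at the reference, and
feed the repeatability denominator of the Q statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .glcm import GLCMSpec, extract_all
from .grid import ROIMask, VolumeGrid, load_mask, load_volume
from .robustness import (
    ConditionGrid,
    QTable,
    build_q_table,
    condition_feature_summary,
    nearest_condition_histogram,
    rank_conditions,
    rank_features,
)
from .roi import perturb_mask, place_spherical_rois, segment_nodule
from .synthetic import (
    NODULE_DOSES,
    NODULE_KERNELS,
    PHANTOM_DOSES,
    PHANTOM_KERNELS,
    NoduleCaseParams,
    condition_label,
    derive_seed,
    generate_nodule_volume,
    generate_water_phantom,
    nodule_condition_grid,
    parse_condition,
    phantom_condition_grid,
    sample_nodule_cases,
    simulate_dose_reduction,
    water_cylinder_mask,
)

__all__ = [
    "StudyConfig",
    "StudyResult",
    "run_study",
    "run_pipeline",
    "simulate_case_volumes",
    "extract_study_features",
    "analyze_feature_table",
]


@dataclass
class StudyConfig:
    """Configuration of one synthetic robustness study."""

    mode: str = "nodule"  # "nodule" | "phantom"
    seed: int = 0
    # feature extraction
    levels: tuple[int, ...] = (25, 32)
    symmetrize: bool = True
    icb_sqrt: bool = False
    mcc_sqrt: bool = False
    kurtosis_denominator: str = "sigma4"
    # acquisition model; None selects the per-mode default (10 HU for the
    # water phantom anchor, 30 HU for thin-slice chest CT at clinical dose)
    sigma_ref: float | None = None
    # nodule mode
    n_cases: int = 33
    n_repeat: int = 17
    flip_prob: float = 0.2
    edge_blur_voxels: float = 0.7
    margin_voxels: int = 8
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # phantom mode
    phantom_shape: tuple[int, int, int] = (24, 72, 72)
    n_rois: int = 5
    roi_diameter_mm: float = 10.0
    water_margin_mm: float = 6.0
    # Q conventions
    ddof: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("nodule", "phantom"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "nodule" and not 2 <= self.n_repeat <= self.n_cases:
            raise ValueError("need 2 <= n_repeat <= n_cases")

    @property
    def effective_sigma_ref(self) -> float:
        """Reference noise level: the water-phantom anchor (10 HU) in phantom
        mode, a thin-slice chest-CT level (30 HU) in nodule mode."""
        if self.sigma_ref is not None:
            return self.sigma_ref
        return 10.0 if self.mode == "phantom" else 30.0

    @property
    def grid(self) -> ConditionGrid:
        return nodule_condition_grid() if self.mode == "nodule" else phantom_condition_grid()

    @property
    def glcm_specs(self) -> list[GLCMSpec]:
        return [
            GLCMSpec(
                levels=lv,
                symmetrize=self.symmetrize,
                icb_sqrt=self.icb_sqrt,
                mcc_sqrt=self.mcc_sqrt,
            )
            for lv in self.levels
        ]

    def iter_cases(self) -> list[NoduleCaseParams]:
        if self.mode == "phantom":
            return [
                NoduleCaseParams("phantom", 0.0, 1.0, 1.0, 0.0, 0.0, 1.0)
            ]
        return sample_nodule_cases(self.n_cases, derive_seed(self.seed, "cases"))

    def repeat_cases(self) -> set[str]:
        if self.mode == "phantom":
            return set()
        ids = [c.case_id for c in self.iter_cases()]
        rng = np.random.default_rng(derive_seed(self.seed, "repeat-subset"))
        return set(rng.choice(ids, size=self.n_repeat, replace=False))


def _nodule_geometry(
    case: NoduleCaseParams, config: StudyConfig
) -> tuple[tuple[int, int, int], tuple[float, float, float]]:
    semi = case.semi_axes_mm
    shape = tuple(
        int(np.ceil(2 * a / s)) + 2 * config.margin_voxels
        for a, s in zip(semi, config.spacing)
    )
    center = tuple((n - 1) / 2.0 for n in shape)
    return shape, center  # type: ignore[return-value]


def simulate_case_volumes(
    config: StudyConfig, case: NoduleCaseParams
) -> tuple[dict[str, VolumeGrid], ROIMask | list[ROIMask], ROIMask | None]:
    """Simulate all condition volumes of one case, plus its contour(s).

    For nodule mode the 100%-dose volume of each kernel is generated directly
    and the reduced-dose volumes are derived from it by image-domain noise
    addition; the anatomy is shared across all conditions of a case.  The
    contour is the Otsu-initialised segmentation at the reference condition;
    the repeat contour is its seeded boundary-flip perturbation (repeat-subset
    cases only).

    For phantom mode a single "case" yields the 24 condition volumes and the
    spherical ROIs placed at the reference condition (no repeats).
    """
    if config.mode == "phantom":
        volumes: dict[str, VolumeGrid] = {}
        for cond in config.grid.conditions:
            kernel, dose = parse_condition(cond, PHANTOM_KERNELS, PHANTOM_DOSES)
            volumes[cond] = generate_water_phantom(
                shape=config.phantom_shape,
                dose=dose,
                kernel=kernel,
                sigma_ref=config.effective_sigma_ref,
                seed=derive_seed(config.seed, "phantom", cond),
            )
        interior = water_cylinder_mask(
            config.phantom_shape,
            config.spacing,
            0.45 * min(
                config.phantom_shape[1] * config.spacing[1],
                config.phantom_shape[2] * config.spacing[2],
            ),
            margin_mm=config.water_margin_mm,
        )
        rois = place_spherical_rois(
            volumes[config.grid.reference],
            config.n_rois,
            config.roi_diameter_mm,
            interior,
            seed=derive_seed(config.seed, "phantom", "rois"),
        )
        return volumes, rois, None

    shape, center = _nodule_geometry(case, config)
    anatomy_seed = derive_seed(config.seed, case.case_id, "anatomy")
    volumes = {}
    for kernel in NODULE_KERNELS:
        full = None
        for dose in NODULE_DOSES:
            cond = condition_label(kernel, dose)
            if dose.fraction == 1.0:
                full, _ = generate_nodule_volume(
                    shape=shape,
                    spacing=config.spacing,
                    center=center,
                    semi_axes_mm=case.semi_axes_mm,
                    nodule_hu=case.nodule_hu,
                    texture_sigma=case.texture_sigma,
                    texture_anisotropy=case.texture_anisotropy,
                    texture_coarse_fraction=case.texture_coarse_fraction,
                    texture_skew=case.texture_skew,
                    edge_blur_voxels=config.edge_blur_voxels,
                    dose=dose,
                    kernel=kernel,
                    sigma_ref=config.effective_sigma_ref,
                    noise_scale=case.noise_scale,
                    seed=derive_seed(config.seed, case.case_id, kernel.name, dose.label),
                    anatomy_seed=anatomy_seed,
                )
                volumes[cond] = full
            else:
                volumes[cond] = simulate_dose_reduction(
                    full,
                    1.0,
                    dose.fraction,
                    kernel,
                    sigma_ref=config.effective_sigma_ref,
                    noise_scale=case.noise_scale,
                    seed=derive_seed(config.seed, case.case_id, kernel.name, dose.label),
                )
    ref_vol = volumes[config.grid.reference]
    seed_point = tuple(int(round(c)) for c in center)
    contour = segment_nodule(ref_vol, seed_point, box_radius_mm=case.diameter_mm + 10.0)
    repeat = None
    if case.case_id in config.repeat_cases():
        repeat = perturb_mask(
            contour, config.flip_prob, derive_seed(config.seed, case.case_id, "repeat")
        )
    return volumes, contour, repeat


def extract_study_features(config: StudyConfig) -> pd.DataFrame:
    """Simulate every case and extract the full feature battery.

    Returns the long-form feature table (case_id, condition, contour_id,
    family, feature, value).  In phantom mode each spherical ROI plays the
    role of a case.
    """
    frames = []
    specs = config.glcm_specs
    for case in config.iter_cases():
        volumes, mask, repeat = simulate_case_volumes(config, case)
        if config.mode == "phantom":
            for i, roi in enumerate(mask):  # type: ignore[arg-type]
                for cond, vol in volumes.items():
                    frames.append(
                        extract_all(
                            vol, roi, specs,
                            case_id=f"roi{i}", condition=cond, contour_id="orig",
                            kurtosis_denominator=config.kurtosis_denominator,
                        )
                    )
        else:
            for cond, vol in volumes.items():
                frames.append(
                    extract_all(
                        vol, mask, specs,  # type: ignore[arg-type]
                        case_id=case.case_id, condition=cond, contour_id="orig",
                        kurtosis_denominator=config.kurtosis_denominator,
                    )
                )
            if repeat is not None:
                frames.append(
                    extract_all(
                        volumes[config.grid.reference], repeat, specs,
                        case_id=case.case_id, condition=config.grid.reference,
                        contour_id="repeat",
                        kurtosis_denominator=config.kurtosis_denominator,
                    )
                )
    return pd.concat(frames, ignore_index=True)


@dataclass
class StudyResult:
    """All analysis artifacts of one study run."""

    config: StudyConfig
    feature_table: pd.DataFrame
    summary: pd.DataFrame
    nearest_histogram: pd.Series
    q_table: QTable | None = None
    feature_ranking: pd.DataFrame | None = None
    condition_ranking: pd.DataFrame | None = None

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.feature_table.to_csv(out / "feature_table.csv", index=False)
        self.summary.to_csv(out / "condition_summary.csv", index=False)
        self.nearest_histogram.rename("count").rename_axis("condition").to_csv(
            out / "nearest_condition_histogram.csv"
        )
        if self.q_table is not None:
            self.q_table.data.to_csv(out / "q_table.csv", index=False)
            self.feature_ranking.to_csv(out / "feature_ranking.csv", index=False)
            self.condition_ranking.to_csv(out / "condition_ranking.csv", index=False)
        return out


def analyze_feature_table(
    table: pd.DataFrame, grid: ConditionGrid, config: StudyConfig
) -> StudyResult:
    """Robustness analysis of an extracted feature table."""
    summary = condition_feature_summary(table)
    hist = nearest_condition_histogram(summary, grid.reference)
    result = StudyResult(
        config=config, feature_table=table, summary=summary, nearest_histogram=hist
    )
    if config.mode == "nodule":
        q = build_q_table(table, grid, ddof=config.ddof)
        result.q_table = q
        result.feature_ranking = rank_features(q)
        result.condition_ranking = rank_conditions(q)
    return result


def run_study(config: StudyConfig) -> StudyResult:
    """Simulate, extract and analyze one study in memory."""
    table = extract_study_features(config)
    return analyze_feature_table(table, config.grid, config)


def run_pipeline(config: StudyConfig, out_dir: str | Path) -> StudyResult:
    """Run a full study and write the CSV artifacts to ``out_dir``."""
    result = run_study(config)
    result.save(out_dir)
    return result


# ---------------------------------------------------------------------------
# disk-backed stages (CLI simulate/extract operate through these)

def extract_study_dir(study_dir: str | Path, config: StudyConfig) -> pd.DataFrame:
    """Extract the feature battery from an on-disk study layout.

    Expects the layout written by :func:`radstab.synthetic.generate_study`.
    """
    study_dir = Path(study_dir)
    manifest = json.loads((study_dir / "manifest.json").read_text())
    ref = manifest["reference"]
    specs = config.glcm_specs
    frames = []

    def cond_dirname(cond: str) -> str:
        return cond.replace("\\", "_").replace("@", "_at_")

    for entry in manifest["cases"]:
        case_id = entry["case_id"]
        case_dir = study_dir / case_id
        ref_dir = case_dir / cond_dirname(ref)
        if manifest["mode"] == "phantom":
            masks = sorted(ref_dir.glob("mask_roi*.nii.gz"))
            rois = [(p.stem.split(".")[0].replace("mask_", ""), load_mask(p)) for p in masks]
        else:
            rois = [("orig", load_mask(ref_dir / "mask.nii.gz"))]
        for cond in manifest["conditions"]:
            vol = load_volume(case_dir / cond_dirname(cond) / "volume.nii.gz")
            for roi_name, roi in rois:
                cid = roi_name if manifest["mode"] == "phantom" else case_id
                frames.append(
                    extract_all(
                        vol, roi, specs,
                        case_id=cid, condition=cond, contour_id="orig",
                        kurtosis_denominator=config.kurtosis_denominator,
                    )
                )
        repeat_path = ref_dir / "mask_repeat.nii.gz"
        if entry.get("has_repeat") and repeat_path.exists():
            vol = load_volume(ref_dir / "volume.nii.gz")
            frames.append(
                extract_all(
                    vol, load_mask(repeat_path), specs,
                    case_id=case_id, condition=ref, contour_id="repeat",
                    kurtosis_denominator=config.kurtosis_denominator,
                )
            )
    return pd.concat(frames, ignore_index=True)
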