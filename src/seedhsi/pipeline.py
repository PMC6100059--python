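"""End-to-end orchestration: scene set -> calibration -> model -> maps.

This module wires the stage modules together in the standard order
(correct -> crop -> mask -> denoise -> average -> PCA/EW -> SVM -> maps)
and is what the command-line interface, the analysis drivers and the
acceptance script all call.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from . import calibrate, classify, pca, preprocess, segment, visualize
from .calibrate import ReferencePair
from .io import HyperCube
from .preprocess import DenoiseConfig
from .segment import RoiLabelMap
from .synthetic import GroundTruth, SceneConfig, generate_scene

__all__ = [
    "SceneResult",
    "PipelineResult",
    "process_scene",
    "match_rois_to_truth",
    "simulate_scene_set",
    "run_end_to_end",
    "planted_center_recovery",
]


@dataclasses.dataclass
class SceneResult:
    """One scene after calibration, segmentation, smoothing and averaging."""

    scene_id: int
    cube: HyperCube  # corrected, cropped, foreground-denoised
    mask: np.ndarray
    rois: RoiLabelMap
    mean_spectra: np.ndarray  # K x bands (per-seed object spectra)
    true_class: np.ndarray | None  # per detected ROI, when ground truth known
    contrast_band_nm: float


def match_rois_to_truth(rois: RoiLabelMap, truth: GroundTruth) -> np.ndarray:
    """True class per detected ROI by majority vote over the ground-truth image.

    Detected labels need not coincide numerically with ground-truth labels;
    each detected ROI inherits the most common true class among its pixels.
    A ROI falling entirely on true background gets class 0.
    """
    class_img = truth.class_image()
    out = np.zeros(rois.n_rois, dtype=int)
    for label in range(1, rois.n_rois + 1):
        vals = class_img[rois.labels == label]
        vals = vals[vals > 0]
        out[label - 1] = np.bincount(vals).argmax() if vals.size else 0
    return out


def process_scene(
    raw: HyperCube,
    dark: np.ndarray,
    white: np.ndarray,
    *,
    scene_id: int = 0,
    crop_low_nm: float = 975.0,
    crop_high_nm: float = 1646.0,
    denoise: DenoiseConfig | None = None,
    min_roi_size: int = 10,
    truth: GroundTruth | None = None,
) -> SceneResult:
    """Run one scene through calibration, segmentation and spectral averaging."""
    corrected = calibrate.correct_reflectance(raw, ReferencePair(dark=dark, white=white))
    cube = calibrate.crop_bands(corrected, crop_low_nm, crop_high_nm)
    band, band_nm = segment.select_contrast_band(cube)
    mask = segment.build_mask(cube, band)
    rois = segment.label_rois(mask, min_roi_size=min_roi_size)
    cube = preprocess.denoise_cube(cube, mask, denoise or DenoiseConfig())
    means = preprocess.roi_mean_spectra(cube, rois)
    true_class = None if truth is None else match_rois_to_truth(rois, truth)
    return SceneResult(
        scene_id=scene_id,
        cube=cube,
        mask=mask,
        rois=rois,
        mean_spectra=means,
        true_class=true_class,
        contrast_band_nm=band_nm,
    )


def simulate_scene_set(
    base_config: SceneConfig, n_scenes: int, rng_seed: int = 0
) -> list[tuple[HyperCube, np.ndarray, np.ndarray, GroundTruth]]:
    """Generate ``n_scenes`` independent scenes from one base configuration."""
    out = []
    for i in range(n_scenes):
        cfg = dataclasses.replace(base_config, rng_seed=(rng_seed * 10_000 + i) % (2**31 - 1))
        out.append(generate_scene(cfg))
    return out


@dataclasses.dataclass
class PipelineResult:
    """Everything the end-to-end run produces."""

    scenes: list[SceneResult]
    split: classify.SplitPlan
    pca_model: pca.PcaModel
    ews: pca.EwSet
    model: classify.DiscriminantModel
    calibration_report: classify.EvalReport
    prediction_report: classify.EvalReport
    external_maps: list[visualize.ClassificationMap]
    external_accuracy: list[tuple[float, int, int]]  # (pct, correct, total) per scene

    @property
    def external_overall(self) -> tuple[float, int, int]:
        correct = sum(c for _, c, _ in self.external_accuracy)
        total = sum(t for _, _, t in self.external_accuracy)
        pct = float(np.round(100.0 * correct / total, 1)) if total else 0.0
        return pct, correct, total


def _stack_objects(results: Sequence[SceneResult], ids: Sequence[int]):
    X, y = [], []
    for r in results:
        if r.scene_id in ids:
            X.append(r.mean_spectra)
            y.append(r.true_class)
    return np.vstack(X), np.concatenate(y)


def run_end_to_end(
    base_config: SceneConfig | None = None,
    n_scenes: int = 10,
    rng_seed: int = 0,
    *,
    denoise: DenoiseConfig | None = None,
    n_components: int = 6,
    prominence_fraction: float = 0.1,
    dedup_window_nm: float = 10.0,
    c_exponents: Sequence[float] = tuple(range(-8, 9)),
    g_exponents: Sequence[float] = tuple(range(-8, 9)),
    cv_folds: int = 5,
    pca_pixel_cap: int = 50_000,
) -> PipelineResult:
    """Full chain on a synthetic scene set.

    Scenes are split 2:1 at the image level with one scene held out as
    external validation.  PCA is fitted on pooled foreground pixels of the
    calibration scenes (capped, seeded), effective wavelengths come from
    its loadings, and the RBF-SVM is trained on calibration-object EW
    spectra.
    """
    base_config = base_config or SceneConfig()
    scenes_raw = simulate_scene_set(base_config, n_scenes, rng_seed)
    results = [
        process_scene(raw, dark, white, scene_id=i, denoise=denoise, truth=truth)
        for i, (raw, dark, white, truth) in enumerate(scenes_raw)
    ]
    split = classify.split_by_image(list(range(n_scenes)), ratio=(2, 1), n_external=1, rng_seed=rng_seed)

    # pixel-level PCA on pooled calibration foreground spectra
    pixel_blocks = []
    for r in results:
        if r.scene_id in split.calibration_ids:
            rows, cols = np.nonzero(r.mask)
            pixel_blocks.append(r.cube.values[rows, cols, :].astype(float))
    pixels = np.vstack(pixel_blocks)
    n_comp = pca.achievable_components(pixels, n_components)
    model_pca = pca.fit_pixel_pca(pixels, n_comp, subsample_cap=pca_pixel_cap, rng_seed=rng_seed)
    wavelengths = results[0].cube.wavelengths_nm
    ews = pca.select_ews(model_pca, wavelengths, prominence_fraction, dedup_window_nm)
    bands = ews.band_indices

    X_cal, y_cal = _stack_objects(results, split.calibration_ids)
    X_pred, y_pred = _stack_objects(results, split.prediction_ids)
    svm = classify.grid_search_svm(
        X_cal[:, bands],
        y_cal,
        c_exponents=c_exponents,
        g_exponents=g_exponents,
        cv_folds=cv_folds,
        rng_seed=rng_seed,
        feature_wavelengths_nm=ews.wavelengths_nm,
    )
    cal_report = classify.evaluate(svm, X_cal[:, bands], y_cal)
    pred_report = classify.evaluate(svm, X_pred[:, bands], y_pred)

    ext_maps, ext_acc = [], []
    for r in results:
        if r.scene_id not in split.external_ids:
            continue
        preds = classify.predict_objects(svm, r.mean_spectra[:, bands])
        ext_maps.append(
            visualize.paint_map(r.rois, preds, provenance=f"scene {r.scene_id}")
        )
        ext_acc.append(visualize.map_accuracy(preds, r.true_class))
    return PipelineResult(
        scenes=results,
        split=split,
        pca_model=model_pca,
        ews=ews,
        model=svm,
        calibration_report=cal_report,
        prediction_report=pred_report,
        external_maps=ext_maps,
        external_accuracy=ext_acc,
    )


def planted_center_recovery(
    n_replicates: int = 20,
    rng_seed: int = 0,
    *,
    base_config: SceneConfig | None = None,
    tolerance_nm: float = 10.0,
    denoise: DenoiseConfig | None = None,
) -> tuple[float, pd.DataFrame]:
    """Fraction of planted absorption centres recovered as effective wavelengths.

    Each replicate generates a fresh scene, runs it through calibration,
    segmentation and smoothing, fits pixel PCA and selects EWs; a planted
    centre counts as recovered when some selected EW lies within
    ``tolerance_nm`` of it.  Returns (recovered fraction, per-centre table).
    """
    base_config = base_config or SceneConfig()
    rows = []
    for rep in range(n_replicates):
        cfg = dataclasses.replace(base_config, rng_seed=(rng_seed * 10_000 + 541 + rep) % (2**31 - 1))
        raw, dark, white, truth = generate_scene(cfg)
        res = process_scene(raw, dark, white, scene_id=rep, denoise=denoise, truth=truth)
        rowsmask, cols = np.nonzero(res.mask)
        pixels = res.cube.values[rowsmask, cols, :].astype(float)
        model = pca.fit_pixel_pca(pixels, pca.achievable_components(pixels, 6), rng_seed=cfg.rng_seed)
        ews = pca.select_ews(model, res.cube.wavelengths_nm)
        for center in cfg.feature_centers_nm:
            hit = len(ews) > 0 and np.min(np.abs(ews.wavelengths_nm - center)) <= tolerance_nm
            rows.append({"replicate": rep, "center_nm": center, "recovered": bool(hit)})
    table = pd.DataFrame(rows)
    return float(table["recovered"].mean()), table
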