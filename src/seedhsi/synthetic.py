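"""Synthetic NIR hyperspectral scenes of seeds with known ground truth.

Scenes emulate the statistical structure the analysis chain assumes: three
seed classes whose mean reflectance spectra share absorption features near
1100, 1200, 1300 and 1450 nm, with classes 1 and 2 spectrally similar
(controlled by ``class_overlap``) and class 3 clearly separated; seeds are
non-touching elliptical blobs on a dark plate.  Raw counts are synthesised
as ``dark + (reflectance + noise) * (white - dark)``, so applying the
standard white/dark correction recovers the endmembers up to noise.

The generator is deliberately simple radiometry: isotropic Gaussian pixel
noise and a smooth illumination gradient carried by the white frame.  It
does not model within-seed heterogeneity or per-seed biological variation.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .io import HyperCube
from .segment import RoiLabelMap

__all__ = ["SceneConfig", "GroundTruth", "LayoutError", "make_endmembers", "generate_scene", "wide_band_config"]

# default absorption-feature centres (nm), shared across classes
DEFAULT_CENTERS = (1100.0, 1200.0, 1300.0, 1450.0)
# absolute reflectance dip depths per class at the four centres
DEFAULT_DEPTHS = {
    1: (0.12, 0.16, 0.10, 0.26),
    2: (0.12, 0.16, 0.10, 0.26),  # + class_overlap * DELTA_12
    3: (0.18, 0.09, 0.16, 0.38),
}
# class-2 depth offsets relative to class 1, scaled by class_overlap
DELTA_12 = (0.030, -0.025, 0.020, 0.028)
# class 3 additionally sits on a lower baseline (strong PC1 separation)
CLASS3_BASELINE_OFFSET = -0.08
FEATURE_SIGMA_NM = 18.0

DARK_LEVEL = 40.0
WHITE_LEVEL = 4040.0
BACKGROUND_REFLECTANCE = 0.03


class LayoutError(RuntimeError):
    """Blob placement failed within the retry budget."""


@dataclasses.dataclass
class SceneConfig:
    """Parameters of one synthetic scene.

    The default spectral grid is 200 bands at 3.36 nm spacing over
    975.1-1643.74 nm (the cropped working range); :func:`wide_band_config`
    yields the full 256-band sensor grid to exercise band cropping.
    ``noise_sd`` is the per-pixel, per-band Gaussian noise in reflectance
    units; ``class_overlap`` scales the class-1/class-2 endmember
    difference (0 makes them identical).
    """

    image_height: int = 96
    image_width: int = 128
    band_count: int = 200
    wavelength_start_nm: float = 975.1
    wavelength_end_nm: float = 1643.74
    n_seeds_per_class: int = 4
    feature_centers_nm: Sequence[float] = DEFAULT_CENTERS
    feature_depths: dict | None = None  # class -> depths; None = defaults
    class_overlap: float = 1.0
    noise_sd: float = 0.02
    illumination_gradient: float = 0.05
    rng_seed: int = 0
    min_gap_px: int = 2
    max_place_tries: int = 2000

    def __post_init__(self) -> None:
        if self.band_count < 2:
            raise ValueError("band_count must be >= 2")
        if self.wavelength_end_nm <= self.wavelength_start_nm:
            raise ValueError("wavelength range must be increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_seeds_per_class < 0:
            raise ValueError("n_seeds_per_class must be >= 0")
        depths = self.feature_depths or DEFAULT_DEPTHS
        for cls, d in depths.items():
            if len(d) != len(self.feature_centers_nm):
                raise ValueError(f"class {cls}: {len(d)} depths for {len(self.feature_centers_nm)} centers")
            if not all(0 <= x < 1 for x in d):
                raise ValueError("feature depths must lie in [0, 1)")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return np.linspace(self.wavelength_start_nm, self.wavelength_end_nm, self.band_count)


def wide_band_config(**overrides) -> SceneConfig:
    """Full-sensor grid: 256 bands at 3.36 nm from 874.3 nm.

    Cropping this grid to 975-1646 nm keeps exactly its middle 200 bands.
    """
    defaults = dict(band_count=256, wavelength_start_nm=874.3, wavelength_end_nm=874.3 + 255 * 3.36)
    defaults.update(overrides)
    return SceneConfig(**defaults)


@dataclasses.dataclass
class GroundTruth:
    """What the generator knows: per-seed labels, classes and endmembers."""

    label_map: RoiLabelMap
    seed_class: np.ndarray  # class code (1..3) per label, index 0 unused = 0
    endmembers: np.ndarray  # 3 x bands, rows = classes 1..3

    def class_image(self) -> np.ndarray:
        """Per-pixel true class (0 = background)."""
        return self.seed_class[self.label_map.labels]


def make_endmembers(config: SceneConfig) -> np.ndarray:
    """Per-class mean reflectance spectra (3 x band_count), values in [0, 1].

    Each endmember is a smooth tilted baseline minus Gaussian dips at the
    shared feature centres; classes 1 and 2 differ by ``class_overlap``
    times a fixed depth offset, class 3 by larger depth changes plus a
    baseline shift.
    """
    wl = config.wavelengths_nm
    lo, hi = wl[0], wl[-1]
    for c in config.feature_centers_nm:
        if not lo <= c <= hi:
            raise ValueError(f"feature center {c} nm outside wavelength range [{lo:.1f}, {hi:.1f}]")
    depths_cfg = config.feature_depths or DEFAULT_DEPTHS
    mid = 0.5 * (lo + hi)
    baseline = 0.52 + 0.08 * (wl - mid) / (hi - lo)  # gentle tilt, ~0.48-0.56
    out = np.zeros((3, config.band_count))
    for cls in (1, 2, 3):
        depths = np.asarray(depths_cfg[cls], dtype=float).copy()
        if cls == 2 and config.feature_depths is None:
            depths = depths + config.class_overlap * np.asarray(DELTA_12)
        spectrum = baseline.copy()
        if cls == 3:
            spectrum = spectrum + CLASS3_BASELINE_OFFSET
        for c, d in zip(config.feature_centers_nm, depths):
            spectrum = spectrum - d * np.exp(-0.5 * ((wl - c) / FEATURE_SIGMA_NM) ** 2)
        out[cls - 1] = spectrum
    if out.min() < 0 or out.max() > 1:
        raise ValueError("endmembers left [0, 1]; reduce depths or baseline tilt")
    return out


def _place_blobs(config: SceneConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-touching ellipses; returns (label map, class per label)."""
    h, w = config.image_height, config.image_width
    labels = np.zeros((h, w), dtype=np.int32)
    occupied = np.zeros((h, w), dtype=bool)  # blobs dilated by the minimum gap
    yy, xx = np.mgrid[0:h, 0:w]
    classes = [0]
    label = 0
    for cls in (1, 2, 3):
        for _ in range(config.n_seeds_per_class):
            placed = False
            for _try in range(config.max_place_tries):
                a = rng.uniform(5.0, 7.0)  # semi-axes in px
                b = rng.uniform(3.5, 5.0)
                theta = rng.uniform(0, np.pi)
                margin = a + config.min_gap_px + 1
                if 2 * margin >= min(h, w):
                    continue
                cy = rng.uniform(margin, h - margin)
                cx = rng.uniform(margin, w - margin)
                ct, st = np.cos(theta), np.sin(theta)
                u = (yy - cy) * ct + (xx - cx) * st
                v = -(yy - cy) * st + (xx - cx) * ct
                inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
                gap = config.min_gap_px
                dilated = (u / (a + gap)) ** 2 + (v / (b + gap)) ** 2 <= 1.0
                if not (dilated & occupied).any():
                    label += 1
                    labels[inside] = label
                    occupied |= dilated
                    classes.append(cls)
                    placed = True
                    break
            if not placed:
                raise LayoutError(
                    f"could not place seed {label + 1} (class {cls}) after "
                    f"{config.max_place_tries} tries: image {h}x{w} too crowded for "
                    f"{3 * config.n_seeds_per_class} blobs with gap {config.min_gap_px} px"
                )
    return labels, np.asarray(classes, dtype=int)


def generate_scene(config: SceneConfig) -> tuple[HyperCube, np.ndarray, np.ndarray, GroundTruth]:
    """Generate one raw scene: (raw cube, dark frame, white frame, truth).

    The same ``config`` (including ``rng_seed``) reproduces the scene
    bit-identically.  The white frame carries the illumination gradient
    along the scan (row) axis; because the same frame scales the seed
    signal, reflectance correction cancels the gradient.
    """
    rng = np.random.default_rng(config.rng_seed)
    h, w, b = config.image_height, config.image_width, config.band_count
    endmembers = make_endmembers(config)
    labels, classes = _place_blobs(config, rng)

    grad = 1.0 + config.illumination_gradient * (np.arange(h) / max(h - 1, 1) - 0.5)
    dark_true = np.full((h, w, b), DARK_LEVEL)
    white_true = np.maximum(np.full((h, w, b), WHITE_LEVEL) * grad[:, None, None], DARK_LEVEL + 1.0)
    scale = white_true - dark_true

    reflectance = np.full((h, w, b), BACKGROUND_REFLECTANCE)
    class_img = classes[labels]
    for cls in (1, 2, 3):
        sel = class_img == cls
        if sel.any():
            reflectance[sel] = endmembers[cls - 1]
    dark, white = dark_true, white_true
    if config.noise_sd > 0:
        reflectance = reflectance + rng.normal(0.0, config.noise_sd, size=(h, w, b))
        # reference frames are separate exposures with their own sensor noise (counts)
        dark = dark_true + rng.normal(0.0, 0.5, size=(h, w, b))
        white = white_true + rng.normal(0.0, 0.5, size=(h, w, b))
    raw = dark_true + reflectance * scale

    sizes = np.bincount(labels.ravel(), minlength=len(classes))
    border = np.zeros(len(classes), dtype=bool)
    roi_map = RoiLabelMap(labels=labels, roi_sizes=sizes, border_labels=np.nonzero(border)[0])
    truth = GroundTruth(label_map=roi_map, seed_class=classes, endmembers=endmembers)
    cube = HyperCube(raw.astype(np.float32), config.wavelengths_nm, kind="raw")
    return cube, dark.astype(np.float32), white.astype(np.float32), truth
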