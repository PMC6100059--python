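"""Seed/background segmentation and per-seed ROI labelling.

The mask is built at the single band where foreground/background contrast
peaks, thresholded by Otsu's method; connected components then become the
regions of interest (one per seed).  The protocol assumes seeds are laid
out without touching, so no splitting of merged objects is attempted.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

from .io import HyperCube

__all__ = ["RoiLabelMap", "select_contrast_band", "build_mask", "label_rois", "apply_mask"]


@dataclasses.dataclass
class RoiLabelMap:
    """Integer image: 0 = background, 1..K = seed objects.

    Labels are consecutive and assigned in raster-scan discovery order.
    ``border_labels`` flags ROIs touching the image border (kept, but a
    caller may wish to treat them specially).
    """

    labels: np.ndarray
    roi_sizes: np.ndarray  # pixel count per label, index 0 unused
    border_labels: np.ndarray

    @property
    def n_rois(self) -> int:
        return len(self.roi_sizes) - 1

    def pixels_of(self, label: int) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.labels == label)


def select_contrast_band(cube: HyperCube, rough_fg_quantile: float = 0.5) -> tuple[int, float]:
    """Band maximising |mean(provisional foreground) - mean(background)|.

    At each band the provisional split is a quantile threshold (default the
    median); ties break to the lower band index.  Returns (index, nm).
    """
    if cube.kind != "corrected":
        raise ValueError("contrast band selection expects a reflectance-corrected cube")
    vals = cube.values.reshape(-1, cube.n_bands)
    thr = np.quantile(vals, rough_fg_quantile, axis=0)
    contrasts = np.zeros(cube.n_bands)
    for b in range(cube.n_bands):
        fg = vals[:, b] > thr[b]
        if fg.all() or not fg.any():
            continue
        contrasts[b] = abs(vals[fg, b].mean() - vals[~fg, b].mean())
    if np.all(contrasts == 0):
        raise ValueError("cube is flat: zero foreground/background contrast at every band")
    band = int(np.argmax(contrasts))  # argmax returns the first (lowest) maximiser
    return band, float(cube.wavelengths_nm[band])


def build_mask(cube: HyperCube, band: int) -> np.ndarray:
    """Binary sample mask from Otsu's threshold on one band's grey image.

    Background pixels carry 0, sample pixels 1, so that multiplying the
    mask into the cube zeroes background spectra and leaves seed spectra
    untouched.
    """
    if not 0 <= band < cube.n_bands:
        raise ValueError(f"band {band} out of range 0..{cube.n_bands - 1}")
    grey = cube.values[:, :, band]
    if np.unique(grey).size < 2:
        raise ValueError("degenerate histogram: all pixels equal, Otsu threshold undefined")
    thr = threshold_otsu(grey)
    return (grey > thr).astype(np.uint8)


def label_rois(mask: np.ndarray, min_roi_size: int = 10, connectivity: int = 8) -> RoiLabelMap:
    """Connected-component labelling of the mask into seed ROIs.

    Components smaller than ``min_roi_size`` pixels are dropped; survivors
    are relabelled 1..K in raster-scan order of their first pixel.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask) > 0
    raw = measure.label(mask, connectivity=1 if connectivity == 4 else 2)
    sizes = np.bincount(raw.ravel())
    keep = np.zeros_like(sizes, dtype=bool)
    keep[1:] = sizes[1:] >= min_roi_size
    # relabel survivors in raster order of first occurrence
    flat = raw.ravel()
    order: dict[int, int] = {}
    for v in flat:
        if v and keep[v] and v not in order:
            order[v] = len(order) + 1
    lut = np.zeros_like(sizes)
    for old, new in order.items():
        lut[old] = new
    labels = lut[raw]
    k = len(order)
    roi_sizes = np.bincount(labels.ravel(), minlength=k + 1)
    border = np.zeros(k + 1, dtype=bool)
    edge = np.concatenate(
        [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
    )
    for v in np.unique(edge):
        if v:
            border[v] = True
    return RoiLabelMap(labels=labels, roi_sizes=roi_sizes, border_labels=np.nonzero(border)[0])


def apply_mask(cube: HyperCube, mask: np.ndarray) -> HyperCube:
    """Zero out background spectra by mask multiplication."""
    if mask.shape != cube.values.shape[:2]:
        raise ValueError("mask geometry does not match cube")
    vals = cube.values * (np.asarray(mask) > 0)[:, :, np.newaxis]
    return HyperCube(vals.astype(cube.values.dtype, copy=False), cube.wavelengths_nm, kind=cube.kind)
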