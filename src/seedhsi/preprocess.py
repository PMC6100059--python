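"""Wavelet smoothing of pixel-wise spectra and per-seed spectral averaging.

Each foreground pixel's spectrum is decomposed with a Daubechies-7 wavelet
to level 3 (symmetric boundary extension).  Two reconstruction rules are
offered: ``universal-soft`` soft-thresholds the detail coefficients at the
universal threshold sigma*sqrt(2 ln n), with sigma estimated per spectrum
from the finest-level details (median absolute deviation / 0.6745);
``approximation-only`` discards the details entirely.  The seed-level
spectrum is the arithmetic mean of its (smoothed) pixel spectra.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pywt

from .io import HyperCube
from .segment import RoiLabelMap

__all__ = ["DenoiseConfig", "denoise_spectrum", "denoise_cube", "roi_mean_spectra"]


@dataclasses.dataclass
class DenoiseConfig:
    wavelet_name: str = "db7"
    level: int = 3
    threshold_rule: str = "universal-soft"  # or "approximation-only"
    boundary_mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("decomposition level must be >= 1")
        if self.threshold_rule not in ("universal-soft", "approximation-only"):
            raise ValueError(f"unknown threshold rule {self.threshold_rule!r}")

    def min_length(self) -> int:
        """Shortest spectrum admitting this decomposition depth."""
        flen = pywt.Wavelet(self.wavelet_name).dec_len
        return (flen - 1) * 2**self.level


def _denoise_block(block: np.ndarray, config: DenoiseConfig) -> np.ndarray:
    """Denoise a (rows, bands) block of spectra along the last axis."""
    n = block.shape[-1]
    coeffs = pywt.wavedec(
        block, config.wavelet_name, level=config.level, mode=config.boundary_mode, axis=-1
    )
    if config.threshold_rule == "approximation-only":
        details = [np.zeros_like(d) for d in coeffs[1:]]
    else:
        finest = coeffs[-1]
        sigma = np.median(np.abs(finest), axis=-1, keepdims=True) / 0.6745
        thr = sigma * np.sqrt(2.0 * np.log(n))
        details = [np.sign(d) * np.maximum(np.abs(d) - thr, 0.0) for d in coeffs[1:]]
    rec = pywt.waverec([coeffs[0]] + details, config.wavelet_name, mode=config.boundary_mode, axis=-1)
    return rec[..., :n]


def denoise_spectrum(spectrum: np.ndarray, config: DenoiseConfig | None = None) -> np.ndarray:
    """Smooth a single spectrum; length preserved, deterministic."""
    config = config or DenoiseConfig()
    spectrum = np.asarray(spectrum, dtype=float)
    need = config.min_length()
    if spectrum.shape[-1] < need:
        raise ValueError(
            f"spectrum of length {spectrum.shape[-1]} too short for level "
            f"{config.level} with {config.wavelet_name}; need >= {need} points"
        )
    return _denoise_block(spectrum[np.newaxis, :], config)[0]


def denoise_cube(cube: HyperCube, mask: np.ndarray, config: DenoiseConfig | None = None) -> HyperCube:
    """Apply :func:`denoise_spectrum` to every foreground pixel of the cube.

    Background pixel spectra are copied through bit-identically.
    """
    config = config or DenoiseConfig()
    mask = np.asarray(mask) > 0
    if mask.shape != cube.values.shape[:2]:
        raise ValueError("mask geometry does not match cube")
    need = config.min_length()
    if cube.n_bands < need:
        raise ValueError(
            f"cube has {cube.n_bands} bands, need >= {need} for level {config.level}"
        )
    out = cube.values.copy()
    rows, cols = np.nonzero(mask)
    if rows.size:
        block = cube.values[rows, cols, :].astype(float)
        out[rows, cols, :] = _denoise_block(block, config).astype(out.dtype, copy=False)
    return HyperCube(out, cube.wavelengths_nm, kind=cube.kind)


def roi_mean_spectra(cube: HyperCube, rois: RoiLabelMap) -> np.ndarray:
    """Mean spectrum per ROI: row r-1 is the per-band average over label r.

    Accumulation is in float64 with a label-wise bincount, so the result
    does not depend on pixel iteration order.
    """
    labels = rois.labels
    if labels.shape != cube.values.shape[:2]:
        raise ValueError("label map geometry does not match cube")
    k = rois.n_rois
    flat_labels = labels.ravel()
    counts = np.bincount(flat_labels, minlength=k + 1)[1:].astype(float)
    means = np.empty((k, cube.n_bands), dtype=float)
    vals = cube.values.reshape(-1, cube.n_bands).astype(np.float64)
    for b in range(cube.n_bands):
        sums = np.bincount(flat_labels, weights=vals[:, b], minlength=k + 1)[1:]
        means[:, b] = sums / counts
    return means
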