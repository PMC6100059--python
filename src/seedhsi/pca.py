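"""Pixel-level PCA, score images and loading-based effective wavelengths.

Principal components are fitted on the foreground pixel spectra; score
images render each foreground pixel's projection onto a component with the
background zeroed by mask multiplication.  Effective wavelengths (EWs) are
the local peaks and valleys of the first few loading curves, pooled across
components and deduplicated so that only one wavelength survives in any
close spectral neighbourhood.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from sklearn.decomposition import PCA

from .io import HyperCube, wavelength_columns

__all__ = [
    "PcaModel",
    "EwSet",
    "achievable_components",
    "fit_pixel_pca",
    "score_images",
    "select_ews",
    "restrict_to_ews",
]


def achievable_components(spectra: np.ndarray, n_components: int) -> int:
    """Largest component count the data's rank supports, capped at ``n_components``.

    Degenerate inputs (e.g. noiseless scenes where all pixels of a class
    share one spectrum) have a centered rank below the requested component
    count; callers can clip to this before fitting.
    """
    spectra = np.asarray(spectra, dtype=float)
    rank = int(np.linalg.matrix_rank(spectra - spectra.mean(axis=0)))
    return max(1, min(n_components, rank))


@dataclasses.dataclass
class PcaModel:
    """Fitted PCA: mean spectrum, loading matrix and variance fractions.

    ``loadings`` is (bands x components) with orthonormal columns; the sign
    of each column is fixed so that its largest-magnitude entry is positive,
    which makes score images and extremum kinds reproducible.
    """

    mean_spectrum: np.ndarray
    loadings: np.ndarray
    explained_variance_fraction: np.ndarray
    n_components: int

    def transform(self, spectra: np.ndarray) -> np.ndarray:
        return (np.asarray(spectra, dtype=float) - self.mean_spectrum) @ self.loadings


@dataclasses.dataclass
class EwSet:
    """Selected effective wavelengths, sorted increasing."""

    wavelengths_nm: np.ndarray
    band_indices: np.ndarray
    source_component: np.ndarray
    extremum_kind: list[str]  # "peak" or "valley" on the loading curve

    def __len__(self) -> int:
        return len(self.wavelengths_nm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavelength_nm": self.wavelengths_nm,
                "band_index": self.band_indices,
                "source_component": self.source_component,
                "extremum_kind": self.extremum_kind,
            }
        )


def fit_pixel_pca(
    spectra: np.ndarray,
    n_components: int = 6,
    *,
    subsample_cap: int | None = 50_000,
    rng_seed: int = 0,
) -> PcaModel:
    """Fit PCA on a (pixels x bands) spectra matrix.

    Rows beyond ``subsample_cap`` are uniformly subsampled (seeded) to bound
    memory; centering is internal.  Components come out ordered by explained
    variance, deterministic thanks to the full SVD solver and the sign
    convention.
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 2:
        raise ValueError("spectra must be a 2-D (pixels x bands) matrix")
    n, p = spectra.shape
    if n < n_components + 1:
        raise ValueError(f"need at least {n_components + 1} spectra, got {n}")
    if subsample_cap is not None and n > subsample_cap:
        rng = np.random.default_rng(rng_seed)
        idx = np.sort(rng.choice(n, size=subsample_cap, replace=False))
        spectra = spectra[idx]
    if min(spectra.shape) <= 200:  # cheap enough to diagnose rank deficiency up front
        rank = np.linalg.matrix_rank(spectra - spectra.mean(axis=0))
        if rank < n_components:
            raise ValueError(f"data rank {rank} below requested {n_components} components")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(spectra)
    loadings = pca.components_.T.copy()  # bands x components
    # sign convention: largest-magnitude entry of each loading is positive
    for j in range(loadings.shape[1]):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
    return PcaModel(
        mean_spectrum=pca.mean_.copy(),
        loadings=loadings,
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
        n_components=n_components,
    )


def score_images(model: PcaModel, cube: HyperCube, mask: np.ndarray) -> np.ndarray:
    """Score image stack (components x height x width); background exactly 0."""
    if model.mean_spectrum.size != cube.n_bands:
        raise ValueError(
            f"model has {model.mean_spectrum.size} bands, cube has {cube.n_bands}"
        )
    mask = np.asarray(mask) > 0
    if mask.shape != cube.values.shape[:2]:
        raise ValueError("mask geometry does not match cube")
    h, w, _ = cube.shape
    out = np.zeros((model.n_components, h, w), dtype=float)
    rows, cols = np.nonzero(mask)
    if rows.size:
        scores = model.transform(cube.values[rows, cols, :])
        out[:, rows, cols] = scores.T
    return out


def select_ews(
    model: PcaModel,
    wavelengths_nm: np.ndarray,
    prominence_fraction: float = 0.1,
    dedup_window_nm: float = 10.0,
    dedup_rank: str = "weighted",
) -> EwSet:
    """Effective wavelengths from loading-curve extrema.

    Per component, local maxima and minima with prominence at least
    ``prominence_fraction`` of that curve's max |loading| are candidates
    (curve endpoints never qualify).  Candidates pooled over components are
    deduplicated: within any ``dedup_window_nm`` neighbourhood only the
    strongest candidate survives (ties go to the lower wavelength).

    With ``dedup_rank="weighted"`` (default) candidate strength is the
    eigenvalue-scaled loading |l| * sqrt(explained variance fraction) — the
    band's contribution to overall spectral variance — so extrema of minor
    components cannot displace those of dominant ones; ``"loading"`` ranks
    by raw |l| irrespective of component importance.
    """
    if dedup_rank not in ("weighted", "loading"):
        raise ValueError(f"unknown dedup_rank {dedup_rank!r}")
    wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
    if wavelengths_nm.size != model.loadings.shape[0]:
        raise ValueError("wavelength vector does not match loading matrix")
    weights = np.sqrt(np.maximum(model.explained_variance_fraction, 0.0))
    if dedup_rank == "loading" or not np.any(weights > 0):
        weights = np.ones(model.n_components)
    cand: list[tuple[float, int, int, str, float]] = []  # (wl, band, comp, kind, strength)
    for comp in range(model.n_components):
        curve = model.loadings[:, comp]
        prom = prominence_fraction * np.max(np.abs(curve))
        if prom == 0:
            continue
        peaks, _ = find_peaks(curve, prominence=prom)
        valleys, _ = find_peaks(-curve, prominence=prom)
        for idx in peaks:
            cand.append((wavelengths_nm[idx], int(idx), comp + 1, "peak", weights[comp] * abs(curve[idx])))
        for idx in valleys:
            cand.append((wavelengths_nm[idx], int(idx), comp + 1, "valley", weights[comp] * abs(curve[idx])))
    # dedup: greedy by descending strength, tie -> lower wavelength
    cand.sort(key=lambda t: (-t[4], t[0]))
    kept: list[tuple[float, int, int, str, float]] = []
    for c in cand:
        if all(abs(c[0] - k[0]) >= dedup_window_nm for k in kept):
            kept.append(c)
    if not kept:
        warnings.warn("no effective wavelengths selected", stacklevel=2)
    kept.sort(key=lambda t: t[0])
    return EwSet(
        wavelengths_nm=np.array([c[0] for c in kept]),
        band_indices=np.array([c[1] for c in kept], dtype=int),
        source_component=np.array([c[2] for c in kept], dtype=int),
        extremum_kind=[c[3] for c in kept],
    )


def restrict_to_ews(table: pd.DataFrame, ews: EwSet) -> pd.DataFrame:
    """Keep only the identifier/class columns and the EW reflectance columns."""
    if len(ews) == 0:
        raise ValueError("empty effective-wavelength set")
    wl_cols = wavelength_columns(table)
    wl_vals = np.array([float(c) for c in wl_cols])
    keep_cols = [c for c in table.columns if c not in wl_cols]
    for wl in ews.wavelengths_nm:
        j = np.argmin(np.abs(wl_vals - wl))
        if abs(wl_vals[j] - wl) > 1e-6:
            raise ValueError(f"effective wavelength {wl} nm not present in table")
        keep_cols.append(wl_cols[j])
    return table[keep_cols].copy()
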