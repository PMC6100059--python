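"""Reflectance calibration against dark/white references and band cropping.

Relative reflectance is computed pixel- and band-wise as

    R = (I_raw - I_dark) / (I_white - I_dark)

where the dark frame records sensor dark current (light off, lens capped)
and the white frame a near-100%-reflectance standard.  References may be
full-frame images (height x width x bands) or line references
(width x bands) that broadcast along the scan axis.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import HyperCube

__all__ = ["ReferencePair", "InvalidReferenceError", "correct_reflectance", "crop_bands"]

#: fraction of elements allowed to violate white > dark before the pair is rejected
_BAD_FRACTION_TOL = 0.01


class InvalidReferenceError(ValueError):
    """White/dark pair unusable: white does not exceed dark almost everywhere."""


@dataclasses.dataclass
class ReferencePair:
    """Dark and white reference frames for reflectance correction."""

    dark: np.ndarray
    white: np.ndarray

    def __post_init__(self) -> None:
        self.dark = np.asarray(self.dark, dtype=float)
        self.white = np.asarray(self.white, dtype=float)
        if self.dark.shape != self.white.shape:
            raise ValueError("dark and white frames must share a shape")
        if self.dark.ndim not in (2, 3):
            raise ValueError("references must be rank 2 (line) or rank 3 (frame)")
        bad = np.mean(self.white <= self.dark)
        if bad > _BAD_FRACTION_TOL:
            raise InvalidReferenceError(
                f"white <= dark on {bad:.1%} of elements (tolerance {_BAD_FRACTION_TOL:.0%})"
            )


def correct_reflectance(
    raw: HyperCube,
    refs: ReferencePair,
    *,
    eps: float = 1e-6,
    clip: tuple[float, float] | None = (-0.05, 1.5),
) -> HyperCube:
    """Convert a raw cube to relative reflectance.

    Pixels where ``white - dark < eps`` are set to 0 (and counted in the
    guard); values outside ``clip`` are clipped.  Correcting a cube that is
    already reflectance is refused.
    """
    if raw.kind == "corrected":
        raise ValueError("cube is already reflectance-corrected")
    dark, white = refs.dark, refs.white
    if dark.ndim == 2:  # line reference: broadcast along the scan (row) axis
        dark = dark[np.newaxis, :, :]
        white = white[np.newaxis, :, :]
    try:
        np.broadcast_shapes(raw.values.shape, dark.shape)
    except ValueError as exc:
        raise ValueError(
            f"reference shape {refs.dark.shape} incompatible with cube {raw.values.shape}"
        ) from exc
    denom = white - dark
    guard = denom < eps
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (raw.values - dark) / denom
    out = np.where(np.broadcast_to(guard, out.shape), 0.0, out)
    if clip is not None:
        out = np.clip(out, clip[0], clip[1])
    return HyperCube(out.astype(raw.values.dtype, copy=False), raw.wavelengths_nm, kind="corrected")


def crop_bands(cube: HyperCube, low_nm: float = 975.0, high_nm: float = 1646.0) -> HyperCube:
    """Keep exactly the bands with ``low_nm <= wavelength <= high_nm``.

    Trims the noisy spectral extremes; with the instrument's 3.36 nm band
    spacing the default bounds retain the working 200-band window.
    """
    if low_nm > high_nm:
        raise ValueError("low_nm must not exceed high_nm")
    keep = (cube.wavelengths_nm >= low_nm) & (cube.wavelengths_nm <= high_nm)
    if not keep.any():
        raise ValueError(
            f"no bands in [{low_nm}, {high_nm}] nm; cube spans "
            f"[{cube.wavelengths_nm[0]:.1f}, {cube.wavelengths_nm[-1]:.1f}] nm"
        )
    return HyperCube(cube.values[:, :, keep], cube.wavelengths_nm[keep], kind=cube.kind)
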