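"""Flat key=value run configuration shared by all CLI stages.

Every field has a documented default; unknown keys are rejected so typos
cannot silently change a run.  The resolved config text is hashed and the
hash recorded with every artifact-producing stage, which makes any output
traceable to the exact configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

from .preprocess import DenoiseConfig
from .synthetic import SceneConfig, wide_band_config

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclasses.dataclass
class RunConfig:
    # scene generation
    n_scenes: int = 10
    image_height: int = 96
    image_width: int = 128
    wide_bands: bool = False  # full 256-band sensor grid instead of the cropped 200
    n_seeds_per_class: int = 4
    class_overlap: float = 1.0
    noise_sd: float = 0.02
    illumination_gradient: float = 0.05
    rng_seed: int = 0
    # calibration
    crop_low_nm: float = 975.0
    crop_high_nm: float = 1646.0
    # segmentation
    min_roi_size: int = 10
    # smoothing
    wavelet_name: str = "db7"
    wavelet_level: int = 3
    threshold_rule: str = "universal-soft"
    # PCA / effective wavelengths
    n_components: int = 6
    prominence_fraction: float = 0.1
    dedup_window_nm: float = 10.0
    pca_pixel_cap: int = 50_000
    # SVM grid search
    c_exp_min: int = -8
    c_exp_max: int = 8
    g_exp_min: int = -8
    g_exp_max: int = 8
    cv_folds: int = 5

    def scene_config(self) -> SceneConfig:
        kwargs = dict(
            image_height=self.image_height,
            image_width=self.image_width,
            n_seeds_per_class=self.n_seeds_per_class,
            class_overlap=self.class_overlap,
            noise_sd=self.noise_sd,
            illumination_gradient=self.illumination_gradient,
            rng_seed=self.rng_seed,
        )
        return wide_band_config(**kwargs) if self.wide_bands else SceneConfig(**kwargs)

    def denoise_config(self) -> DenoiseConfig:
        return DenoiseConfig(
            wavelet_name=self.wavelet_name,
            level=self.wavelet_level,
            threshold_rule=self.threshold_rule,
        )

    def c_exponents(self) -> list[int]:
        return list(range(self.c_exp_min, self.c_exp_max + 1))

    def g_exponents(self) -> list[int]:
        return list(range(self.g_exp_min, self.g_exp_max + 1))

    def as_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        return "\n".join(lines) + "\n"

    def hash(self) -> str:
        return hashlib.sha256(self.as_text().encode()).hexdigest()[:12]


def _coerce(value: str, target_type) -> object:
    value = value.strip()
    if target_type is bool:
        if value.lower() in ("true", "1", "yes"):
            return True
        if value.lower() in ("false", "0", "no"):
            return False
        raise ValueError(f"not a boolean: {value!r}")
    return target_type(value)


def load_config(path: str | Path | None, overrides: dict | None = None) -> RunConfig:
    """Parse a flat ``key = value`` file; ``overrides`` win over the file."""
    known = {f.name: f.type for f in dataclasses.fields(RunConfig)}
    types = {f.name: type(getattr(RunConfig(), f.name)) for f in dataclasses.fields(RunConfig)}
    values: dict = {}
    if path is not None:
        for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value', got {line!r}")
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in known:
                raise ValueError(f"{path}:{ln}: unknown config key {key!r}")
            values[key] = _coerce(val, types[key])
    for key, val in (overrides or {}).items():
        if val is None:
            continue
        if key not in known:
            raise ValueError(f"unknown config key {key!r}")
        values[key] = val
    return RunConfig(**values)


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(config.as_text())
    return path
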