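"""Pipeline configuration: every tunable of every stage, with validation.

A single flat :class:`Config` travels through the whole pipeline and is
echoed into every report so that a run can be reproduced bit-exactly from
its report alone. YAML round-trip via :func:`load_config` / :func:`save_config`;
unknown keys and out-of-range values are rejected loudly rather than ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["Config", "load_config", "save_config", "CONFIG_VERSION"]

CONFIG_VERSION = "1"


@dataclass(frozen=True)
class Config:
    # --- image enhancement ---
    target_mean: float = 128.0  # normalization target mean (gray levels)
    target_variance: float = 2000.0  # normalization target variance (gray levels^2)
    binarize_method: str = "adaptive"  # "adaptive" (block-wise Otsu) | "otsu" (global)
    adaptive_block: int = 16  # tile side for block-wise Otsu (px)
    smooth_sigma: float = 1.0  # Gaussian pre-smoothing before thresholding (px)
    min_object_px: int = 10  # speckles below this area are erased before thinning

    # --- ridge analysis ---
    orientation_block: int = 16  # orientation-field block side (px)
    l_eye: float = 40.0  # max enclosure skeleton-cycle length (px)
    l_spur: float = 8.0  # max spur branch length (px)
    l_prune: float = 4.0  # junction branches below this are noise, deleted
    min_quality: float = 0.3  # drop minutiae in low-coherence blocks
    l_short: float = 15.0  # max short-ridge length (px)
    pore_area_min: int = 1  # sweat-pore area window (px^2)
    pore_area_max: int = 20
    border_margin: int = 10  # drop features this close to the edge (px)
    min_separation: float = 12.0  # merge facing terminations closer than this (px)
    seg_exclusion_px: float = 10.0  # rim width excluded around signal dropouts (px)

    # --- matching ---
    r_min: float = 3.0  # exclusion radius around the core (px)
    include_pores: bool = False  # admit level-3 pores into the feature matrix
    tol_r: float = 10.0  # correspondence radius tolerance (px)
    tol_phi: float = 0.3  # correspondence angle tolerance (rad)
    penalize_unpaired: bool = False  # unmatched points contribute zero terms

    # imaging modality of each side of a comparison (controls polarity)
    sample_modality: str = "fluorescent_sample"
    control_modality: str = "inked_control"

    version: str = CONFIG_VERSION

    def __post_init__(self):
        positive = (
            "target_variance",
            "adaptive_block",
            "orientation_block",
            "l_eye",
            "l_spur",
            "l_short",
            "tol_r",
            "tol_phi",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)}")
        nonneg = (
            "target_mean",
            "min_object_px",
            "pore_area_min",
            "pore_area_max",
            "border_margin",
            "min_separation",
            "r_min",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.pore_area_max < self.pore_area_min:
            raise ConfigurationError("pore_area_max must be >= pore_area_min")
        if self.binarize_method not in ("otsu", "adaptive"):
            raise ConfigurationError(f"binarize_method must be otsu|adaptive, got {self.binarize_method!r}")
        for side in ("sample_modality", "control_modality"):
            if getattr(self, side) not in ("inked_control", "fluorescent_sample"):
                raise ConfigurationError(f"{side} must be inked_control|fluorescent_sample")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None) -> Config:
    """Load a YAML config; ``None`` or an empty file yield all defaults."""
    if path is None:
        return Config()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(Config)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return Config(**data)


def save_config(cfg: Config, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
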