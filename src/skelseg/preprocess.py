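"""HU thresholding, volume clipping, and the two normalization regimes.

Preprocessing runs in four steps: stretcher removal, thresholding to
[0, 300] HU (air/fat collapse to 0, everything at or above cortical density
saturates at 300), clipping of the caller-supplied slice range, and the
0–255 intensity normalization

    V_norm = 255 * (V - minGL) / (maxGL - minGL)

whose anchors equal the thresholding bounds.  Experiment B applies the
normalization intrapatient, i.e. here; Experiment A defers it to dataset
assembly, where the input volume is a randomized multi-patient set.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np

from . import stretcher as _stretcher
from .volume_io import CTVolume

__all__ = [
    "NormalizationMode",
    "PreprocessConfig",
    "threshold_hu",
    "clip_volume",
    "normalize",
    "run_preprocess",
    "DEFAULT_LOWER_HU",
    "DEFAULT_UPPER_HU",
]

logger = logging.getLogger(__name__)

DEFAULT_LOWER_HU = 0.0
DEFAULT_UPPER_HU = 300.0


class NormalizationMode(str, enum.Enum):
    """Placement of the 0–255 normalization in the pipeline."""

    A_INTERPATIENT_INTRASET = "A"
    B_INTRAPATIENT = "B"


@dataclass
class PreprocessConfig:
    lower_hu: float = DEFAULT_LOWER_HU
    upper_hu: float = DEFAULT_UPPER_HU
    normalization_mode: NormalizationMode = NormalizationMode.A_INTERPATIENT_INTRASET
    crop_femur_start: int | None = None
    crop_head_start: int | None = None
    # stretcher-removal knobs, forwarded verbatim
    remove_stretcher: bool = True
    binarize_hu: float = _stretcher.DEFAULT_BINARIZE_HU
    dilation_radius: int = _stretcher.DEFAULT_DILATION_RADIUS
    gap: int = _stretcher.DEFAULT_GAP
    accessory_fraction: float = _stretcher.DEFAULT_ACCESSORY_FRACTION

    def __post_init__(self) -> None:
        if self.lower_hu >= self.upper_hu:
            raise ValueError("lower_hu must be < upper_hu")
        self.normalization_mode = NormalizationMode(self.normalization_mode)
        if (
            self.crop_femur_start is not None
            and self.crop_head_start is not None
            and not self.crop_femur_start < self.crop_head_start
        ):
            raise ValueError("crop_femur_start must be < crop_head_start")


def threshold_hu(
    volume: CTVolume,
    lower_hu: float = DEFAULT_LOWER_HU,
    upper_hu: float = DEFAULT_UPPER_HU,
) -> CTVolume:
    """Clamp HU values to [lower_hu, upper_hu] (idempotent)."""
    if lower_hu >= upper_hu:
        raise ValueError("lower_hu must be < upper_hu")
    return volume.with_voxels(np.clip(volume.voxels, lower_hu, upper_hu))


def clip_volume(volume: CTVolume, femur_start: int, head_start: int) -> CTVolume:
    """Keep only axial slices [femur_start, head_start)."""
    if not 0 <= femur_start < head_start <= volume.slice_count:
        raise ValueError(
            f"invalid clip range ({femur_start}, {head_start}) for "
            f"{volume.slice_count} slices"
        )
    return volume.with_voxels(volume.voxels[femur_start:head_start].copy())


def _round_half_away_from_zero(x: np.ndarray) -> np.ndarray:
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


def normalize(values: np.ndarray, min_gl: float, max_gl: float) -> np.ndarray:
    """Map gray levels in [min_gl, max_gl] linearly onto integers in [0, 255].

    The anchors map exactly to 0 and 255; the conversion to integers rounds
    half away from zero (127.5 -> 128).  Values outside the anchor range are
    rejected — threshold first.
    """
    values = np.asarray(values)
    if not max_gl > min_gl:
        raise ValueError("max_gl must be > min_gl")
    if values.size and (values.min() < min_gl or values.max() > max_gl):
        raise ValueError(
            f"values outside [{min_gl}, {max_gl}]; apply threshold_hu first"
        )
    scaled = 255.0 * (values - min_gl) / (max_gl - min_gl)
    return _round_half_away_from_zero(scaled).astype(np.int64)


def run_preprocess(volume: CTVolume, config: PreprocessConfig) -> CTVolume:
    """Run the preprocessing chain on one patient volume.

    Order: stretcher removal -> thresholding -> clipping; under mode B the
    0-255 normalization is applied here (intrapatient), under mode A it is
    deferred to dataset assembly.
    """
    out = volume
    if config.remove_stretcher:
        out, _ = _stretcher.remove_stretcher(
            out,
            dilation_radius=config.dilation_radius,
            threshold=config.binarize_hu,
            gap=config.gap,
            accessory_fraction=config.accessory_fraction,
        )
    out = threshold_hu(out, config.lower_hu, config.upper_hu)
    if config.crop_femur_start is not None or config.crop_head_start is not None:
        femur = config.crop_femur_start or 0
        head = config.crop_head_start if config.crop_head_start is not None else out.slice_count
        out = clip_volume(out, femur, head)
    if config.normalization_mode is NormalizationMode.B_INTRAPATIENT:
        out = out.with_voxels(normalize(out.voxels, config.lower_hu, config.upper_hu))
    return out


def suggest_femur_start(volume: CTVolume, min_bone_area: int = 20) -> int:
    """Naive optional heuristic: first slice whose bone-candidate area
    (voxels at or above 300 HU) reaches ``min_bone_area`` pixels.

    Off by default everywhere; anatomical landmark detection is out of scope
    and crop indices are normally caller-supplied.
    """
    areas = np.sum(volume.voxels >= DEFAULT_UPPER_HU, axis=(1, 2))
    hits = np.flatnonzero(areas >= min_bone_area)
    return int(hits[0]) if hits.size else 0
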