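"""Threshold-based segmentation of puncta, mitochondria, somata and the cell ROI.

Segmentation everywhere follows the same recipe: optional Gaussian
pre-smoothing, a global intensity threshold (Otsu by default, with
percentile/absolute overrides reproducing per-image optimization), then
morphological and size/shape filtering. The numeric threshold applied to
each image is recorded in the mask metadata so per-image choices stay
auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology

from .errors import AnalysisError, ConfigurationError, DegenerateThresholdError, InputError
from .imaging import BinaryMask, CalibratedImage, LabelMask, ParticleSet, label_connected

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdSpec",
    "SizeShapeFilter",
    "threshold_channel",
    "filter_particles",
    "detect_somata",
    "define_cell_roi",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """How to binarize one channel.

    method
        ``otsu`` (histogram bimodality criterion), ``percentile`` (foreground
        = pixels above the given order statistic) or ``absolute``.
    pre_smooth_sigma_px
        Gaussian sigma applied before thresholding; 0 disables smoothing.
    """

    method: str = "otsu"
    percentile: float | None = None
    absolute_value: float | None = None
    pre_smooth_sigma_px: float = 0.0

    def __post_init__(self) -> None:
        if self.method not in ("otsu", "percentile", "absolute"):
            raise ConfigurationError(f"unknown threshold method {self.method!r}")
        if self.pre_smooth_sigma_px < 0:
            raise ConfigurationError("pre_smooth_sigma_px must be >= 0")
        if self.method == "percentile":
            if self.percentile is None or not (0 < self.percentile < 100):
                raise ConfigurationError("percentile method needs percentile in (0,100)")
            if self.absolute_value is not None:
                raise ConfigurationError("absolute_value not allowed with percentile")
        elif self.method == "absolute":
            if self.absolute_value is None:
                raise ConfigurationError("absolute method needs absolute_value")
            if self.percentile is not None:
                raise ConfigurationError("percentile not allowed with absolute")
        else:
            if self.percentile is not None or self.absolute_value is not None:
                raise ConfigurationError("otsu takes no percentile/absolute parameters")


@dataclass(frozen=True)
class SizeShapeFilter:
    """Size and shape window selecting punctate particles.

    Defaults select diffraction-limited-to-small puncta (0.03–1.5 μm²) and
    reject poorly filled or strongly elongated fragments such as pieces of
    labeled processes.
    """

    min_area_um2: float = 0.03
    max_area_um2: float = 1.5
    min_solidity: float = 0.6
    max_eccentricity: float = 0.98

    def __post_init__(self) -> None:
        if not self.min_area_um2 < self.max_area_um2:
            raise ConfigurationError("min_area_um2 must be < max_area_um2")
        if not (0 <= self.min_solidity <= 1):
            raise ConfigurationError("min_solidity must be in [0,1]")
        if not (0 <= self.max_eccentricity <= 1):
            raise ConfigurationError("max_eccentricity must be in [0,1]")


def _smoothed(arr: np.ndarray, sigma: float) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if sigma > 0:
        arr = ndi.gaussian_filter(arr, sigma=sigma)
    return arr


def threshold_channel(
    image: CalibratedImage,
    channel: str,
    spec: ThresholdSpec,
    role: str = "particle",
    allow_degenerate: bool = False,
) -> BinaryMask:
    """Binarize one channel; foreground = smoothed intensity > threshold.

    The numeric threshold is stored in ``mask.meta["threshold"]``. Otsu on a
    constant image raises :class:`DegenerateThresholdError` unless
    ``allow_degenerate`` explicitly permits an empty mask.
    """
    arr = _smoothed(image.channel(channel), spec.pre_smooth_sigma_px)
    if spec.method == "otsu":
        if np.ptp(arr) == 0:
            if allow_degenerate:
                return BinaryMask(
                    np.zeros(arr.shape, bool),
                    image.pixel_size_nm,
                    role=role,
                    meta={"threshold": float("nan"), "method": "otsu"},
                )
            raise DegenerateThresholdError(
                f"channel {channel!r} is constant; Otsu threshold undefined"
            )
        thr = float(filters.threshold_otsu(arr))
    elif spec.method == "percentile":
        thr = float(np.percentile(arr, spec.percentile))
    else:
        thr = float(spec.absolute_value)
    mask = arr > thr
    logger.debug("threshold_channel %s: method=%s thr=%.4g fg=%d",
                 channel, spec.method, thr, int(mask.sum()))
    return BinaryMask(
        mask,
        image.pixel_size_nm,
        role=role,
        meta={"threshold": thr, "method": spec.method,
              "pre_smooth_sigma_px": spec.pre_smooth_sigma_px},
    )


def filter_particles(particles: ParticleSet, filt: SizeShapeFilter) -> ParticleSet:
    """Keep particles inside the size/shape window (bounds inclusive)."""
    kept = []
    removed = {"too_small": 0, "too_large": 0, "low_solidity": 0, "too_eccentric": 0}
    for p in particles:
        if p.area_um2 < filt.min_area_um2:
            removed["too_small"] += 1
        elif p.area_um2 > filt.max_area_um2:
            removed["too_large"] += 1
        elif p.solidity < filt.min_solidity:
            removed["low_solidity"] += 1
        elif p.eccentricity > filt.max_eccentricity:
            removed["too_eccentric"] += 1
        else:
            kept.append(p)
    if any(removed.values()):
        logger.info("filter_particles removed %s", removed)
    return ParticleSet(kept, particles.pixel_size_nm)


def detect_somata(
    image: CalibratedImage,
    marker_channel: str,
    spec: ThresholdSpec,
    min_soma_area_um2: float = 50.0,
    fill_holes: bool = True,
    selection: Sequence[int] | None = None,
    morph_radius_px: int = 2,
) -> LabelMask:
    """Detect neuronal somata from a cytoplasmic marker channel.

    Threshold, then morphological opening and closing with a disk of
    ``morph_radius_px``, optional hole filling, a minimum-area filter, and
    connected-component labeling. ``selection`` reproduces manual
    verification as an explicit include-list of label ids (an empty list
    keeps nothing); labels are renumbered consecutively afterwards.
    """
    mask = threshold_channel(image, marker_channel, spec, role="soma").mask
    if morph_radius_px > 0:
        disk = morphology.disk(morph_radius_px)
        mask = morphology.opening(mask, disk)
        mask = morphology.closing(mask, disk)
    if fill_holes:
        mask = ndi.binary_fill_holes(mask)
    lab = label_connected(
        BinaryMask(mask, image.pixel_size_nm, role="soma"), connectivity=8
    )
    um2_per_px = (image.pixel_size_nm / 1000.0) ** 2
    counts = np.bincount(lab.labels.ravel())
    keep = {
        k for k in range(1, len(counts)) if counts[k] * um2_per_px >= min_soma_area_um2
    }
    if selection is not None:
        keep &= set(int(s) for s in selection)
    out = np.zeros(lab.shape, dtype=np.int32)
    for new_id, old_id in enumerate(sorted(keep), start=1):
        out[lab.labels == old_id] = new_id
    if not keep:
        logger.warning("detect_somata: no soma survived filtering/selection")
    return LabelMask(out, image.pixel_size_nm)


def define_cell_roi(
    strategy: str,
    *,
    image: CalibratedImage | None = None,
    membrane_channel: str | None = None,
    threshold_spec: ThresholdSpec | None = None,
    mitochondria: BinaryMask | None = None,
    particles: BinaryMask | None = None,
    user_mask: BinaryMask | None = None,
    margin_px: int = 20,
) -> BinaryMask:
    """Delineate the cellular region of interest used for randomization.

    Strategies: ``membrane_channel`` (threshold + fill holes),
    ``hull_of_structures`` (convex hull of the union of the mitochondrial and
    particle masks, dilated by ``margin_px``), ``user_mask`` (pass-through
    after a dimension check).
    """
    if strategy == "user_mask":
        if user_mask is None:
            raise ConfigurationError("user_mask strategy needs user_mask")
        roi = user_mask.mask.copy()
        px = user_mask.pixel_size_nm
    elif strategy == "membrane_channel":
        if image is None or membrane_channel is None:
            raise ConfigurationError("membrane_channel strategy needs image+channel")
        m = threshold_channel(
            image, membrane_channel, threshold_spec or ThresholdSpec()
        ).mask
        roi = ndi.binary_fill_holes(m)
        px = image.pixel_size_nm
    elif strategy == "hull_of_structures":
        if mitochondria is None:
            raise ConfigurationError("hull_of_structures strategy needs mitochondria")
        union = mitochondria.mask.copy()
        px = mitochondria.pixel_size_nm
        if particles is not None:
            if particles.shape != mitochondria.shape:
                raise InputError("particle/mitochondria mask shape mismatch")
            union |= particles.mask
        if not union.any():
            raise AnalysisError("hull_of_structures: union of structures is empty")
        roi = morphology.convex_hull_image(union)
        if margin_px > 0:
            roi = morphology.dilation(roi, morphology.disk(margin_px))
    else:
        raise ConfigurationError(f"unknown ROI strategy {strategy!r}")
    if not roi.any():
        raise AnalysisError("cell ROI is empty; randomization cannot run")
    return BinaryMask(roi, px, role="cell_roi", meta={"strategy": strategy})
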