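"""Calibrated image containers, TIFF I/O, labeling and particle extraction.

All rasters are 2-D ``(row, col)`` arrays with 0-based indices; row increases
downward. Physical calibration is a single positive pixel edge length in
nanometres that every derived quantity (areas in μm², distances in nm)
inherits. Pixel size must be supplied explicitly — TIFF resolution tags are
used only as a fallback, with a logged warning, because acquisition metadata
is frequently wrong or missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage import measure

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "CalibratedImage",
    "BinaryMask",
    "LabelMask",
    "Particle",
    "ParticleSet",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "project_z",
    "label_connected",
    "extract_particles",
]


@dataclass
class CalibratedImage:
    """Multi-channel fluorescence image with physical pixel calibration.

    Parameters
    ----------
    channels
        Ordered mapping of channel name to a 2-D intensity raster, or to a
        3-D ``(planes, rows, cols)`` stack awaiting Z-projection.
    pixel_size_nm
        Edge length of one pixel in nanometres; must be positive.
    source_id
        Free-text provenance tag (file path, generator seed, ...).
    """

    channels: dict[str, np.ndarray]
    pixel_size_nm: float
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise InputError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")
        if not self.channels:
            raise InputError("image must have at least one channel")
        shapes = set()
        for name, arr in self.channels.items():
            arr = np.asarray(arr)
            if arr.ndim not in (2, 3):
                raise InputError(f"channel {name!r} must be 2-D or a 3-D stack")
            if arr.ndim == 3 and arr.shape[0] == 0:
                raise InputError(f"channel {name!r} is an empty stack")
            if not np.all(np.isfinite(arr)):
                raise InputError(f"channel {name!r} contains non-finite values")
            if arr.min() < 0:
                raise InputError(f"channel {name!r} contains negative intensities")
            self.channels[name] = arr
            shapes.add(arr.shape[-2:])
        if len(shapes) != 1:
            raise InputError(f"channels differ in height×width: {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, int]:
        """Height × width shared by all channels."""
        return next(iter(self.channels.values())).shape[-2:]

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    @property
    def is_stack(self) -> bool:
        """True if any channel is a multi-plane stack needing projection."""
        return any(a.ndim == 3 for a in self.channels.values())

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise ConfigurationError(
                f"no channel {name!r}; available: {self.channel_names}"
            ) from None


@dataclass
class BinaryMask:
    """Boolean raster sharing geometry and calibration with its parent image."""

    mask: np.ndarray
    pixel_size_nm: float
    role: str = "particle"  # particle | mitochondria | soma | cell_roi
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise InputError("mask must be 2-D")
        if self.pixel_size_nm <= 0:
            raise InputError("pixel_size_nm must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())

    @property
    def area_um2(self) -> float:
        """Total foreground area in μm²."""
        return self.n_foreground * (self.pixel_size_nm / 1000.0) ** 2


@dataclass
class LabelMask:
    """Integer raster: 0 = background, k > 0 = object k (consecutive labels)."""

    labels: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise InputError("label raster must be 2-D")
        if self.pixel_size_nm <= 0:
            raise InputError("pixel_size_nm must be > 0")
        if self.labels.size and self.labels.min() < 0:
            raise InputError("labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    def binary(self, role: str = "particle") -> BinaryMask:
        return BinaryMask(self.labels > 0, self.pixel_size_nm, role=role)


@dataclass
class Particle:
    """One segmented punctum."""

    id: int
    coords: np.ndarray  # (n_px, 2) int row/col
    centroid: tuple[float, float]  # intensity-unweighted, pixel units
    area_px: int
    area_um2: float
    mean_intensity: float
    solidity: float
    eccentricity: float


@dataclass
class ParticleSet:
    """Collection of particles sharing one image's calibration."""

    particles: list[Particle]
    pixel_size_nm: float

    def __len__(self) -> int:
        return len(self.particles)

    def __iter__(self) -> Iterator[Particle]:
        return iter(self.particles)

    def __getitem__(self, i: int) -> Particle:
        return self.particles[i]

    @property
    def ids(self) -> list[int]:
        return [p.id for p in self.particles]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "particle_id": [p.id for p in self.particles],
                "centroid_row": [p.centroid[0] for p in self.particles],
                "centroid_col": [p.centroid[1] for p in self.particles],
                "area_px": [p.area_px for p in self.particles],
                "area_um2": [p.area_um2 for p in self.particles],
                "mean_intensity": [p.mean_intensity for p in self.particles],
                "solidity": [p.solidity for p in self.particles],
                "eccentricity": [p.eccentricity for p in self.particles],
            }
        )


# ---------------------------------------------------------------------------
# I/O


def _pixel_size_from_tags(tif: tifffile.TiffFile) -> float | None:
    # XResolution is pixels per ResolutionUnit; unit 3 = cm, 2 = inch
    page = tif.pages[0]
    tags = page.tags
    if "XResolution" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    unit = tags.get("ResolutionUnit")
    unit_nm = {2: 2.54e7, 3: 1e7}.get(getattr(unit, "value", 3), 1e7)
    return float(den) / float(num) * unit_nm


def read_image(
    path,
    pixel_size_nm: float | None,
    channel_names: Sequence[str],
    source_id: str | None = None,
) -> CalibratedImage:
    """Read a single- or multi-page TIFF as a :class:`CalibratedImage`.

    Page layout is interpreted against ``channel_names``: a 3-D array whose
    leading axis matches the number of names is one page per channel; with a
    single declared name it is a Z-stack (returned flagged for projection);
    anything else is a configuration error. 4-D arrays are taken as
    ``(planes, channels, rows, cols)`` or ``(channels, planes, rows, cols)``.

    If ``pixel_size_nm`` is None the TIFF resolution tags are consulted as a
    fallback and a warning is logged; absent usable tags, calibration is
    refused.
    """
    try:
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            if pixel_size_nm is None:
                pixel_size_nm = _pixel_size_from_tags(tif)
                if pixel_size_nm is None:
                    raise ConfigurationError(
                        f"{path}: no pixel size supplied and no usable "
                        "resolution tags; refusing uncalibrated analysis"
                    )
                logger.warning(
                    "%s: pixel size %.3f nm taken from TIFF resolution tags "
                    "(fallback); supply it explicitly for trusted calibration",
                    path,
                    pixel_size_nm,
                )
    except (FileNotFoundError, OSError, tifffile.TiffFileError) as exc:
        if isinstance(exc, ConfigurationError):
            raise
        raise InputError(f"cannot read TIFF {path}: {exc}") from exc

    names = list(channel_names)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        planes = [arr]
    elif arr.ndim == 3:
        if arr.shape[0] == len(names):
            planes = [arr[i] for i in range(arr.shape[0])]
        elif len(names) == 1:
            return CalibratedImage(
                {names[0]: arr}, pixel_size_nm, source_id or str(path)
            )
        else:
            raise ConfigurationError(
                f"{path}: {arr.shape[0]} pages but {len(names)} channel names"
            )
    elif arr.ndim == 4:
        if arr.shape[1] == len(names):  # (Z, C, H, W)
            return CalibratedImage(
                {n: arr[:, i] for i, n in enumerate(names)},
                pixel_size_nm,
                source_id or str(path),
            )
        if arr.shape[0] == len(names):  # (C, Z, H, W)
            return CalibratedImage(
                {n: arr[i] for i, n in enumerate(names)},
                pixel_size_nm,
                source_id or str(path),
            )
        raise ConfigurationError(
            f"{path}: 4-D shape {arr.shape} does not match {len(names)} channels"
        )
    else:
        raise InputError(f"{path}: unsupported TIFF dimensionality {arr.ndim}")

    if len(planes) != len(names):
        raise ConfigurationError(
            f"{path}: {len(planes)} pages but {len(names)} channel names"
        )
    return CalibratedImage(
        dict(zip(names, planes)), pixel_size_nm, source_id or str(path)
    )


def write_image(path, image: CalibratedImage) -> None:
    """Write channels as TIFF pages in order (stacks as (Z, C, H, W))."""
    arrs = list(image.channels.values())
    if image.is_stack:
        data = np.stack([np.atleast_3d(a) for a in arrs], axis=1)
    else:
        data = np.stack(arrs, axis=0)
    # grayscale pages; without this 3-channel images are misread as RGB
    tifffile.imwrite(path, data, photometric="minisblack")


def write_mask(path, mask: BinaryMask) -> None:
    """Write a binary mask as 8-bit {0, 255} TIFF."""
    tifffile.imwrite(path, mask.mask.astype(np.uint8) * 255,
                     photometric="minisblack")


def read_mask(path, pixel_size_nm: float, role: str = "particle") -> BinaryMask:
    try:
        arr = tifffile.imread(path)
    except (FileNotFoundError, OSError, tifffile.TiffFileError) as exc:
        raise InputError(f"cannot read mask TIFF {path}: {exc}") from exc
    return BinaryMask(np.asarray(arr) > 0, pixel_size_nm, role=role)


# ---------------------------------------------------------------------------
# Operations


def project_z(stack: CalibratedImage, method: str = "max") -> CalibratedImage:
    """Maximum-intensity projection of a Z-stack; single-plane input passes through."""
    if method != "max":
        raise ConfigurationError(f"unsupported projection {method!r}; only 'max'")
    out = {}
    for name, arr in stack.channels.items():
        if arr.ndim == 3:
            if arr.shape[0] == 0:
                raise InputError(f"channel {name!r}: empty stack")
            out[name] = arr.max(axis=0)
        else:
            out[name] = arr
    return CalibratedImage(out, stack.pixel_size_nm, stack.source_id)


def label_connected(mask: BinaryMask, connectivity: int = 8) -> LabelMask:
    """Label connected components under 4- or 8-connectivity.

    Labels are assigned 1..K in raster-scan order of first encounter.
    """
    if connectivity not in (4, 8):
        raise ConfigurationError(f"connectivity must be 4 or 8, got {connectivity}")
    lab = measure.label(mask.mask, connectivity=1 if connectivity == 4 else 2)
    return LabelMask(lab, mask.pixel_size_nm)


def extract_particles(labels: LabelMask, intensity: np.ndarray) -> ParticleSet:
    """Per-label geometry and intensity descriptors.

    Centroids are area (intensity-unweighted) centroids in pixel units;
    areas are reported both in pixels and μm² using the mask calibration.
    """
    intensity = np.asarray(intensity)
    if intensity.shape != labels.shape:
        raise InputError(
            f"intensity shape {intensity.shape} != labels shape {labels.shape}"
        )
    um2_per_px = (labels.pixel_size_nm / 1000.0) ** 2
    out: list[Particle] = []
    for rp in measure.regionprops(labels.labels, intensity_image=intensity):
        out.append(
            Particle(
                id=int(rp.label),
                coords=np.asarray(rp.coords, dtype=np.intp),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                area_px=int(rp.area),
                area_um2=float(rp.area) * um2_per_px,
                mean_intensity=float(rp.intensity_mean),
                solidity=float(rp.solidity),
                eccentricity=float(rp.eccentricity),
            )
        )
    return ParticleSet(out, labels.pixel_size_nm)
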