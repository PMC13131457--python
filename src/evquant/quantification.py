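"""Per-soma punctum counts, densities and the simple image quantifications.

A punctum belongs to the soma whose mask contains its centroid pixel
(floor-rounded), so each punctum is counted at most once. Dataset summaries
report mean ± SEM particles per cell, particle density per μm² of soma area,
and the fraction of somata containing at least one punctum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, InputError, UndefinedStatisticError
from .imaging import BinaryMask, CalibratedImage, LabelMask, ParticleSet

__all__ = [
    "SomaQuantResult",
    "CorrelationResult",
    "assign_particles_to_somata",
    "summarize_somata",
    "pearson_correlation",
    "correlation_p_from_r",
    "colabel_fraction",
    "channel_total_intensity",
    "dots_per_mask_area",
]


@dataclass
class SomaQuantResult:
    """Per-soma counts/densities plus dataset-level summaries."""

    per_soma: pd.DataFrame  # soma_id, soma_area_um2, particle_count, particle_density_per_um2
    mean_count: float
    sem_count: float
    fraction_of_somata_with_particles: float

    @property
    def n_somata(self) -> int:
        return len(self.per_soma)


@dataclass
class CorrelationResult:
    """Pearson product-moment correlation with exact t-based two-sided p."""

    r: float
    n: int
    t_statistic: float
    p_two_sided: float


def assign_particles_to_somata(
    particles: ParticleSet, somata: LabelMask
) -> dict[int, Optional[int]]:
    """Map each particle id to the soma label at its centroid pixel.

    The centroid is floor-rounded to the pixel that contains it; a centroid
    over background maps to ``None`` (unassigned).
    """
    out: dict[int, Optional[int]] = {}
    h, w = somata.shape
    for p in particles:
        r, c = int(np.floor(p.centroid[0])), int(np.floor(p.centroid[1]))
        if 0 <= r < h and 0 <= c < w:
            lab = int(somata.labels[r, c])
        else:
            lab = 0
        out[p.id] = lab if lab > 0 else None
    return out


def summarize_somata(
    assignment: Mapping[int, Optional[int]],
    somata: LabelMask,
) -> SomaQuantResult:
    """Per-soma particle counts and densities plus dataset mean ± SEM.

    Somata with zero particles are included; SEM uses the n−1 sample
    standard deviation. Raises on an empty soma mask.
    """
    k = somata.n_labels
    if k == 0:
        raise AnalysisError("no somata in label mask; nothing to summarize")
    um2_per_px = (somata.pixel_size_nm / 1000.0) ** 2
    areas_px = np.bincount(somata.labels.ravel(), minlength=k + 1)[1:]
    counts = np.zeros(k, dtype=int)
    for soma in assignment.values():
        if soma is not None:
            counts[soma - 1] += 1
    areas = areas_px * um2_per_px
    df = pd.DataFrame(
        {
            "soma_id": np.arange(1, k + 1),
            "soma_area_um2": areas,
            "particle_count": counts,
            "particle_density_per_um2": counts / areas,
        }
    )
    sem = float(np.std(counts, ddof=1) / np.sqrt(k)) if k > 1 else float("nan")
    return SomaQuantResult(
        per_soma=df,
        mean_count=float(counts.mean()),
        sem_count=sem,
        fraction_of_somata_with_particles=float((counts > 0).mean()),
    )


def correlation_p_from_r(r: float, n: int) -> tuple[float, float]:
    """Two-sided p for a Pearson r via t = r·√((n−2)/(1−r²)), n−2 df."""
    if n < 3:
        raise UndefinedStatisticError("correlation p requires n >= 3")
    if not -1 <= r <= 1:
        raise InputError(f"r must lie in [-1, 1], got {r}")
    if abs(r) == 1:
        return float("inf") * np.sign(r), 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return float(t), float(p)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with exact two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise UndefinedStatisticError("Pearson correlation requires n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("correlation undefined for zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = min(1.0, max(-1.0, r))
    t, p = correlation_p_from_r(r, n)
    return CorrelationResult(r=r, n=n, t_statistic=t, p_two_sided=p)


def colabel_fraction(reference: ParticleSet, query_mask: BinaryMask) -> float:
    """Fraction of reference particles overlapping ≥1 foreground query pixel."""
    if len(reference) == 0:
        raise UndefinedStatisticError("co-label fraction undefined for empty particle set")
    q = query_mask.mask
    hit = sum(1 for p in reference if q[p.coords[:, 0], p.coords[:, 1]].any())
    return hit / len(reference)


def channel_total_intensity(
    image: CalibratedImage, channel: str, within: BinaryMask | None = None
) -> float:
    """Summed intensity of one channel, optionally restricted to a mask."""
    arr = image.channel(channel)
    if within is None:
        return float(arr.sum())
    if within.shape != arr.shape:
        raise InputError("mask shape does not match channel")
    return float(arr[within.mask].sum())


def dots_per_mask_area(particles: ParticleSet, organelle_mask: BinaryMask) -> float:
    """Number of particles overlapping the mask per μm² of mask area."""
    if organelle_mask.n_foreground == 0:
        raise AnalysisError("organelle mask is empty; density undefined")
    m = organelle_mask.mask
    n_overlap = sum(1 for p in particles if m[p.coords[:, 0], p.coords[:, 1]].any())
    return n_overlap / organelle_mask.area_um2
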