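"""Ground-truthed synthetic micrographs for the three study image classes.

Apposition fields pair a filamentous organelle channel (union of dilated,
directionally persistent self-avoiding random walks) with a punctate EV
channel whose puncta are placed to satisfy an explicit distance plan —
an exact list of pixel edge-gaps, an exact contact fraction with a far-gap
range, or a Gaussian-mixture plan over distances in nm. Placement candidates
are found on a minimum-filtered Euclidean distance map so the realized
ground-truth distance is *verified with the same edge-distance definition
the analysis uses*; every field therefore carries exact per-punctum truth.

Soma fields place non-overlapping elliptical somata in a marker channel and
draw per-soma punctum counts from a zero-inflated model: a cell is
EV-positive with probability π, and positive cells draw counts from a
shifted Poisson with mean μ⁺ (so the dataset mean is π·μ⁺). Puncta are
placed near-uniformly inside each soma with a small boundary margin and a
minimum pairwise separation so that noise-free detection is exactly
invertible.

Rendering convolves the truth masks with a Gaussian PSF, applies Poisson
shot noise to the scaled intensities and adds Gaussian read noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy import ndimage as ndi
from skimage import draw, morphology

from .apposition import CONTACT_D_PX, _edge_nm, edge_to_edge_distances
from .errors import GenerationError, InputError
from .imaging import (
    BinaryMask,
    CalibratedImage,
    LabelMask,
    ParticleSet,
    extract_particles,
)

__all__ = [
    "GapListPlan",
    "ContactFractionPlan",
    "MixturePlan",
    "AppositionFieldSpec",
    "SomaFieldSpec",
    "PunctumTruth",
    "SyntheticGroundTruth",
    "generate_apposition_field",
    "generate_soma_field",
    "render_channels",
    "worked_example_field",
    "DEFAULT_AMPLITUDES",
]

DEFAULT_AMPLITUDES = {"ev": 200.0, "mitochondria": 150.0, "soma_marker": 120.0}


@dataclass(frozen=True)
class GapListPlan:
    """Exact background edge-gaps, in pixels, one per punctum."""

    gaps_px: tuple[int, ...]


@dataclass(frozen=True)
class ContactFractionPlan:
    """Exact contact fraction; the rest placed at far gaps (px range, inclusive)."""

    contact_fraction: float
    far_gap_px_range: tuple[int, int] = (6, 25)

    def __post_init__(self) -> None:
        if not 0 <= self.contact_fraction <= 1:
            raise InputError("contact_fraction must be in [0,1]")
        lo, hi = self.far_gap_px_range
        if lo < 1 or hi < lo:
            raise InputError("far_gap_px_range must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class MixturePlan:
    """Target edge distances drawn from a Gaussian mixture (nm); ≤0 → contact."""

    weights: tuple[float, ...]
    means_nm: tuple[float, ...]
    sds_nm: tuple[float, ...]

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.weights), 1.0):
            raise InputError("mixture weights must sum to 1")
        if not len(self.weights) == len(self.means_nm) == len(self.sds_nm):
            raise InputError("mixture component lists must have equal length")


DistancePlan = Union[GapListPlan, ContactFractionPlan, MixturePlan]


@dataclass(frozen=True)
class AppositionFieldSpec:
    shape: tuple[int, int] = (256, 256)
    pixel_size_nm: float = 65.0
    n_filaments: int = 3
    filament_width_px: int = 3
    filament_steps: int = 300
    n_puncta: int = 20
    punctum_radius_px: int = 2
    distance_plan: DistancePlan = ContactFractionPlan(0.5)
    psf_sigma_px: float = 1.0
    gaussian_sd: float = 2.0
    poisson_scaling: float = 1.0
    seed: int = 0


@dataclass(frozen=True)
class SomaFieldSpec:
    shape: tuple[int, int] = (1024, 1024)
    pixel_size_nm: float = 65.0
    n_somata: int = 10
    soma_semiaxis_a_um: tuple[float, float] = (5.0, 7.0)
    soma_semiaxis_b_um: tuple[float, float] = (4.0, 5.5)
    positive_probability: float = 0.67
    positive_mean: float = 4.2 / 0.67
    punctum_radius_px: int = 2
    psf_sigma_px: float = 1.0
    gaussian_sd: float = 2.0
    poisson_scaling: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.positive_probability <= 1:
            raise InputError("positive_probability must be in [0,1]")
        if self.positive_mean < 1:
            raise InputError("shifted-Poisson positive mean must be >= 1")


@dataclass
class PunctumTruth:
    id: int
    centroid: tuple[float, float]
    edge_distance_nm: float | None
    in_contact: bool | None
    soma_id: int | None = None


@dataclass
class SyntheticGroundTruth:
    """True masks and per-object records paired with a rendered image."""

    masks: dict[str, np.ndarray]  # truth label/binary rasters per channel role
    puncta: list[PunctumTruth]
    pixel_size_nm: float
    soma_counts: dict[int, int] | None = None
    extras: dict = field(default_factory=dict)

    @property
    def true_contact_fraction(self) -> float | None:
        flags = [p.in_contact for p in self.puncta if p.in_contact is not None]
        return float(np.mean(flags)) if flags else None

    @property
    def true_mean_count(self) -> float | None:
        if self.soma_counts is None:
            return None
        return float(np.mean(list(self.soma_counts.values())))

    def particle_set(self, channel: str = "ev") -> ParticleSet:
        """Extract particles from a truth label mask (unit intensity)."""
        lab = LabelMask(self.masks[channel], self.pixel_size_nm)
        return extract_particles(lab, np.ones(lab.shape))


# ---------------------------------------------------------------------------
# Mitochondrial network


def _filament_mask(
    shape: tuple[int, int],
    n_filaments: int,
    width_px: int,
    steps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Union of dilated directionally persistent self-avoiding random walks."""
    h, w = shape
    canvas = np.zeros(shape, dtype=bool)
    for _ in range(n_filaments):
        r = rng.uniform(0.15 * h, 0.85 * h)
        c = rng.uniform(0.15 * w, 0.85 * w)
        theta = rng.uniform(0, 2 * np.pi)
        visited: set[tuple[int, int]] = set()
        recent: list[tuple[int, int]] = []
        for _ in range(steps):
            placed = False
            for attempt in range(8):
                t = theta + rng.normal(0, 0.25) + attempt * rng.choice([-1, 1]) * 0.6
                nr, nc = r + np.sin(t), c + np.cos(t)
                px = (int(round(nr)), int(round(nc)))
                if not (1 <= px[0] < h - 1 and 1 <= px[1] < w - 1):
                    continue
                if px in visited and px not in recent[-3:]:
                    continue  # self-avoidance: do not recross the path
                r, c, theta = nr, nc, t
                visited.add(px)
                recent.append(px)
                canvas[px] = True
                placed = True
                break
            if not placed:
                break  # walk boxed in; stop this filament
    if width_px > 1:
        canvas = morphology.dilation(canvas, morphology.disk(width_px // 2))
    return canvas


# ---------------------------------------------------------------------------
# Punctum placement


def _disk_offsets(radius_px: int) -> np.ndarray:
    foot = morphology.disk(radius_px)
    return np.argwhere(foot) - radius_px


def _min_distance_map(mito: np.ndarray, radius_px: int) -> np.ndarray:
    """Per candidate center: min pixel-center distance from the punctum disk to mito."""
    edt = ndi.distance_transform_edt(~mito)
    return ndi.minimum_filter(edt, footprint=morphology.disk(radius_px))


def _place_puncta(
    mito: np.ndarray,
    targets: Sequence[tuple[float, float]],  # (target d_px, tolerance)
    radius_px: int,
    rng: np.random.Generator,
    separation_px: int = 3,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Place disks so each realizes its target min pixel separation to mito.

    ``targets`` entries are (d_px, tol): accept centers whose disk's minimum
    center distance to the organelle lies within tol of d_px. Contact targets
    use d_px = 0 with tol = CONTACT_D_PX. Puncta keep a pairwise gap of at
    least ``separation_px`` background pixels so they stay distinct objects.
    """
    h, w = mito.shape
    minf = _min_distance_map(mito, radius_px)
    margin = radius_px + 1
    inbounds = np.zeros_like(mito)
    inbounds[margin:h - margin, margin:w - margin] = True
    blocked = np.zeros_like(mito)
    block_r = 2 * radius_px + separation_px
    offs = _disk_offsets(radius_px)
    labels = np.zeros((h, w), dtype=np.int32)
    centers: list[tuple[int, int]] = []
    for i, (d_target, tol) in enumerate(targets, start=1):
        if d_target == 0.0:
            cond = minf <= tol
        else:
            cond = np.abs(minf - d_target) <= tol
        cand = np.argwhere(cond & inbounds & ~blocked)
        if len(cand) == 0:
            raise GenerationError(
                f"no placement satisfies target d_px={d_target:.2f}±{tol:.2f} "
                f"for punctum {i}; enlarge the field or relax the plan"
            )
        ctr = cand[rng.integers(0, len(cand))]
        pix = ctr + offs
        labels[pix[:, 0], pix[:, 1]] = i
        rr, cc = draw.disk(tuple(ctr), block_r + 0.5, shape=(h, w))
        blocked[rr, cc] = True
        centers.append((int(ctr[0]), int(ctr[1])))
    return labels, centers


def _plan_targets(
    plan: DistancePlan, n_puncta: int, pixel_size_nm: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Translate a distance plan into per-punctum (target d_px, tol) pairs."""
    if isinstance(plan, GapListPlan):
        if len(plan.gaps_px) != n_puncta:
            raise InputError("gap list length must equal n_puncta")
        return [(float(g) + 1.0, 1e-6) for g in plan.gaps_px]
    if isinstance(plan, ContactFractionPlan):
        n_contact = int(round(plan.contact_fraction * n_puncta))
        lo, hi = plan.far_gap_px_range
        targets = [(0.0, CONTACT_D_PX)] * n_contact
        for _ in range(n_puncta - n_contact):
            g = int(rng.integers(lo, hi + 1))
            targets.append((float(g) + 1.0, 1e-6))
        return targets
    if isinstance(plan, MixturePlan):
        comps = rng.choice(len(plan.weights), size=n_puncta, p=plan.weights)
        targets = []
        for k in comps:
            nm = rng.normal(plan.means_nm[k], plan.sds_nm[k])
            if nm <= 0.5 * pixel_size_nm:
                targets.append((0.0, CONTACT_D_PX))
            else:
                targets.append((nm / pixel_size_nm + 1.0, 0.5))
        return targets
    raise InputError(f"unknown distance plan {type(plan).__name__}")


def generate_apposition_field(
    spec: AppositionFieldSpec, max_field_retries: int = 5
) -> tuple[CalibratedImage, SyntheticGroundTruth]:
    """Render an EV + mitochondria field realizing the spec's distance plan.

    The realized per-punctum edge distances are recomputed on the truth
    masks with the analysis definition and stored in the ground truth; a
    plan that cannot be realized after ``max_field_retries`` fresh organelle
    geometries raises :class:`GenerationError`.
    """
    rng = np.random.default_rng(spec.seed)
    last_err: GenerationError | None = None
    for _ in range(max_field_retries):
        mito = _filament_mask(
            spec.shape, spec.n_filaments, spec.filament_width_px,
            spec.filament_steps, rng,
        )
        if not mito.any():
            continue
        targets = _plan_targets(spec.distance_plan, spec.n_puncta,
                                spec.pixel_size_nm, rng)
        try:
            labels, _ = _place_puncta(mito, targets, spec.punctum_radius_px, rng)
        except GenerationError as err:
            last_err = err
            continue
        break
    else:
        raise last_err or GenerationError("could not draw a usable organelle network")

    mito_mask = BinaryMask(mito, spec.pixel_size_nm, role="mitochondria")
    particles = extract_particles(
        LabelMask(labels, spec.pixel_size_nm), np.ones(spec.shape)
    )
    records = edge_to_edge_distances(particles, mito_mask)
    puncta = [
        PunctumTruth(
            id=p.id,
            centroid=p.centroid,
            edge_distance_nm=rec.edge_distance_nm,
            in_contact=rec.in_contact,
        )
        for p, rec in zip(particles, records)
    ]
    image = render_channels(
        {"ev": (labels > 0).astype(float), "mitochondria": mito.astype(float)},
        pixel_size_nm=spec.pixel_size_nm,
        psf_sigma_px=spec.psf_sigma_px,
        gaussian_sd=spec.gaussian_sd,
        poisson_scaling=spec.poisson_scaling,
        seed=int(rng.integers(0, 2**31)),
    )
    truth = SyntheticGroundTruth(
        masks={"ev": labels, "mitochondria": mito},
        puncta=puncta,
        pixel_size_nm=spec.pixel_size_nm,
        extras={"spec_seed": spec.seed},
    )
    return image, truth


# ---------------------------------------------------------------------------
# Soma fields


def generate_soma_field(
    spec: SomaFieldSpec, max_retries_per_soma: int = 500
) -> tuple[CalibratedImage, SyntheticGroundTruth]:
    """Render a soma-marker + EV field with zero-inflated per-soma counts."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    px_per_um = 1000.0 / spec.pixel_size_nm
    soma_labels = np.zeros(spec.shape, dtype=np.int32)
    ellipses = []
    for soma_id in range(1, spec.n_somata + 1):
        for _ in range(max_retries_per_soma):
            a = rng.uniform(*spec.soma_semiaxis_a_um) * px_per_um
            b = rng.uniform(*spec.soma_semiaxis_b_um) * px_per_um
            ang = rng.uniform(0, np.pi)
            r0 = rng.uniform(a + 2, h - a - 2)
            c0 = rng.uniform(a + 2, w - a - 2)
            # 8 px clearance so neighboring somata never merge after PSF
            # blur and morphological closing in detection
            rr, cc = draw.ellipse(r0, c0, a + 8, b + 8, shape=spec.shape, rotation=ang)
            if soma_labels[rr, cc].any():
                continue
            rr, cc = draw.ellipse(r0, c0, a, b, shape=spec.shape, rotation=ang)
            soma_labels[rr, cc] = soma_id
            ellipses.append((r0, c0, a, b, ang))
            break
        else:
            raise GenerationError(
                f"could not place soma {soma_id} of {spec.n_somata} without overlap"
            )

    counts: dict[int, int] = {}
    puncta: list[PunctumTruth] = []
    punct_labels = np.zeros(spec.shape, dtype=np.int32)
    offs = _disk_offsets(spec.punctum_radius_px)
    margin = 3 + spec.punctum_radius_px
    min_sep = 2 * spec.punctum_radius_px + 3
    next_id = 1
    for soma_id, (r0, c0, a, b, ang) in enumerate(ellipses, start=1):
        if rng.random() < spec.positive_probability:
            k = 1 + int(rng.poisson(spec.positive_mean - 1.0))
        else:
            k = 0
        counts[soma_id] = k
        if k == 0:
            continue
        rr, cc = draw.ellipse(
            r0, c0, max(a - margin, 1), max(b - margin, 1),
            shape=spec.shape, rotation=ang,
        )
        interior = np.column_stack([rr, cc])
        chosen: list[np.ndarray] = []
        for _ in range(k):
            for _ in range(max_retries_per_soma):
                ctr = interior[rng.integers(0, len(interior))]
                if all(np.hypot(*(ctr - c)) >= min_sep for c in chosen):
                    chosen.append(ctr)
                    break
            else:
                raise GenerationError(
                    f"could not place {k} separated puncta inside soma {soma_id}"
                )
        for ctr in chosen:
            pix = ctr + offs
            punct_labels[pix[:, 0], pix[:, 1]] = next_id
            puncta.append(
                PunctumTruth(
                    id=next_id,
                    centroid=(float(ctr[0]), float(ctr[1])),
                    edge_distance_nm=None,
                    in_contact=None,
                    soma_id=soma_id,
                )
            )
            next_id += 1

    image = render_channels(
        {
            "soma_marker": (soma_labels > 0).astype(float),
            "ev": (punct_labels > 0).astype(float),
        },
        pixel_size_nm=spec.pixel_size_nm,
        psf_sigma_px=spec.psf_sigma_px,
        gaussian_sd=spec.gaussian_sd,
        poisson_scaling=spec.poisson_scaling,
        seed=int(rng.integers(0, 2**31)),
    )
    truth = SyntheticGroundTruth(
        masks={"soma_marker": soma_labels, "ev": punct_labels},
        puncta=puncta,
        pixel_size_nm=spec.pixel_size_nm,
        soma_counts=counts,
        extras={"spec_seed": spec.seed},
    )
    return image, truth


# ---------------------------------------------------------------------------
# Rendering


def render_channels(
    masks: dict[str, np.ndarray],
    pixel_size_nm: float,
    psf_sigma_px: float = 1.0,
    gaussian_sd: float = 2.0,
    poisson_scaling: float = 1.0,
    seed: int = 0,
    amplitudes: dict[str, float] | None = None,
    background: float = 2.0,
) -> CalibratedImage:
    """Truth masks → noisy fluorescence channels.

    Each channel is ``background + amplitude·mask`` convolved with a Gaussian
    PSF; Poisson shot noise is applied to intensities scaled by
    ``poisson_scaling`` (0 disables it) and Gaussian read noise of standard
    deviation ``gaussian_sd`` is added; output is clipped at zero.
    Reproducible given ``seed``.
    """
    amps = {**DEFAULT_AMPLITUDES, **(amplitudes or {})}
    rng = np.random.default_rng(seed)
    channels = {}
    for name, mask in masks.items():
        truth = background + amps.get(name, 100.0) * np.asarray(mask, dtype=float)
        img = ndi.gaussian_filter(truth, psf_sigma_px) if psf_sigma_px > 0 else truth
        if poisson_scaling > 0:
            img = rng.poisson(img * poisson_scaling).astype(float) / poisson_scaling
        if gaussian_sd > 0:
            img = img + rng.normal(0.0, gaussian_sd, size=img.shape)
        channels[name] = np.clip(img, 0.0, None)
    return CalibratedImage(channels, pixel_size_nm, source_id=f"synthetic:{seed}")


# ---------------------------------------------------------------------------
# Worked example


def worked_example_field(
    gaps_px: Sequence[int] = (1, 2, 3, 4, 5),
    pixel_size_nm: float = 31.0,
) -> tuple[ParticleSet, BinaryMask]:
    """Deterministic bar-and-puncta field with exact horizontal edge gaps.

    A solid vertical organelle bar plus one single-pixel punctum per entry
    of ``gaps_px``, each separated from the bar by exactly that many
    background pixels along its row, so the true edge distances are
    ``gap · pixel_size_nm``.
    """
    gaps = [int(g) for g in gaps_px]
    if any(g < 1 for g in gaps):
        raise InputError("gaps must be >= 1 background pixel")
    h = 4 * len(gaps) + 8
    w = max(gaps) + 16
    mito = np.zeros((h, w), dtype=bool)
    bar_right = 5
    mito[:, 2:bar_right + 1] = True
    labels = np.zeros((h, w), dtype=np.int32)
    for i, g in enumerate(gaps, start=1):
        labels[4 * i, bar_right + g + 1] = i
    particles = extract_particles(LabelMask(labels, pixel_size_nm), np.ones((h, w)))
    return particles, BinaryMask(mito, pixel_size_nm, role="mitochondria")
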