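"""EV–organelle apposition: edge distances, bins, Monte Carlo nulls, tests.

Distances are measured on the pixel grid. For a punctum P and organelle mask
M, let d_px be the minimum center-to-center distance from any pixel of P to
any pixel of M (computed via the exact Euclidean distance transform of M).
The punctum is *in contact* (edge distance 0 nm) when it overlaps M or is
8-adjacent to it (d_px ≤ √2): adjacent pixels have zero boundary separation.
Otherwise the edge-to-edge distance is (d_px − 1)·pixel_size_nm, subtracting
the one-pixel allowance for the two half-pixel boundaries.

The randomization null re-places each punctum's segmented pixel shape
rigidly (translation only) with its anchor uniform over the cellular ROI,
leaving the organelle geometry untouched; placements whose pixels leave the
ROI are rejected and redrawn. Empirical p-values use the add-one convention
p = (1 + #{null at least as extreme}) / (1 + n_iterations), one-sided toward
proximity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy import stats
from scipy.spatial import cKDTree

from .errors import AnalysisError, InputError, PlacementError
from .imaging import BinaryMask, ParticleSet

__all__ = [
    "DistanceRecord",
    "AppositionSummary",
    "BinEnrichment",
    "MonteCarloResult",
    "GroupComparison",
    "DEFAULT_THRESHOLDS_NM",
    "CONTACT_D_PX",
    "edge_to_edge_distances",
    "summarize_apposition",
    "monte_carlo_null",
    "pooled_enrichment",
    "mann_whitney",
    "fisher_exact_contact",
]

DEFAULT_THRESHOLDS_NM: tuple[float, ...] = (0.0, 100.0, 200.0, 500.0, 1000.0)

#: contact when the minimum pixel-center separation is at most √2 (8-adjacency)
CONTACT_D_PX: float = math.sqrt(2.0) + 1e-9


@dataclass
class DistanceRecord:
    """Per-punctum distances (nm) to the organelle mask."""

    particle_id: int
    edge_distance_nm: float
    centroid_distance_nm: float
    in_contact: bool


@dataclass
class AppositionSummary:
    """Cumulative apposition-bin fractions plus location summaries."""

    n_particles: int
    mean_edge_nm: float
    median_edge_nm: float
    thresholds_nm: tuple[float, ...]
    cumulative_fractions: tuple[float, ...]

    @property
    def contact_fraction(self) -> float:
        """Fraction of puncta at edge distance exactly 0 nm."""
        return self.cumulative_fractions[self.thresholds_nm.index(0.0)]


@dataclass
class BinEnrichment:
    threshold_nm: float
    observed_fraction: float
    expected_fraction: float
    fold_enrichment: float
    empirical_p: float


@dataclass
class MonteCarloResult:
    statistic_name: str
    observed: float
    null_mean: float
    null_sd: float
    n_iterations: int
    empirical_p: float
    bins: list[BinEnrichment] = field(default_factory=list)
    seed: int | None = None


@dataclass
class GroupComparison:
    test: str  # mann_whitney_u | fisher_exact
    statistic: float
    p_two_sided: float
    n1: int
    n2: int
    odds_ratio: float | None = None
    method: str | None = None


# ---------------------------------------------------------------------------
# Distances


def _distance_to_mask_px(organelle: np.ndarray) -> np.ndarray:
    """Exact EDT: each pixel's distance (px) to the nearest organelle pixel."""
    return ndi.distance_transform_edt(~organelle)


def _edge_nm(d_px: np.ndarray | float, pixel_size_nm: float):
    """Map minimum pixel-center separation to edge-to-edge nm (0 = contact)."""
    d = np.asarray(d_px, dtype=float)
    out = np.where(d <= CONTACT_D_PX, 0.0, (d - 1.0) * pixel_size_nm)
    return out if out.ndim else float(out)


def edge_to_edge_distances(
    particles: ParticleSet,
    organelle: BinaryMask,
    pixel_size_nm: float | None = None,
) -> list[DistanceRecord]:
    """Edge-to-edge and centroid distances from each punctum to the organelle.

    Edge distance follows the contact rule in the module docstring; the
    centroid distance is the Euclidean distance from the punctum centroid to
    the nearest organelle pixel center, in nm.
    """
    if organelle.n_foreground == 0:
        raise AnalysisError("organelle mask is empty; distances undefined")
    ps = pixel_size_nm if pixel_size_nm is not None else organelle.pixel_size_nm
    edt = _distance_to_mask_px(organelle.mask)
    tree = cKDTree(np.argwhere(organelle.mask))
    records = []
    for p in particles:
        if (p.coords[:, 0].max() >= organelle.shape[0]
                or p.coords[:, 1].max() >= organelle.shape[1]):
            raise InputError("particle pixels outside organelle mask geometry")
        d_px = float(edt[p.coords[:, 0], p.coords[:, 1]].min())
        edge = _edge_nm(d_px, ps)
        cdist = float(tree.query(np.asarray(p.centroid))[0]) * ps
        records.append(
            DistanceRecord(
                particle_id=p.id,
                edge_distance_nm=edge,
                centroid_distance_nm=cdist,
                in_contact=edge == 0.0,
            )
        )
    return records


def summarize_apposition(
    records: Sequence[DistanceRecord],
    thresholds_nm: Sequence[float] = DEFAULT_THRESHOLDS_NM,
) -> AppositionSummary:
    """Cumulative fractions at each threshold (≤ semantics; 0 = contact)."""
    if not records:
        raise InputError("no distance records to summarize")
    edges = np.array([r.edge_distance_nm for r in records])
    fracs = tuple(float(np.mean(edges <= t)) for t in thresholds_nm)
    return AppositionSummary(
        n_particles=len(records),
        mean_edge_nm=float(edges.mean()),
        median_edge_nm=float(np.median(edges)),
        thresholds_nm=tuple(float(t) for t in thresholds_nm),
        cumulative_fractions=fracs,
    )


# ---------------------------------------------------------------------------
# Monte Carlo randomization


def _null_edge_nm_matrix(
    particles: ParticleSet,
    edt: np.ndarray,
    roi: np.ndarray,
    n_iterations: int,
    rng: np.random.Generator,
    pixel_size_nm: float,
    max_rejections_per_placement: int = 1000,
) -> np.ndarray:
    """(n_iterations, n_particles) edge distances under random re-placement.

    Each particle's pixel shape is translated so its anchor (floor-rounded
    centroid) lands on a ROI pixel drawn uniformly; placements with any
    pixel outside the ROI are rejected and redrawn.
    """
    h, w = roi.shape
    roi_coords = np.argwhere(roi)
    if len(roi_coords) == 0:
        raise AnalysisError("ROI is empty")
    out = np.empty((n_iterations, len(particles)))
    for j, p in enumerate(particles):
        anchor = np.floor(p.centroid).astype(np.intp)
        offs = p.coords - anchor  # (m, 2)
        got = 0
        attempts = 0
        budget = max_rejections_per_placement * n_iterations + n_iterations
        d_acc = np.empty(n_iterations)
        while got < n_iterations:
            batch = min(4 * (n_iterations - got) + 16, budget - attempts)
            if batch <= 0:
                raise PlacementError(
                    f"particle {p.id}: could not place shape inside ROI "
                    f"after {attempts} attempts"
                )
            idx = rng.integers(0, len(roi_coords), size=batch)
            cand = roi_coords[idx]  # (B, 2)
            pix = cand[:, None, :] + offs[None, :, :]  # (B, m, 2)
            inb = (
                (pix[..., 0] >= 0) & (pix[..., 0] < h)
                & (pix[..., 1] >= 0) & (pix[..., 1] < w)
            ).all(axis=1)
            ok = np.zeros(batch, dtype=bool)
            if inb.any():
                sub = pix[inb]
                ok[inb] = roi[sub[..., 0], sub[..., 1]].all(axis=1)
            attempts += batch
            if ok.any():
                good = pix[ok]
                d = edt[good[..., 0], good[..., 1]].min(axis=1)
                take = min(len(d), n_iterations - got)
                d_acc[got:got + take] = d[:take]
                got += take
        out[:, j] = _edge_nm(d_acc, pixel_size_nm)
    return out


def _mc_from_matrix(
    observed_edges: np.ndarray,
    null_nm: np.ndarray,
    statistic: str,
    threshold_nm: float,
    thresholds_nm: Sequence[float],
    seed: int | None,
) -> MonteCarloResult:
    n_iterations = null_nm.shape[0]

    def frac_within(edges: np.ndarray, t: float, axis=None):
        if t == 0:
            return (edges == 0).mean(axis=axis)
        return (edges <= t).mean(axis=axis)

    if statistic == "mean_edge_distance":
        observed = float(observed_edges.mean())
        null_stat = null_nm.mean(axis=1)
        extreme = null_stat <= observed  # proximity = smaller mean
    elif statistic == "fraction_within_nm":
        observed = float(frac_within(observed_edges, threshold_nm))
        null_stat = frac_within(null_nm, threshold_nm, axis=1)
        extreme = null_stat >= observed  # proximity = larger close fraction
    else:
        raise InputError(f"unknown Monte Carlo statistic {statistic!r}")

    bins = []
    for t in thresholds_nm:
        obs_f = float(frac_within(observed_edges, t))
        null_f = frac_within(null_nm, t, axis=1)
        exp_f = float(null_f.mean())
        bins.append(
            BinEnrichment(
                threshold_nm=float(t),
                observed_fraction=obs_f,
                expected_fraction=exp_f,
                fold_enrichment=obs_f / exp_f if exp_f > 0 else float("inf"),
                empirical_p=float((1 + np.sum(null_f >= obs_f)) / (1 + n_iterations)),
            )
        )
    name = statistic if statistic == "mean_edge_distance" else (
        f"fraction_within_{threshold_nm:g}nm"
    )
    return MonteCarloResult(
        statistic_name=name,
        observed=observed,
        null_mean=float(null_stat.mean()),
        null_sd=float(null_stat.std(ddof=1)) if n_iterations > 1 else float("nan"),
        n_iterations=n_iterations,
        empirical_p=float((1 + np.sum(extreme)) / (1 + n_iterations)),
        bins=bins,
        seed=seed,
    )


def _check_particles_in_roi(particles: ParticleSet, roi: BinaryMask) -> None:
    m = roi.mask
    for p in particles:
        if not m[p.coords[:, 0], p.coords[:, 1]].all():
            raise AnalysisError(
                f"particle {p.id} lies partly outside the ROI; "
                "enlarge the ROI margin"
            )


def monte_carlo_null(
    particles: ParticleSet,
    organelle: BinaryMask,
    roi: BinaryMask,
    statistic: str = "mean_edge_distance",
    threshold_nm: float = 100.0,
    n_iterations: int = 1000,
    seed: int = 0,
    thresholds_nm: Sequence[float] = DEFAULT_THRESHOLDS_NM,
) -> MonteCarloResult:
    """Single-image randomization test of EV proximity to the organelle.

    ``statistic`` is ``mean_edge_distance`` (proximity = smaller) or
    ``fraction_within_nm`` at ``threshold_nm`` (proximity = larger). The
    result also carries observed/expected fractions and fold enrichment for
    every cumulative threshold. Bit-reproducible given ``seed``.
    """
    if n_iterations < 100:
        raise InputError("n_iterations must be >= 100")
    if len(particles) == 0:
        raise AnalysisError("no particles; Monte Carlo undefined")
    if organelle.shape != roi.shape:
        raise InputError("organelle and ROI shapes differ")
    _check_particles_in_roi(particles, roi)
    observed = np.array(
        [r.edge_distance_nm for r in edge_to_edge_distances(particles, organelle)]
    )
    edt = _distance_to_mask_px(organelle.mask)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    null_nm = _null_edge_nm_matrix(
        particles, edt, roi.mask, n_iterations, rng, organelle.pixel_size_nm
    )
    return _mc_from_matrix(observed, null_nm, statistic, threshold_nm,
                           thresholds_nm, seed)


def pooled_enrichment(
    per_image: Sequence[tuple[ParticleSet, BinaryMask, BinaryMask]],
    thresholds_nm: Sequence[float] = DEFAULT_THRESHOLDS_NM,
    n_iterations: int = 10000,
    seed: int = 0,
    statistic: str = "fraction_within_nm",
    threshold_nm: float = 100.0,
) -> MonteCarloResult:
    """Binned-distance enrichment pooled over a cohort of images.

    Observed fractions pool all particles of all images; each null iteration
    randomizes every image's particles within that image's own ROI (derived
    per-image random substreams from ``seed``) and pools the same way.
    With a single image this reduces exactly to :func:`monte_carlo_null`.
    """
    if not per_image:
        raise InputError("pooled_enrichment needs at least one image")
    if n_iterations < 100:
        raise InputError("n_iterations must be >= 100")
    seqs = np.random.SeedSequence(seed).spawn(len(per_image))
    obs_parts = []
    null_parts = []
    for (particles, organelle, roi), ss in zip(per_image, seqs):
        if len(particles) == 0:
            raise AnalysisError("an image has no particles")
        _check_particles_in_roi(particles, roi)
        obs_parts.append(
            [r.edge_distance_nm for r in edge_to_edge_distances(particles, organelle)]
        )
        edt = _distance_to_mask_px(organelle.mask)
        null_parts.append(
            _null_edge_nm_matrix(
                particles, edt, roi.mask, n_iterations,
                np.random.default_rng(ss), organelle.pixel_size_nm,
            )
        )
    observed = np.concatenate([np.asarray(o) for o in obs_parts])
    null_nm = np.hstack(null_parts)
    return _mc_from_matrix(observed, null_nm, statistic, threshold_nm,
                           thresholds_nm, seed)


# ---------------------------------------------------------------------------
# Group comparisons


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> GroupComparison:
    """Two-sided Mann-Whitney U.

    Exact enumeration when n₁·n₂ ≤ 400 and the pooled sample has no ties;
    otherwise the normal approximation with mid-rank tie correction and
    continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InputError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) * len(b) <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return GroupComparison(
        test="mann_whitney_u",
        statistic=float(res.statistic),
        p_two_sided=float(min(res.pvalue, 1.0)),
        n1=len(a),
        n2=len(b),
        method=method,
    )


def fisher_exact_contact(
    contact_a: int, n_a: int, contact_b: int, n_b: int
) -> GroupComparison:
    """Two-sided Fisher's exact test on contact counts of two conditions."""
    for contact, n, name in ((contact_a, n_a, "A"), (contact_b, n_b, "B")):
        if n <= 0:
            raise InputError(f"group {name} has no particles (n = {n})")
        if not 0 <= contact <= n:
            raise InputError(f"group {name}: contact count outside [0, n]")
    table = [[contact_a, n_a - contact_a], [contact_b, n_b - contact_b]]
    res = stats.fisher_exact(table, alternative="two-sided")
    return GroupComparison(
        test="fisher_exact",
        statistic=float(res.statistic),
        p_two_sided=float(res.pvalue),
        n1=n_a,
        n2=n_b,
        odds_ratio=float(res.statistic),
    )
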