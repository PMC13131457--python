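"""End-to-end pipelines: detection → assignment → statistics.

The in-memory entry points (:func:`run_soma_quant`, :func:`run_apposition`)
operate on lists of :class:`~evquant.imaging.CalibratedImage` so they can be
driven identically by the CLI (reading TIFFs) and by the synthetic
generator. Every numeric output is a pure function of the images, the
parameter dataclasses and the master seed; per-image Monte Carlo seeds are
derived deterministically from the master seed and the image index.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import apposition as appo
from . import quantification as quant
from .errors import AnalysisError, DegenerateThresholdError
from .imaging import (
    BinaryMask,
    CalibratedImage,
    LabelMask,
    ParticleSet,
    extract_particles,
    label_connected,
    project_z,
)
from .segmentation import (
    SizeShapeFilter,
    ThresholdSpec,
    define_cell_roi,
    detect_somata,
    filter_particles,
    threshold_channel,
)
from .shape_stats import bimodality_coefficient, select_mixture_model

__all__ = [
    "SomaPipelineParams",
    "SomaPipelineResult",
    "AppositionParams",
    "AppositionPipelineResult",
    "run_soma_quant",
    "run_apposition",
    "to_jsonable",
]


def _derived_seed(master: int, index: int) -> int:
    # deterministic per-image substream, kept below 2**31
    return int((master * 1_000_003 + 7919 * index + 1) % (2**31))


@dataclass(frozen=True)
class SomaPipelineParams:
    soma_channel: str = "soma_marker"
    ev_channel: str = "ev"
    soma_threshold: ThresholdSpec = ThresholdSpec(method="otsu", pre_smooth_sigma_px=2.0)
    ev_threshold: ThresholdSpec = ThresholdSpec(method="otsu", pre_smooth_sigma_px=1.0)
    size_filter: SizeShapeFilter = SizeShapeFilter()
    min_soma_area_um2: float = 50.0
    soma_morph_radius_px: int = 2
    fill_holes: bool = True
    selection: Optional[Sequence[int]] = None  # per-image manual include-list
    allow_empty_ev: bool = True  # constant EV channel → zero detections


@dataclass
class SomaPipelineResult:
    per_soma: pd.DataFrame  # image_index, soma_id, area, count, density
    mean_count: float
    sem_count: float
    fraction_of_somata_with_particles: float
    count_vs_area: quant.CorrelationResult | None
    density_vs_area: quant.CorrelationResult | None
    run_log: list[dict]

    @property
    def n_somata(self) -> int:
        return len(self.per_soma)


def _detect_puncta(
    image: CalibratedImage,
    channel: str,
    spec: ThresholdSpec,
    size_filter: SizeShapeFilter,
    allow_empty: bool,
) -> tuple[ParticleSet, BinaryMask]:
    mask = threshold_channel(image, channel, spec, role="particle",
                             allow_degenerate=allow_empty)
    labels = label_connected(mask, connectivity=8)
    particles = extract_particles(labels, image.channel(channel))
    return filter_particles(particles, size_filter), mask


def run_soma_quant(
    images: Sequence[CalibratedImage],
    params: SomaPipelineParams = SomaPipelineParams(),
) -> SomaPipelineResult:
    """Per-soma punctum counting pooled over a cohort of images.

    Per image: detect somata from the marker channel, detect and filter EV
    puncta, assign puncta to somata by centroid, then pool per-soma rows.
    Dataset statistics (mean ± SEM count, positive fraction) and the two
    soma-size correlations (count vs area, density vs area) are computed
    over all somata of all images.
    """
    rows = []
    log = []
    for i, img in enumerate(images):
        if img.is_stack:
            img = project_z(img)
        somata = detect_somata(
            img,
            params.soma_channel,
            params.soma_threshold,
            min_soma_area_um2=params.min_soma_area_um2,
            fill_holes=params.fill_holes,
            selection=params.selection,
            morph_radius_px=params.soma_morph_radius_px,
        )
        if somata.n_labels == 0:
            raise AnalysisError(f"image {i}: no somata detected/selected")
        particles, ev_mask = _detect_puncta(
            img, params.ev_channel, params.ev_threshold,
            params.size_filter, params.allow_empty_ev,
        )
        assignment = quant.assign_particles_to_somata(particles, somata)
        res = quant.summarize_somata(assignment, somata)
        df = res.per_soma.copy()
        df.insert(0, "image_index", i)
        rows.append(df)
        log.append(
            {
                "stage": "soma_quant",
                "image_index": i,
                "source_id": img.source_id,
                "n_somata": somata.n_labels,
                "n_particles_detected": len(particles),
                "ev_threshold": ev_mask.meta.get("threshold"),
            }
        )
    pooled = pd.concat(rows, ignore_index=True)
    counts = pooled["particle_count"].to_numpy()
    areas = pooled["soma_area_um2"].to_numpy()
    dens = pooled["particle_density_per_um2"].to_numpy()
    n = len(pooled)

    def _corr(x, y):
        try:
            return quant.pearson_correlation(x, y)
        except Exception:
            return None

    return SomaPipelineResult(
        per_soma=pooled,
        mean_count=float(counts.mean()),
        sem_count=float(np.std(counts, ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        fraction_of_somata_with_particles=float((counts > 0).mean()),
        count_vs_area=_corr(counts.astype(float), areas),
        density_vs_area=_corr(dens, areas),
        run_log=log,
    )


# ---------------------------------------------------------------------------
# Apposition pipeline


@dataclass(frozen=True)
class AppositionParams:
    ev_channel: str = "ev"
    mito_channel: str = "mitochondria"
    ev_threshold: ThresholdSpec = ThresholdSpec(method="otsu", pre_smooth_sigma_px=1.0)
    mito_threshold: ThresholdSpec = ThresholdSpec(method="otsu", pre_smooth_sigma_px=1.0)
    size_filter: SizeShapeFilter = SizeShapeFilter()
    roi_strategy: str = "hull_of_structures"
    roi_margin_px: int = 20
    iterations_per_image: int = 1000
    pooled_iterations: int = 10000
    thresholds_nm: tuple[float, ...] = appo.DEFAULT_THRESHOLDS_NM
    statistic: str = "mean_edge_distance"
    statistic_threshold_nm: float = 100.0


@dataclass
class ConditionResult:
    condition: str
    per_image_summaries: list[appo.AppositionSummary]
    per_image_mc: list[appo.MonteCarloResult]
    pooled: appo.MonteCarloResult
    edge_distances_nm: np.ndarray
    contact_count: int
    n_particles: int
    bimodality: object | None
    mixture: object | None


@dataclass
class AppositionPipelineResult:
    conditions: dict[str, ConditionResult]
    mann_whitney: appo.GroupComparison | None
    fisher_contact: appo.GroupComparison | None
    run_log: list[dict]
    seed: int


def run_apposition(
    images_by_condition: dict[str, Sequence[CalibratedImage]],
    params: AppositionParams = AppositionParams(),
    seed: int = 0,
) -> AppositionPipelineResult:
    """EV–mitochondria apposition analysis over one or two conditions.

    Per image: segment both channels, compute edge distances, summarize
    cumulative bins, run the per-image randomization test. Per condition:
    pooled enrichment over all images, bimodality coefficient and 1- vs
    2-component mixture selection on the pooled distances. With exactly two
    conditions, Mann-Whitney on pooled distances and Fisher's exact test on
    contact counts compare them.
    """
    conditions: dict[str, ConditionResult] = {}
    log: list[dict] = []
    img_counter = 0
    for cond, images in images_by_condition.items():
        per_image = []
        summaries = []
        mcs = []
        distances = []
        for img in images:
            if img.is_stack:
                img = project_z(img)
            mito = threshold_channel(img, params.mito_channel, params.mito_threshold,
                                     role="mitochondria")
            particles, ev_mask = _detect_puncta(
                img, params.ev_channel, params.ev_threshold, params.size_filter,
                allow_empty=False,
            )
            if len(particles) == 0:
                raise AnalysisError(
                    f"condition {cond!r}: an image has no puncta after filtering"
                )
            roi = define_cell_roi(
                params.roi_strategy,
                image=img,
                mitochondria=mito,
                particles=ev_mask,
                margin_px=params.roi_margin_px,
            )
            records = appo.edge_to_edge_distances(particles, mito)
            summaries.append(
                appo.summarize_apposition(records, params.thresholds_nm)
            )
            mc = appo.monte_carlo_null(
                particles, mito, roi,
                statistic=params.statistic,
                threshold_nm=params.statistic_threshold_nm,
                n_iterations=params.iterations_per_image,
                seed=_derived_seed(seed, img_counter),
                thresholds_nm=params.thresholds_nm,
            )
            mcs.append(mc)
            per_image.append((particles, mito, roi))
            distances.append([r.edge_distance_nm for r in records])
            log.append(
                {
                    "stage": "apposition",
                    "condition": cond,
                    "image_index": img_counter,
                    "source_id": img.source_id,
                    "n_particles": len(particles),
                    "ev_threshold": ev_mask.meta.get("threshold"),
                    "mito_threshold": mito.meta.get("threshold"),
                    "mc_seed": _derived_seed(seed, img_counter),
                }
            )
            img_counter += 1
        pooled = appo.pooled_enrichment(
            per_image,
            thresholds_nm=params.thresholds_nm,
            n_iterations=params.pooled_iterations,
            seed=_derived_seed(seed, 10_000 + len(conditions)),
            statistic="fraction_within_nm",
            threshold_nm=params.statistic_threshold_nm,
        )
        edges = np.concatenate([np.asarray(d) for d in distances])
        bim = bimodality_coefficient(edges) if len(edges) >= 4 and edges.std() > 0 else None
        mix = (
            select_mixture_model(edges, seed=_derived_seed(seed, 20_000 + len(conditions)))
            if len(edges) >= 20
            else None
        )
        conditions[cond] = ConditionResult(
            condition=cond,
            per_image_summaries=summaries,
            per_image_mc=mcs,
            pooled=pooled,
            edge_distances_nm=edges,
            contact_count=int((edges == 0).sum()),
            n_particles=len(edges),
            bimodality=bim,
            mixture=mix,
        )

    mw = fisher = None
    if len(conditions) == 2:
        (ca, cb) = conditions.values()
        mw = appo.mann_whitney(ca.edge_distances_nm, cb.edge_distances_nm)
        fisher = appo.fisher_exact_contact(
            ca.contact_count, ca.n_particles, cb.contact_count, cb.n_particles
        )
    return AppositionPipelineResult(
        conditions=conditions,
        mann_whitney=mw,
        fisher_contact=fisher,
        run_log=log,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Serialization


def to_jsonable(obj):
    """Recursively convert dataclasses / numpy objects to JSON-safe types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        if np.isnan(v):
            return None
        if np.isinf(v):
            return "inf" if v > 0 else "-inf"
        return v
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj
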