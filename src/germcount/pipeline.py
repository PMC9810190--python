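"""End-to-end orchestration: segmentation -> counting -> germ detection.

``run_pipeline`` chains the four stages on one RGB image and returns a
:class:`PipelineResult` with the germination report and every
intermediate product (masks, the refinement threshold, the area curve,
the optimal single-grain area).  All thresholds live in
:class:`PipelineConfig`, whose defaults are the method's stated
constants; the whole pipeline is deterministic, so two runs on the
same image produce identical results.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import coarse, counting, germs
from .refine import (
    RefinementResult,
    fit_quintic,
    find_threshold,
    gaussian_smooth_histogram,
    red_histogram,
    refine as apply_refinement,
)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "PipelineStageError",
    "EvalMetrics",
    "run_pipeline",
    "evaluate",
    "report_to_dict",
]

logger = logging.getLogger("germcount")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable thresholds of the pipeline (defaults = method constants)."""

    # coarse segmentation
    clip_delta: int = 60
    clip_value: int = 30
    kmeans_centers: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 0.0), (40.0, 40.0))
    kmeans_max_iter: int = 100

    # refinement
    hist_filter_size: int = 100
    hist_filter_sigma: float = 7.5
    per_region_threshold: bool = False

    # grain counting
    connectivity: int = 8
    curve_smooth_len: int = 3
    curve_smooth_sigma: float = 0.65
    ratio_threshold: float = 1.2
    fraction_threshold: float = 0.4
    point_b_convention: str = "stable"   # or "jump"
    condition7_on_smoothed: bool = False
    exclude_noise_regions: bool = False

    # germ detection
    gray_threshold: int = 160
    area_lo_divisor: float = 50.0
    area_hi_divisor: float = 3.0
    lp_ratio_max: float = 0.4
    adjacency_excludes_noise: bool = False

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        """Build a config from a flat key/value mapping (e.g. parsed TOML)."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        coerced = {}
        for key, value in mapping.items():
            if key == "kmeans_centers":
                value = tuple(tuple(float(v) for v in c) for c in value)
            elif isinstance(value, list):
                value = tuple(value)
            coerced[key] = value
        return cls(**coerced)


@dataclass
class PipelineResult:
    """Germination report plus every intermediate pipeline product."""

    report: germs.GerminationReport
    coarse_mask: np.ndarray
    grain_mask: np.ndarray
    refinement: RefinementResult
    regions: counting.RegionTable
    curve: counting.AreaCurve | None
    counts: counting.GrainCountResult | None

    @property
    def n_grains(self) -> int:
        return self.report.n_grain

    @property
    def n_germinated(self) -> int:
        return self.report.n_bud

    @property
    def germination_rate(self) -> float | None:
        return self.report.germination_rate

    @property
    def s_opt(self) -> int | None:
        return self.counts.s_opt if self.counts is not None else None


@dataclass(frozen=True)
class EvalMetrics:
    """Absolute error |A - B| and relative error |A - B|/A x 100%.

    ``A`` is the true value, ``B`` the prediction.  The relative error
    is undefined (``None``, flagged) when the truth is zero.
    """

    absolute_error: float
    relative_error_pct: float | None
    relative_defined: bool


def _empty_result(img: np.ndarray, coarse_mask: np.ndarray, mask: np.ndarray,
                  res: RefinementResult) -> PipelineResult:
    report = germs.GerminationReport(
        n_grain=0, n_bud=0, germination_rate=None, rate_defined=False
    )
    return PipelineResult(
        report=report,
        coarse_mask=coarse_mask,
        grain_mask=mask,
        refinement=res,
        regions=counting.RegionTable(
            np.zeros(img.shape[:2], dtype=np.int32),
            np.empty(0, int), np.empty(0, int), [],
        ),
        curve=None,
        counts=None,
    )


def run_pipeline(img: np.ndarray, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full germination-rate assessment on one RGB image.

    An image with no detectable grains yields a zero-grain report with
    an undefined (flagged) germination rate rather than an error.
    """
    config = config or PipelineConfig()
    img = np.asarray(img)
    t0 = time.perf_counter()

    try:
        coarse_mask = coarse.coarse_segment(
            img,
            clip_delta=config.clip_delta,
            clip_value=config.clip_value,
            centers=config.kmeans_centers,
            max_iter=config.kmeans_max_iter,
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineStageError("coarse_segmentation", exc) from exc
    logger.info("coarse segmentation: %d foreground px (%.2fs)",
                int(coarse_mask.sum()), time.perf_counter() - t0)

    no_threshold = RefinementResult(threshold_d=None)
    if not coarse_mask.any():
        return _empty_result(img, coarse_mask, coarse_mask.copy(), no_threshold)

    try:
        if config.per_region_threshold:
            mask, res = _refine_per_region(img, coarse_mask, config)
        else:
            hist = red_histogram(img, coarse_mask)
            smoothed = gaussian_smooth_histogram(
                hist, size=config.hist_filter_size, sigma=config.hist_filter_sigma
            )
            res = find_threshold(fit_quintic(smoothed))
            mask = apply_refinement(img, coarse_mask, res)
    except Exception as exc:
        raise PipelineStageError("refinement_segmentation", exc) from exc
    logger.info("refinement: threshold d=%s, %d foreground px",
                res.threshold_d, int(mask.sum()))

    if not mask.any():
        return _empty_result(img, coarse_mask, mask, res)

    try:
        table = counting.label_regions(mask, connectivity=config.connectivity)
        curve = counting.build_area_curve(
            table, smooth_len=config.curve_smooth_len,
            smooth_sigma=config.curve_smooth_sigma,
        )
        index_a = counting.find_point_a(curve)
        index_b = counting.find_point_b(
            curve, index_a,
            ratio_threshold=config.ratio_threshold,
            convention=config.point_b_convention,
            on_smoothed=config.condition7_on_smoothed,
        )
        curve.index_a, curve.index_b = index_a, index_b
        s_opt = counting.optimal_grain_area(curve.areas[index_a : index_b + 1])
        counts = counting.count_grains(
            curve, table, s_opt,
            fraction_threshold=config.fraction_threshold,
            index_a=index_a,
            exclude_noise_regions=config.exclude_noise_regions,
        )
    except Exception as exc:
        raise PipelineStageError("grain_counting", exc) from exc
    logger.info("counting: m=%d regions, s_opt=%d, n_grain=%d",
                len(table), counts.s_opt, counts.n_grain)

    try:
        gmask = germs.germ_mask(img, mask, gray_threshold=config.gray_threshold)
        germ_labels, cands = germs.extract_candidates(gmask)
        cands = germs.filter_by_area(
            cands, counts.s_opt,
            area_lo_divisor=config.area_lo_divisor,
            area_hi_divisor=config.area_hi_divisor,
        )
        if config.adjacency_excludes_noise and counts.noise_labels:
            grain_for_contact = np.isin(
                table.label_image, sorted(set(map(int, table.labels)) - counts.noise_labels)
            ) & mask
        else:
            grain_for_contact = mask
        cands = germs.measure_candidates(
            germ_labels, cands, grain_for_contact, table.label_image
        )
        report = germs.count_germinated(
            cands, counts.n_grain, ratio_max=config.lp_ratio_max
        )
    except Exception as exc:
        raise PipelineStageError("germ_detection", exc) from exc
    logger.info("germs: %d candidates, n_bud=%d, rate=%s (total %.2fs)",
                len(report.candidates), report.n_bud,
                report.germination_rate, time.perf_counter() - t0)

    return PipelineResult(
        report=report,
        coarse_mask=coarse_mask,
        grain_mask=mask,
        refinement=res,
        regions=table,
        curve=curve,
        counts=counts,
    )


def _refine_per_region(img, coarse_mask, config):
    """Optional per-region refinement: one valley threshold per region."""
    table = counting.label_regions(coarse_mask, connectivity=config.connectivity)
    mask = coarse_mask.copy()
    last = RefinementResult(threshold_d=None)
    for lab in table.labels:
        region = table.label_image == lab
        hist = red_histogram(img, region)
        smoothed = gaussian_smooth_histogram(
            hist, size=config.hist_filter_size, sigma=config.hist_filter_sigma
        )
        res = find_threshold(fit_quintic(smoothed))
        mask &= ~region | apply_refinement(img, region, res)
        if res.threshold_d is not None:
            last = res
    return mask, last


def evaluate(truth: float, predicted: float) -> EvalMetrics:
    """Absolute and relative error of a prediction against the truth."""
    abs_err = abs(truth - predicted)
    if truth == 0:
        return EvalMetrics(abs_err, None, False)
    return EvalMetrics(abs_err, abs_err / truth * 100.0, True)


def report_to_dict(result: PipelineResult) -> dict:
    """JSON-serialisable report mirroring the documented schema."""
    curve = result.curve
    counts = result.counts
    regions = []
    if counts is not None:
        for lab, area in zip(result.regions.labels, result.regions.areas):
            regions.append(
                {
                    "label": int(lab),
                    "area": int(area),
                    "count": counts.per_region_counts[int(lab)],
                    "is_noise": int(lab) in counts.noise_labels,
                }
            )
    germs_out = [
        {
            "label": c.label,
            "area": c.area,
            "perimeter": c.perimeter,
            "intersection_length": c.intersection_length,
            "lp_ratio": c.lp_ratio,
            "accepted": c.accepted,
            "reason": c.reason,
        }
        for c in result.report.candidates
    ]
    rate = result.germination_rate
    return {
        "n_grains": result.n_grains,
        "n_germinated": result.n_germinated,
        "germination_rate": rate,
        "germination_rate_pct": None if rate is None else 100.0 * rate,
        "rate_defined": result.report.rate_defined,
        "s_opt": result.s_opt,
        "s_A": None if curve is None or curve.index_a is None else curve.s_a,
        "s_B": None if curve is None or curve.index_b is None else curve.s_b,
        "threshold_d": result.refinement.threshold_d,
        "regions": regions,
        "germs": germs_out,
    }
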