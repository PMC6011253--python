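"""End-to-end segmentation pipeline.

Stage order: grayscale conversion -> histogram -> progressive-weighted-mean
curve -> polynomial fit -> inflection-point candidates -> initial threshold
by maximum median area -> area classification, small-object deletion and
big-object splitting -> solidity-adaptive marker watershed -> final
small-object erase.  Deterministic for a fixed input and config.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import area as _area
from . import pwm as _pwm
from . import separation as _sep
from .config import PipelineConfig

__all__ = ["SegmentationResult", "run_pipeline"]


@dataclass
class SegmentationResult:
    """Everything the pipeline produced for one image."""

    mask: np.ndarray
    initial_threshold: int | None
    candidates: list[int]
    stage_counts: dict[str, int]
    records: list[_area.RegionRecord]
    warnings: list[str] = field(default_factory=list)
    config: PipelineConfig | None = None
    histogram: _pwm.GrayHistogram | None = None
    curve: _pwm.PWMCurve | None = None

    @property
    def n_objects(self) -> int:
        return int(self.mask.max())


def run_pipeline(rgb_image: np.ndarray, config: PipelineConfig | None = None) -> SegmentationResult:
    """Segment nuclei in an 8-bit RGB (or grayscale) histology image."""
    if config is None:
        config = PipelineConfig()
    conn = config.skimage_connectivity
    cmp = config.threshold_comparison
    caught: list[str] = []

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        gray = _pwm.to_grayscale(rgb_image)
        hist = _pwm.compute_histogram(gray)
        curve = None
        candidates = _pwm.CandidateThresholds()
        try:
            curve = _pwm.compute_pwm_curve(hist)
            curve = _pwm.fit_pwm_polynomial(curve, order=config.poly_order)
            candidates = _pwm.find_inflection_points(curve)
        except ValueError as exc:  # constant image and similar degeneracies
            caught.append(str(exc))
        t0, mask0 = _pwm.select_initial_threshold(
            gray, candidates, connectivity=conn, comparison=cmp
        )
        stage_counts = {"initial": int(mask0.max())}

        mean_total, records = _area.classify_by_area(
            mask0, small_factor=config.small_factor, big_factor=config.big_factor
        )
        mask1 = _area.delete_small(mask0, records)
        stage_counts["after_delete_small"] = int(mask1.max())
        if records:
            # classes must be looked up on the relabeled mask: recompute on mask1
            _, records1 = _area.classify_by_area(
                mask1, small_factor=config.small_factor, big_factor=config.big_factor
            )
            # size classes are still measured against the pre-correction mean
            for r in records1:
                if r.area < config.small_factor * mean_total:
                    r.size_class = "small"
                elif r.area > config.big_factor * mean_total:
                    r.size_class = "big"
                else:
                    r.size_class = "normal"
            mask2, _ = _area.split_big(
                gray,
                mask1,
                t0,
                mean_total,
                records1,
                big_factor=config.big_factor,
                step=config.split_step,
                connectivity=conn,
                comparison=cmp,
            )
        else:
            mask2 = mask1
        stage_counts["after_split_big"] = int(mask2.max())

        mask3 = _sep.separate_all(
            mask2,
            solidity_cutoff=config.solidity_cutoff,
            h_fraction_low=config.h_fraction_low,
            h_fraction_high=config.h_fraction_high,
            connectivity=conn,
        )
        stage_counts["after_watershed"] = int(mask3.max())

        mask4 = _sep.final_small_filter(mask3, small_factor=config.small_factor)
        stage_counts["final"] = int(mask4.max())
        stage_counts["erased_by_final_filter"] = (
            stage_counts["after_watershed"] - stage_counts["final"]
        )

        _, final_records = _area.classify_by_area(
            mask4, small_factor=config.small_factor, big_factor=config.big_factor
        )
        caught.extend(str(w.message) for w in wlist)

    if stage_counts["final"] == 0:
        caught.append("no nuclei detected (blank or degenerate image?)")

    return SegmentationResult(
        mask=mask4,
        initial_threshold=int(t0),
        candidates=list(candidates.levels),
        stage_counts=stage_counts,
        records=final_records,
        warnings=caught,
        config=config,
        histogram=hist,
        curve=curve,
    )
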