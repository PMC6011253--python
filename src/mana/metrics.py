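"""Object-level and per-nucleus evaluation against point annotations.

Ground truth is a list of manually marked nucleus centers.  A center is
matched when it falls on a nonzero label of the segmentation mask.  At
object level, recall = TP/(TP+FN), precision = TP/(TP+FP) and F1 is their
harmonic mean, where FP counts *ghost* regions containing no center.  Each
ground-truth nucleus is also classified as correctly segmented (CS: alone
in its region), under-segmented (US: sharing a region with another
center), or a segmentation error (SE: in no region); the three classes
partition the ground truth, and their rates are reported as percentages
of N_GT.

Note F1 deliberately penalizes only object-level errors: with the default
per-center convention every matched center is a true positive, so
under-segmentation lowers the CS rate but not F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ManualAnnotation",
    "EvaluationResult",
    "match_detections",
    "object_level_metrics",
    "pixel_level_rates",
    "evaluate",
    "read_centers_csv",
    "write_centers_csv",
]


@dataclass
class ManualAnnotation:
    """Point annotation: one (row, col) center per nucleus, 0-based."""

    centers: np.ndarray  # shape (n, 2), float or int
    image_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64).reshape(-1, 2)
        if self.image_shape is not None and self.n_gt:
            rows, cols = self.centers[:, 0], self.centers[:, 1]
            h, w = self.image_shape
            if (rows < 0).any() or (cols < 0).any() or (rows >= h).any() or (cols >= w).any():
                raise ValueError("annotation centers fall outside the image bounds")

    @property
    def n_gt(self) -> int:
        return int(self.centers.shape[0])


@dataclass
class EvaluationResult:
    """Counts, rates and per-center / per-region classifications."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    n_cs: int = 0
    n_us: int = 0
    n_se: int = 0
    n_gt: int = 0
    recall: float = float("nan")
    precision: float = float("nan")
    f1: float = float("nan")
    cs_rate: float = float("nan")
    us_rate: float = float("nan")
    se_rate: float = float("nan")
    per_center_class: list[str] = field(default_factory=list)
    per_region_status: dict[int, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "cs_rate": self.cs_rate,
            "us_rate": self.us_rate,
            "se_rate": self.se_rate,
            "n_gt": self.n_gt,
        }


def match_detections(
    annotation: ManualAnnotation,
    mask: np.ndarray,
    *,
    tp_convention: str = "per_center",
    match_tolerance_px: float = 0.0,
) -> EvaluationResult:
    """Match annotated centers to mask regions and fill in all counts.

    A center matches the region whose label its (rounded) pixel carries;
    with ``match_tolerance_px > 0`` a center on background is snapped to
    the nearest labeled pixel within that radius.  TP/FN/FP follow the
    chosen convention; CS/US/SE classify each ground-truth center by how
    many centers share its region.
    """
    mask = np.asarray(mask)
    if annotation.image_shape is not None and tuple(annotation.image_shape) != mask.shape:
        raise ValueError(
            f"annotation frame {annotation.image_shape} does not match "
            f"mask shape {mask.shape}"
        )
    centers = annotation.centers
    n_gt = annotation.n_gt
    labels_at_centers = np.zeros(n_gt, dtype=np.int64)
    for i, (r, c) in enumerate(centers):
        ri, ci = int(np.floor(r + 0.5)), int(np.floor(c + 0.5))
        if not (0 <= ri < mask.shape[0] and 0 <= ci < mask.shape[1]):
            raise ValueError(f"center {i} at ({r}, {c}) is outside the mask")
        lab = int(mask[ri, ci])
        if lab == 0 and match_tolerance_px > 0:
            lab = _nearest_label(mask, ri, ci, match_tolerance_px)
        labels_at_centers[i] = lab

    matched = labels_at_centers > 0
    occupied, counts_per_region = np.unique(
        labels_at_centers[matched], return_counts=True
    )
    centers_in_region = dict(zip(occupied.tolist(), counts_per_region.tolist()))

    per_center = []
    for lab in labels_at_centers:
        if lab == 0:
            per_center.append("SE")
        elif centers_in_region[int(lab)] == 1:
            per_center.append("CS")
        else:
            per_center.append("US")

    all_labels = np.unique(mask)
    all_labels = all_labels[all_labels > 0]
    per_region = {
        int(lab): ("matched" if int(lab) in centers_in_region else "ghost")
        for lab in all_labels
    }
    fp = sum(1 for s in per_region.values() if s == "ghost")

    if tp_convention == "per_center":
        tp = int(matched.sum())
        fn = n_gt - tp
    elif tp_convention == "per_region":
        tp = len(centers_in_region)
        fn = n_gt - int(matched.sum())
    else:
        raise ValueError(f"unknown tp_convention {tp_convention!r}")

    result = EvaluationResult(
        tp=tp,
        fp=fp,
        fn=fn,
        n_cs=per_center.count("CS"),
        n_us=per_center.count("US"),
        n_se=per_center.count("SE"),
        n_gt=n_gt,
        per_center_class=per_center,
        per_region_status=per_region,
    )
    return result


def _nearest_label(mask: np.ndarray, r: int, c: int, tol: float) -> int:
    """Label of the nearest labeled pixel within tol of (r, c), else 0."""
    rad = int(np.ceil(tol))
    r0, r1 = max(r - rad, 0), min(r + rad + 1, mask.shape[0])
    c0, c1 = max(c - rad, 0), min(c + rad + 1, mask.shape[1])
    win = mask[r0:r1, c0:c1]
    rr, cc = np.nonzero(win)
    if rr.size == 0:
        return 0
    d2 = (rr + r0 - r) ** 2 + (cc + c0 - c) ** 2
    best = np.argmin(d2)
    if d2[best] > tol * tol:
        return 0
    return int(win[rr[best], cc[best]])


def object_level_metrics(result: EvaluationResult) -> tuple[float, float, float]:
    """Recall, precision and F1 from the matched counts (also stored on result)."""
    if result.tp + result.fn == 0:
        raise ValueError("no ground-truth nuclei: recall is undefined")
    recall = result.tp / (result.tp + result.fn)
    if result.tp + result.fp == 0:
        import warnings

        warnings.warn("no detections at all; precision defined as 0", stacklevel=2)
        precision = 0.0
    else:
        precision = result.tp / (result.tp + result.fp)
    f1 = 0.0 if recall + precision == 0 else 2 * recall * precision / (recall + precision)
    result.recall, result.precision, result.f1 = recall, precision, f1
    return recall, precision, f1


def pixel_level_rates(result: EvaluationResult) -> tuple[float, float, float]:
    """CS/US/SE rates as percentages of N_GT (they sum to 100 exactly)."""
    if result.n_gt == 0:
        raise ValueError("no ground-truth nuclei: rates are undefined")
    if result.n_cs + result.n_us + result.n_se != result.n_gt:
        raise AssertionError("CS/US/SE do not partition the ground truth")
    cs = 100.0 * result.n_cs / result.n_gt
    us = 100.0 * result.n_us / result.n_gt
    se = 100.0 * result.n_se / result.n_gt
    result.cs_rate, result.us_rate, result.se_rate = cs, us, se
    return cs, us, se


def evaluate(
    annotation: ManualAnnotation,
    mask: np.ndarray,
    *,
    tp_convention: str = "per_center",
    match_tolerance_px: float = 0.0,
) -> EvaluationResult:
    """Full evaluation: matching plus object-level and per-nucleus rates."""
    result = match_detections(
        annotation,
        mask,
        tp_convention=tp_convention,
        match_tolerance_px=match_tolerance_px,
    )
    object_level_metrics(result)
    pixel_level_rates(result)
    return result


def read_centers_csv(path: str, image_shape: tuple[int, int] | None = None) -> ManualAnnotation:
    """Read a centers CSV with mandatory header ``row,col`` (0-based)."""
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["row", "col"]:
        raise ValueError(f"{path}: expected header 'row,col', got {list(df.columns)}")
    return ManualAnnotation(df[["row", "col"]].to_numpy(), image_shape=image_shape)


def write_centers_csv(path: str, centers: np.ndarray) -> None:
    pd.DataFrame(np.asarray(centers).reshape(-1, 2), columns=["row", "col"]).to_csv(
        path, index=False
    )
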