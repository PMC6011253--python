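"""File I/O: images, label masks, overlays, diagnostics, reports.

Conventions used in every file this module writes: 0-based (row, col)
coordinates, half-open bounding boxes, label 0 = background.
"""

from __future__ import annotations

import json
import os

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from skimage.segmentation import find_boundaries

from .pipeline import SegmentationResult

__all__ = [
    "read_image",
    "write_label_tiff",
    "read_label_tiff",
    "make_overlay",
    "write_outputs",
    "write_diagnostics",
]


def read_image(path: str) -> np.ndarray:
    """Read an 8-bit RGB (or RGBA/grayscale) image; RGBA is flattened to RGB."""
    img = iio.imread(path)
    if img.dtype != np.uint8:
        raise ValueError(f"{path}: only 8-bit images are supported, got {img.dtype}")
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[..., :3]
    return img


def write_label_tiff(path: str, mask: np.ndarray) -> None:
    """Write a label mask as 16-bit TIFF (lossless round-trip)."""
    mask = np.asarray(mask)
    if mask.max() > np.iinfo(np.uint16).max:
        raise ValueError(f"more than {np.iinfo(np.uint16).max} labels; cannot store as 16-bit")
    tifffile.imwrite(path, mask.astype(np.uint16))


def read_label_tiff(path: str) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def make_overlay(rgb_image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Input image with 1-px green contours on every object boundary."""
    rgb_image = np.asarray(rgb_image)
    if rgb_image.ndim == 2:
        rgb_image = np.stack([rgb_image] * 3, axis=-1)
    overlay = rgb_image.copy()
    boundary = find_boundaries(mask, mode="inner")
    overlay[boundary] = (0, 255, 0)
    return overlay


def write_outputs(result: SegmentationResult, out_dir: str, rgb_image: np.ndarray) -> dict[str, str]:
    """Write mask.tif, overlay.png, centroids.csv and report.json.

    Returns the mapping of artifact name to path.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "mask": os.path.join(out_dir, "mask.tif"),
        "overlay": os.path.join(out_dir, "overlay.png"),
        "centroids": os.path.join(out_dir, "centroids.csv"),
        "report": os.path.join(out_dir, "report.json"),
    }
    write_label_tiff(paths["mask"], result.mask)
    iio.imwrite(paths["overlay"], make_overlay(rgb_image, result.mask))
    rows = [
        {
            "label": r.label,
            "row": r.centroid[0],
            "col": r.centroid[1],
            "area": r.area,
            "solidity": r.solidity,
        }
        for r in result.records
    ]
    pd.DataFrame(rows, columns=["label", "row", "col", "area", "solidity"]).to_csv(
        paths["centroids"], index=False
    )
    report = {
        "initial_threshold": result.initial_threshold,
        "candidate_thresholds": result.candidates,
        "stage_counts": result.stage_counts,
        "n_objects": result.n_objects,
        "warnings": result.warnings,
        "config": result.config.to_dict() if result.config else None,
    }
    with open(paths["report"], "w") as fh:
        json.dump(report, fh, indent=2)
    return paths


def write_diagnostics(result: SegmentationResult, out_dir: str) -> dict[str, str]:
    """Write the threshold-detection diagnostics CSVs.

    histogram.csv (class,count), pwm_curve.csv (class,pwm,fitted) and
    candidates.csv (level) document how the initial threshold was found.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    if result.histogram is not None:
        paths["histogram"] = os.path.join(out_dir, "histogram.csv")
        pd.DataFrame(
            {"class": result.histogram.bin_locations, "count": result.histogram.counts}
        ).to_csv(paths["histogram"], index=False)
    if result.curve is not None and result.curve.poly is not None:
        paths["pwm_curve"] = os.path.join(out_dir, "pwm_curve.csv")
        classes = np.arange(result.curve.n_classes)
        fitted = np.full(classes.size, np.nan)
        lo, hi = result.curve.fit_domain
        fitted[lo : hi + 1] = result.curve.poly(np.arange(lo, hi + 1, dtype=float))
        pd.DataFrame(
            {"class": classes, "pwm": result.curve.values, "fitted": fitted}
        ).to_csv(paths["pwm_curve"], index=False)
    paths["candidates"] = os.path.join(out_dir, "candidates.csv")
    pd.DataFrame({"level": result.candidates}).to_csv(paths["candidates"], index=False)
    return paths
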