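"""Area-based correction: delete tiny objects, split oversized ones.

After the initial thresholding, objects far smaller than the mean area are
debris and objects far larger are fused nuclei.  Relative to the mean area
of the initial mask (*mean_total*), objects below ``small_factor * mean``
(default 25%) are deleted and objects above ``big_factor * mean`` (default
5x) are split by locally and iteratively lowering the threshold inside the
object's own pixel support until every resulting piece is below the big
cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.measure import label as _label
from skimage.measure import regionprops

__all__ = ["RegionRecord", "classify_by_area", "delete_small", "split_big", "relabel"]


@dataclass
class RegionRecord:
    """Geometry of one labeled object."""

    label: int
    area: int
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col), half-open
    centroid: tuple[float, float]
    solidity: float
    size_class: str = "normal"  # small | normal | big


def classify_by_area(
    mask: np.ndarray,
    *,
    small_factor: float = 0.25,
    big_factor: float = 5.0,
) -> tuple[float, list[RegionRecord]]:
    """Mean object area and per-object records with small/normal/big classes.

    An object is *small* iff area < small_factor * mean (strict), *big* iff
    area > big_factor * mean (strict), else *normal*.  An empty mask yields
    ``(nan, [])``.
    """
    mask = np.asarray(mask)
    props = regionprops(mask)
    if not props:
        return float("nan"), []
    areas = np.array([p.area for p in props], dtype=np.float64)
    mean_total = float(areas.mean())
    records = []
    for p in props:
        if p.area < small_factor * mean_total:
            cls = "small"
        elif p.area > big_factor * mean_total:
            cls = "big"
        else:
            cls = "normal"
        records.append(
            RegionRecord(
                label=int(p.label),
                area=int(p.area),
                bbox=tuple(p.bbox),
                centroid=tuple(p.centroid),
                solidity=float(p.solidity),
                size_class=cls,
            )
        )
    return mean_total, records


def relabel(mask: np.ndarray) -> np.ndarray:
    """Relabel consecutively 1..K preserving the original label order."""
    mask = np.asarray(mask)
    present = np.unique(mask)
    present = present[present > 0]
    lut = np.zeros(int(mask.max()) + 1, dtype=np.int32)
    lut[present] = np.arange(1, present.size + 1, dtype=np.int32)
    return lut[mask]


def delete_small(mask: np.ndarray, records: list[RegionRecord]) -> np.ndarray:
    """Erase all small-class objects and relabel consecutively."""
    mask = np.asarray(mask)
    small = [r.label for r in records if r.size_class == "small"]
    out = mask.copy()
    if small:
        out[np.isin(out, small)] = 0
    return relabel(out)


def split_big(
    gray_image: np.ndarray,
    mask: np.ndarray,
    initial_threshold: int,
    mean_total: float,
    records: list[RegionRecord],
    *,
    big_factor: float = 5.0,
    step: int = 1,
    connectivity: int = 2,
    comparison: str = "le",
) -> tuple[np.ndarray, list[str]]:
    """Split big objects by iteratively lowering the threshold locally.

    For each big-class object, the threshold is decreased by ``step`` gray
    levels at a time and re-applied only inside that object's pixel support
    (pixels outside the object are never re-admitted).  Iteration stops as
    soon as every connected component inside the support has area
    <= big_factor * mean_total, with ``mean_total`` frozen at its
    pre-correction value.  An object whose foreground vanishes before it
    is ever classified normal is kept as-is with a warning.

    Returns the relabeled mask and a list of per-object warnings.
    """
    gray_image = np.asarray(gray_image)
    mask = np.asarray(mask)
    out = mask.copy().astype(np.int32)
    notes: list[str] = []
    bound = big_factor * mean_total
    next_label = int(out.max()) + 1
    for rec in records:
        if rec.size_class != "big":
            continue
        support = mask == rec.label
        out[support] = 0
        chosen: np.ndarray | None = None  # last nonempty partition seen
        satisfied = False
        t = initial_threshold
        while t - step >= 0:
            t -= step
            fg = (gray_image <= t if comparison == "le" else gray_image < t) & support
            if not fg.any():
                break
            comp = _label(fg, connectivity=connectivity)
            chosen = comp
            areas = np.bincount(comp.ravel())[1:]
            if (areas <= bound).all():
                satisfied = True
                break
        if chosen is None:
            # foreground vanished immediately: unsplittable, keep the object
            notes.append(
                f"object {rec.label}: could not be split (foreground vanished); "
                "kept as-is"
            )
            out[support] = rec.label
            continue
        if not satisfied:
            notes.append(
                f"object {rec.label}: never classified normal before the "
                "threshold bottomed out; keeping last partition"
            )
        n_comp = int(chosen.max())
        piece = chosen > 0
        out[piece] = chosen[piece] + next_label - 1
        next_label += n_comp
    for note in notes:
        warnings.warn(note, stacklevel=2)
    return relabel(out), notes
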