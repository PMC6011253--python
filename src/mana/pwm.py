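"""Object-based threshold detection via the progressive weighted mean curve.

The central idea: for an 8-bit grayscale image with histogram counts
``w_i`` at gray levels ``x_i``, the progressive weighted mean at class P is

    PWM(P) = sum_{i<=P} w_i * x_i / sum_{i<=P} w_i,

i.e. the mean gray level of all pixels at or below P.  Where the histogram
has a concentration of mass (a mode), the curve is flat; where a new
population of pixels enters, its concavity changes.  Inflection points of a
smooth (polynomial) fit of the curve are therefore candidate segmentation
thresholds, and the one whose binarization yields objects with the highest
median area is taken as the initial nuclei threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import Polynomial
from skimage.filters import threshold_otsu
from skimage.measure import label as _label

__all__ = [
    "GrayHistogram",
    "PWMCurve",
    "CandidateThresholds",
    "to_grayscale",
    "compute_histogram",
    "compute_pwm_curve",
    "fit_pwm_polynomial",
    "find_inflection_points",
    "segment_at_threshold",
    "select_initial_threshold",
]

#: BT.601 luminance weights for R, G, B.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class GrayHistogram:
    """Per-gray-level pixel counts of an 8-bit image (256 classes)."""

    counts: np.ndarray
    bin_locations: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.bin_locations = np.asarray(self.bin_locations, dtype=np.int64)
        if self.counts.shape != self.bin_locations.shape:
            raise ValueError("counts and bin_locations must have equal length")
        if (self.counts < 0).any():
            raise ValueError("histogram counts must be non-negative")

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())


@dataclass
class PWMCurve:
    """Progressive weighted mean per gray-level class, plus its polynomial fit.

    ``values[P]`` is the weighted mean gray level of all pixels with value
    <= P.  Classes below ``defined_from`` (the first occupied gray level)
    are undefined by the formula (0/0) and carry the value at
    ``defined_from`` so the curve is total; they are excluded from the fit
    domain.
    """

    values: np.ndarray
    defined_from: int
    defined_to: int = -1
    poly: Polynomial | None = None
    fit_domain: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.defined_to < 0:
            self.defined_to = self.values.size - 1

    @property
    def n_classes(self) -> int:
        return self.values.size


@dataclass
class CandidateThresholds:
    """Integer candidate thresholds with the real-valued roots they came from."""

    levels: list[int] = field(default_factory=list)
    source: dict[int, list[float]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.levels)


def to_grayscale(rgb_image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to 8-bit luminance (BT.601 weights).

    Hue and saturation are discarded; luminance is retained as
    0.299 R + 0.587 G + 0.114 B, rounded half-up to the nearest integer.
    A single-channel input is passed through unchanged with a warning.
    """
    img = np.asarray(rgb_image)
    if img.ndim == 2:
        warnings.warn("input is already grayscale; passing through", stacklevel=2)
        return img.astype(np.uint8, copy=False)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an RGB image with 3 channels, got shape {img.shape}")
    lum = img.astype(np.float64) @ _LUMA
    # round-half-up: floor(x + 0.5) (np.round would round half-to-even)
    return np.floor(lum + 0.5).astype(np.uint8)


def compute_histogram(gray_image: np.ndarray) -> GrayHistogram:
    """256-class histogram of an 8-bit grayscale image."""
    img = np.asarray(gray_image)
    if img.size == 0:
        raise ValueError("cannot compute the histogram of an empty image")
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    counts = np.bincount(img.astype(np.int64).ravel(), minlength=256)
    if counts.size > 256:
        raise ValueError("gray values exceed 255; only 8-bit images are supported")
    return GrayHistogram(counts=counts, bin_locations=np.arange(256))


def compute_pwm_curve(hist: GrayHistogram) -> PWMCurve:
    """Progressive weighted mean of the histogram, one value per class.

    Uses cumulative sums: PWM(P) = cumsum(w*x)[P] / cumsum(w)[P].
    """
    w = hist.counts.astype(np.float64)
    if not w.any():
        raise ValueError("all-zero histogram: the PWM curve is undefined")
    x = hist.bin_locations.astype(np.float64)
    cw = np.cumsum(w)
    cwx = np.cumsum(w * x)
    defined_from = int(np.argmax(w > 0))
    values = np.empty_like(cw)
    defined = cw > 0
    values[defined] = cwx[defined] / cw[defined]
    values[~defined] = values[defined_from]  # backfill below first occupied class
    defined_to = int(len(w) - 1 - np.argmax(w[::-1] > 0))
    return PWMCurve(values=values, defined_from=defined_from, defined_to=defined_to)


def fit_pwm_polynomial(curve: PWMCurve, order: int = 15) -> PWMCurve:
    """Least-squares polynomial fit of the PWM curve over its occupied range.

    The fit domain is [first occupied class, last occupied class]; classes
    outside it carry no information (the curve is constant there).  The
    abscissa is affinely mapped to [-1, 1] before
    fitting (an order-15 fit on the raw 0..255 axis is numerically
    ill-conditioned); numpy's Polynomial keeps the mapping in its
    domain/window attributes.  If fewer points than ``order + 1`` are
    available the order is reduced with a warning.
    """
    lo, hi = curve.defined_from, curve.defined_to
    n_points = hi - lo + 1
    if n_points < 2:
        raise ValueError("PWM curve defined on fewer than 2 classes; cannot fit")
    eff_order = order
    if n_points < order + 1:
        eff_order = n_points - 1
        warnings.warn(
            f"only {n_points} defined classes; reducing polynomial order "
            f"from {order} to {eff_order}",
            stacklevel=2,
        )
    xs = np.arange(lo, hi + 1, dtype=np.float64)
    ys = curve.values[lo : hi + 1]
    poly = Polynomial.fit(xs, ys, deg=eff_order, domain=[lo, hi], window=[-1.0, 1.0])
    curve.poly = poly
    curve.fit_domain = (lo, hi)
    return curve


def find_inflection_points(curve: PWMCurve) -> CandidateThresholds:
    """Candidate thresholds: sign-change inflection points of the fitted curve.

    Real roots of the second derivative of the fitted polynomial are kept
    only if they lie strictly inside the fit domain and the second
    derivative actually changes sign across them (a tangential double root
    is not a concavity change).  Sign changes whose curvature magnitude is
    numerically negligible for the curve's amplitude are discarded: fitting
    a high-order polynomial to data with no genuine curvature (e.g. an
    exactly linear curve) leaves second-derivative noise at the level of
    float round-off, which must not produce candidates.  Roots are rounded
    to integer gray levels and deduplicated.
    """
    if curve.poly is None or curve.fit_domain is None:
        raise ValueError("polynomial not fitted; call fit_pwm_polynomial first")
    lo, hi = curve.fit_domain
    d2 = curve.poly.deriv(2)
    roots = d2.roots()
    real = np.real(roots[np.abs(np.imag(roots)) < 1e-8])
    result = CandidateThresholds()
    # probe offset for the sign-change check, small relative to one gray level
    span = max(hi - lo, 1)
    eps = 1e-4 * span
    amplitude = float(np.ptp(curve.values[lo : hi + 1]))
    floor = curvature_floor(amplitude, span)
    for r in sorted(real):
        if not (lo < r < hi):
            continue
        left = d2(max(r - eps, lo))
        right = d2(min(r + eps, hi))
        if np.sign(left) * np.sign(right) >= 0:
            continue  # tangential root, no concavity change
        if max(abs(left), abs(right)) < floor:
            continue  # numerically flat: round-off, not concavity
        level = int(np.floor(r + 0.5))
        if level < 0 or level > curve.n_classes - 1:
            continue
        if level not in result.source:
            result.levels.append(level)
            result.source[level] = []
        result.source[level].append(float(r))
    result.levels.sort()
    return result


def curvature_floor(amplitude: float, span: float) -> float:
    """Minimum second-derivative magnitude considered a real concavity change.

    A curve of amplitude A over a span L has meaningful curvature of order
    A / L**2; anything many orders below that is least-squares round-off.
    """
    return 1e-6 * max(amplitude, 1.0) / span**2


def segment_at_threshold(
    gray_image: np.ndarray,
    t: int,
    *,
    connectivity: int = 2,
    comparison: str = "le",
) -> np.ndarray:
    """Label dark objects: pixels with value <= t (or < t), 8-connected.

    Returns an integer label mask (0 = background).
    """
    img = np.asarray(gray_image)
    fg = img <= t if comparison == "le" else img < t
    return _label(fg, connectivity=connectivity)


def _interior_areas(mask: np.ndarray) -> np.ndarray:
    """Areas of the objects that do not touch the image border."""
    areas = np.bincount(mask.ravel())[1:]
    border = np.unique(
        np.concatenate([mask[0], mask[-1], mask[:, 0], mask[:, -1]])
    )
    border = border[border > 0]
    keep = np.ones(areas.size, dtype=bool)
    keep[border - 1] = False
    return areas[keep & (areas > 0)]


def select_initial_threshold(
    gray_image: np.ndarray,
    candidates: CandidateThresholds,
    *,
    connectivity: int = 2,
    comparison: str = "le",
) -> tuple[int, np.ndarray]:
    """Pick the candidate whose binarization has the highest median object area.

    Every candidate threshold is applied and the median area over the
    resulting connected components is computed; the candidate maximizing it
    wins, ties going to the lower threshold (less foreground, fewer merged
    nuclei).  Candidates yielding zero objects are skipped.  With no usable
    candidate at all, Otsu's threshold is used as a fallback with a warning.

    Objects touching the image border are excluded from the median-area
    statistic (they are kept in the returned mask).  This is the standard
    clear-border guard: a candidate at or above the background mode turns
    nearly the whole image into one border-spanning component whose area
    would otherwise always win, which is never a usable nuclei threshold.
    """
    gray_image = np.asarray(gray_image)
    best_t: int | None = None
    best_median = -np.inf
    best_mask: np.ndarray | None = None
    for t in candidates.levels:  # ascending, so ties keep the lower threshold
        mask = segment_at_threshold(
            gray_image, t, connectivity=connectivity, comparison=comparison
        )
        n_obj = mask.max()
        if n_obj == 0:
            continue
        areas = _interior_areas(mask)
        if areas.size == 0:
            continue
        med = float(np.median(areas))
        if med > best_median:
            best_median = med
            best_t = t
            best_mask = mask
    if best_t is None:
        if len(candidates) == 0:
            warnings.warn(
                "no candidate thresholds; falling back to Otsu", stacklevel=2
            )
        else:
            warnings.warn(
                "no candidate threshold produced any object; falling back to Otsu",
                stacklevel=2,
            )
        if gray_image.size == 0 or gray_image.min() == gray_image.max():
            warnings.warn(
                "constant image; returning an empty segmentation", stacklevel=2
            )
            return 0, np.zeros_like(np.asarray(gray_image), dtype=np.int32)
        best_t = int(threshold_otsu(gray_image))
        best_mask = segment_at_threshold(
            gray_image, best_t, connectivity=connectivity, comparison=comparison
        )
    return best_t, best_mask
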