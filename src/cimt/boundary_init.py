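"""Initial boundary estimation inside the ROI.

Two interfaces bound the intima-media complex: the lumen-intima
interface (LII) on top and the media-adventitia interface (MAI) below.
Both are dark-to-bright transitions going down in depth, which this
module exploits twice:

* The **LII** is found photometrically.  After filtering, the ROI
  intensity histogram is roughly tri-modal (lumen+media / intima /
  adventitia); a threshold ``T1`` in the first valley separates the dark
  lumen from the intima.  A column-by-column state machine traces a
  rough, eight-neighborhood-continuous boundary along the first
  super-threshold pixel of each column, and morphological closing of the
  thresholded mask bridges columns where artifacts locally erase the
  intima.

* The **MAI** is found geometrically.  Because the two interfaces are
  nearly parallel, the estimated LII is displaced downward through the
  physiological IMT range (0.4-1.4 mm) and, on each displaced line, the
  vertical-derivative-of-Gaussian edge response is summed; the
  displacement with the strongest cumulative response marks the bright
  adventitia edge.

The signed edge map built here is shared with the dynamic-programming
refinement stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from skimage.morphology import closing as _closing

from .errors import InitializationFailure, ValidationError
from .image_io import GrayImage, mm_to_px

#: Default intensity threshold separating lumen from intima.
DEFAULT_THRESHOLD = 0.1
#: Default side length (px) of the square closing element.
DEFAULT_CLOSING_SIZE = 15
#: Physiological intima-media thickness range searched for the MAI (mm).
DEFAULT_IMT_RANGE_MM = (0.4, 1.4)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class Boundary:
    """One vertical position per column over a contiguous column range.

    Rows may be fractional (sub-pixel ground truth, interpolated
    columns); pipeline stages that index pixels round explicitly.
    """

    col_start: int
    rows: np.ndarray

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=np.float64)
        if rows.ndim != 1 or rows.size < 2:
            raise ValidationError("boundary needs at least 2 columns")
        if not np.all(np.isfinite(rows)):
            raise ValidationError("boundary rows contain non-finite values")
        object.__setattr__(self, "rows", rows)

    @property
    def n(self) -> int:
        return self.rows.size

    @property
    def cols(self) -> np.ndarray:
        return np.arange(self.col_start, self.col_start + self.n)

    def shifted(self, delta: float) -> "Boundary":
        return Boundary(self.col_start, self.rows + delta)

    def rounded(self) -> "Boundary":
        return Boundary(self.col_start, np.floor(self.rows + 0.5))


@dataclass(frozen=True)
class EdgeMap:
    """Signed vertical-gradient response, same shape as the ROI.

    Positive where intensity increases with the row index, i.e. at
    dark-above / bright-below interfaces — the polarity of both the LII
    and the MAI.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 2:
            raise ValidationError("edge map must be 2-D")
        object.__setattr__(self, "values", vals)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class HistogramAnalysis:
    """Diagnostic summary of the ROI intensity histogram.

    ``t1`` is the valley between the dark (lumen/media) and intima modes
    and can serve as an adaptive threshold; ``t2`` (intima/adventitia
    valley) is reported for inspection only.  ``ambiguous`` is set when
    the three-peak structure expected of a healthy ROI is absent — the
    signature of a missing intima layer.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    smoothed: np.ndarray
    peak_intensities: tuple[float, ...]
    t1: float | None = None
    t2: float | None = None
    ambiguous: bool = True
    notes: str = field(default="")


def analyze_histogram(roi: GrayImage, n_bins: int = 64) -> HistogramAnalysis:
    """Histogram the ROI intensities and locate the inter-mode valleys.

    The histogram is smoothed with a narrow Gaussian before peak/valley
    detection so speckle-induced jitter does not create spurious modes.
    Absent valleys are reported as ``None`` with ``ambiguous=True``;
    callers fall back to the fixed threshold.
    """
    counts, edges = np.histogram(roi.pixels, bins=n_bins, range=(0.0, 1.0))
    smoothed = gaussian_filter1d(counts.astype(float), sigma=1.5, mode="nearest")
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak_idx, props = find_peaks(smoothed, prominence=0.02 * smoothed.max())
    if peak_idx.size < 3:
        return HistogramAnalysis(
            edges, counts, smoothed, tuple(centers[peak_idx]),
            ambiguous=True, notes=f"only {peak_idx.size} peak(s) found",
        )
    # Keep the three most prominent modes, in intensity order.
    order = np.argsort(props["prominences"])[::-1][:3]
    p3 = np.sort(peak_idx[order])
    valleys = []
    for a, b in zip(p3[:-1], p3[1:]):
        valleys.append(a + int(np.argmin(smoothed[a : b + 1])))
    t1, t2 = float(centers[valleys[0]]), float(centers[valleys[1]])
    # A valley nearly as tall as its flanking peaks carries no separation.
    depth_ok = all(
        smoothed[v] <= 0.8 * min(smoothed[a], smoothed[b])
        for v, (a, b) in zip(valleys, zip(p3[:-1], p3[1:]))
    )
    return HistogramAnalysis(
        edges, counts, smoothed, tuple(centers[p3]),
        t1=t1, t2=t2, ambiguous=not depth_ok,
        notes="" if depth_ok else "shallow valley(s)",
    )


def _first_crossings(roi: GrayImage, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Per column: the first row with intensity > threshold, and a
    missing-column mask where no such row exists."""
    above = roi.pixels > threshold
    has = above.any(axis=0)
    first = np.where(has, above.argmax(axis=0), -1)
    return first, ~has


def trace_rough_lii(roi: GrayImage, threshold: float = DEFAULT_THRESHOLD) -> Boundary:
    """Trace the rough LII with the four-step threshold-crossing tracker.

    Column by column, the first super-threshold pixel is located; the
    boundary then advances by +1 if the new crossing lies deeper than the
    current boundary row, by -1 if it lies shallower, and re-anchors to
    the crossing row when the two coincide.  The result is an
    eight-neighborhood-continuous line (|row step| <= 1 between adjacent
    columns).

    Columns with no super-threshold pixel carry the current boundary row
    forward unchanged; leading missing columns are backfilled from the
    first traced column.  An entirely sub-threshold ROI cannot be traced.
    """
    if not (0.0 < threshold < 1.0):
        raise ValidationError(f"threshold must be in (0, 1), got {threshold}")
    crossings, missing = _first_crossings(roi, threshold)
    n = roi.n_cols
    if missing.all():
        raise InitializationFailure("no pixel above threshold in any column")
    j0 = int(np.argmin(missing))  # first traced column
    rows = np.empty(n, dtype=np.float64)
    state = int(crossings[j0])
    rows[: j0 + 1] = state
    for j in range(j0 + 1, n):
        if not missing[j]:
            c = int(crossings[j])
            if c > state:
                state += 1
            elif c < state:
                state -= 1
            else:
                state = c
        rows[j] = state
    return Boundary(0, rows)


def segment_binary(roi: GrayImage, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Binary mask of super-threshold pixels (intima band + adventitia)."""
    if not (0.0 < threshold < 1.0):
        raise ValidationError(f"threshold must be in (0, 1), got {threshold}")
    return roi.pixels > threshold


def close_gaps(mask: np.ndarray, r: int = DEFAULT_CLOSING_SIZE) -> np.ndarray:
    """Morphological closing (dilation then erosion) with a square
    structuring element of side ``r``, bridging gaps narrower than the
    element where artifacts locally erased the intima band.

    The mask is padded with background before closing so the element
    cannot anchor on the ROI border and fabricate foreground there.
    """
    if r < 1:
        raise ValidationError(f"structuring element size must be >= 1, got {r}")
    if r == 1:
        return mask.copy()
    padded = np.pad(mask.astype(bool), r, mode="constant", constant_values=False)
    closed = _closing(padded, footprint=np.ones((r, r), dtype=bool))
    return closed[r:-r, r:-r]


def estimate_lii(
    roi: GrayImage,
    threshold: float = DEFAULT_THRESHOLD,
    r: int = DEFAULT_CLOSING_SIZE,
) -> Boundary:
    """Estimated LII: top contour of the gap-closed threshold mask.

    Columns still empty after closing are linearly interpolated from the
    nearest traced neighbors (edge columns extended constant).  If more
    than half the columns are empty the intima is effectively absent and
    initialization fails.
    """
    closed = close_gaps(segment_binary(roi, threshold), r)
    has = closed.any(axis=0)
    n = roi.n_cols
    n_missing = int((~has).sum())
    if n_missing > 0.5 * n:
        raise InitializationFailure(
            f"{n_missing}/{n} columns have no super-threshold pixel after closing"
        )
    first = closed.argmax(axis=0).astype(np.float64)
    cols = np.arange(n)
    rows = np.interp(cols, cols[has], first[has])
    return Boundary(0, rows)


def _edge_kernel(kernel_size: int, sigma: float) -> np.ndarray:
    """Separable vertical derivative-of-Gaussian kernel.

    Sampled on a ``kernel_size`` grid centered between pixels for even
    sizes (offsets ±0.5, ±1.5, ...).  The row factor is the analytic
    Gaussian derivative, oriented so that intensity increasing with row
    index yields a positive response; the column factor is a unit-sum
    Gaussian.  Applied by correlation (not flipped convolution).
    """
    offsets = np.arange(kernel_size) - (kernel_size - 1) / 2.0
    g = np.exp(-(offsets**2) / (2.0 * sigma**2))
    g_norm = g / g.sum()
    dg = (offsets / sigma**2) * g / g.sum()
    return np.outer(dg, g_norm)


def edge_map(roi: GrayImage, kernel_size: int = 10, sigma: float = 1.0) -> EdgeMap:
    """Vertical-edge response of the ROI.

    Correlation of the ROI with the vertical first-order
    derivative-of-Gaussian kernel (default 10x10, sigma 1 in both
    directions), with edge-replicated borders.  The accumulation pairs
    the kernel's antisymmetric rows, so a constant image maps to exactly
    zero (not just to rounding error) and the operator is exactly linear
    in the image.
    """
    if kernel_size < 2:
        raise ValidationError(f"kernel_size must be >= 2, got {kernel_size}")
    if not sigma > 0:
        raise ValidationError(f"sigma must be > 0, got {sigma}")
    kern = _edge_kernel(kernel_size, sigma)
    n = kernel_size
    half = n // 2  # correlation origin, as in scipy.ndimage.correlate
    h, w = roi.shape
    padded = np.pad(roi.pixels, n, mode="edge")

    def window(oi: int, oj: int) -> np.ndarray:
        return padded[n + oi : n + oi + h, n + oj : n + oj + w]

    vals = np.zeros((h, w))
    for i in range(n // 2):
        i_mirror = n - 1 - i  # kern[i, :] == -kern[i_mirror, :] exactly
        for j in range(n):
            diff = window(i - half, j - half) - window(i_mirror - half, j - half)
            vals += kern[i, j] * diff
    if n % 2 == 1:
        mid = (n - 1) // 2  # zero offset row of an odd kernel: weight 0
        for j in range(n):
            if kern[mid, j] != 0.0:
                vals += kern[mid, j] * window(mid - half, j - half)
    return EdgeMap(vals)


def estimate_mai(
    lii: Boundary,
    emap: EdgeMap,
    roi: GrayImage,
    imt_range_mm: tuple[float, float] = DEFAULT_IMT_RANGE_MM,
) -> tuple[Boundary, int]:
    """Estimated MAI: the downward displacement of the LII with maximal
    cumulative edge response.

    Integer displacements from ``round(lo_mm * density)`` to
    ``round(hi_mm * density)`` pixels (round half up) are scanned; for
    each, the signed edge response is summed along the displaced line
    (rows clipped to the ROI) and the argmax displacement wins, ties
    going to the smaller displacement.  Returns the displaced boundary
    and the chosen displacement in pixels.
    """
    n_rows, n_cols = emap.shape
    if lii.n != n_cols or lii.col_start != 0:
        raise ValidationError("LII boundary must cover every ROI column")
    lo = _round_half_up(mm_to_px(imt_range_mm[0], roi))
    hi = _round_half_up(mm_to_px(imt_range_mm[1], roi))
    if hi < lo:
        raise ValidationError(f"empty displacement range {imt_range_mm}")
    base = np.floor(lii.rows + 0.5).astype(int)
    cols = np.arange(n_cols)
    if (base + lo >= n_rows).all():
        raise InitializationFailure("every candidate MAI line lies below the ROI")
    best_delta, best_sum = None, -np.inf
    for delta in range(lo, hi + 1):
        rows = np.clip(base + delta, 0, n_rows - 1)
        s = float(emap.values[rows, cols].sum())
        if s > best_sum:  # strict: ties keep the smaller displacement
            best_sum, best_delta = s, delta
    shifted = np.clip(lii.rows + best_delta, 0.0, n_rows - 1.0)
    return Boundary(0, shifted), int(best_delta)
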