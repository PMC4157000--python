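"""Region-of-interest extraction by template matching.

The intima-media complex (IMC) of the far carotid wall shows a
characteristic depth profile — dark lumen, medium-bright intima band,
dark media, bright adventitia.  A small template cut from a reference
image is slid along seven evenly spaced vertical lines of the search
image, and on each line the position minimizing the sum of absolute
differences (SAD) of pixel intensities is the best IMC estimate there.

Because speckle or artifacts can drag individual matches to wrong
positions, matches are cross-validated: a match is kept only if its
vertical position agrees (within 2 mm) with at least three of the other
matches, exploiting the near-horizontal course of the vessel in a
longitudinal scan.  If at least four matches survive, a rectangular ROI
of half-height ``d`` around their representative row, spanning their
column range, is extracted; otherwise the image is rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml
from numpy.lib.stride_tricks import sliding_window_view

from .denoise import BilateralParams, bilateral_filter
from .errors import RoiFailure, ValidationError
from .image_io import GrayImage, load_image, mm_to_px, save_image

#: Default ROI half-height in pixels.
DEFAULT_ROI_HALF_HEIGHT = 20
#: Number of vertical search lines.
DEFAULT_N_LINES = 7


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class Template:
    """A small grayscale patch covering part of the IMC plus some lumen
    above and adventitia below.  Both dimensions must be odd so the
    template has a well-defined center pixel."""

    pixels: np.ndarray
    pixel_density: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValidationError("template must be 2-D")
        if px.shape[0] % 2 == 0 or px.shape[1] % 2 == 0:
            raise ValidationError(f"template dimensions must be odd, got {px.shape}")
        if px.min() < -1e-9 or px.max() > 1 + 1e-9:
            raise ValidationError("template intensities outside [0, 1]")
        object.__setattr__(self, "pixels", np.clip(px, 0.0, 1.0))

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def half_rows(self) -> int:
        return (self.n_rows - 1) // 2

    @property
    def half_cols(self) -> int:
        return (self.n_cols - 1) // 2


@dataclass(frozen=True)
class MatchPoint:
    """Best template match on one vertical line."""

    col: int
    row: int
    sad: float
    valid: bool = True


@dataclass(frozen=True)
class MatchSet:
    """Ordered matches on strictly increasing columns."""

    points: tuple[MatchPoint, ...]

    def __post_init__(self) -> None:
        cols = [p.col for p in self.points]
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ValidationError(f"match columns must be strictly increasing: {cols}")

    @property
    def valid_points(self) -> tuple[MatchPoint, ...]:
        return tuple(p for p in self.points if p.valid)


@dataclass(frozen=True)
class ROIBox:
    """Inclusive pixel rectangle of the extracted ROI within the source image."""

    row_lo: int
    row_hi: int
    col_min: int
    col_max: int
    half_height: int

    def __post_init__(self) -> None:
        if self.row_lo >= self.row_hi or self.col_min >= self.col_max:
            raise ValidationError(f"degenerate ROI rectangle: {self}")


def sad_score(img: GrayImage, tmpl: Template, center_row: int, center_col: int) -> float:
    """Sum of absolute intensity differences between the template and the
    image patch centered at ``(center_row, center_col)``.

    Defined only where the full template footprint lies inside the image;
    no padding is ever applied.
    """
    hr, hc = tmpl.half_rows, tmpl.half_cols
    if (
        center_row - hr < 0
        or center_row + hr >= img.n_rows
        or center_col - hc < 0
        or center_col + hc >= img.n_cols
    ):
        raise ValidationError(
            f"template footprint at ({center_row}, {center_col}) exceeds image {img.shape}"
        )
    patch = img.pixels[
        center_row - hr : center_row + hr + 1, center_col - hc : center_col + hc + 1
    ]
    return float(np.abs(patch - tmpl.pixels).sum())


def _sad_profile(img: GrayImage, tmpl: Template, col: int) -> tuple[np.ndarray, int]:
    """SAD scores for every admissible center row on one column.

    Returns ``(scores, first_row)`` where ``scores[i]`` is the SAD at
    center row ``first_row + i``.
    """
    hr, hc = tmpl.half_rows, tmpl.half_cols
    if col - hc < 0 or col + hc >= img.n_cols:
        raise ValidationError(f"column {col} does not admit a full template footprint")
    if img.n_rows < tmpl.n_rows:
        raise ValidationError("image shorter than template; no admissible row")
    strip = img.pixels[:, col - hc : col + hc + 1]
    windows = sliding_window_view(strip, (tmpl.n_rows, tmpl.n_cols))[:, 0]
    scores = np.abs(windows - tmpl.pixels[None]).sum(axis=(1, 2))
    return scores, hr


def match_on_line(img: GrayImage, tmpl: Template, col: int) -> MatchPoint:
    """Best match on one vertical line: the admissible center row with the
    lowest SAD score; ties are broken toward the smallest row."""
    scores, first_row = _sad_profile(img, tmpl, col)
    idx = int(np.argmin(scores))  # argmin returns the first minimum -> smallest row
    return MatchPoint(col=col, row=first_row + idx, sad=float(scores[idx]), valid=True)


def find_matches(img: GrayImage, tmpl: Template, n_lines: int = DEFAULT_N_LINES) -> MatchSet:
    """Match the template on ``n_lines`` evenly spaced vertical lines.

    Line columns are placed at ``lo + round((j + 1) * W / (n_lines + 1))``
    over the admissible column range ``[lo, hi]`` (width ``W``), i.e. at
    interior positions away from the borders.
    """
    if n_lines < 1:
        raise ValidationError(f"n_lines must be >= 1, got {n_lines}")
    hc = tmpl.half_cols
    lo, hi = hc, img.n_cols - 1 - hc
    if hi <= lo:
        raise ValidationError("image too narrow for the template")
    width = hi - lo
    cols = [lo + _round_half_up((j + 1) * width / (n_lines + 1)) for j in range(n_lines)]
    if len(set(cols)) != n_lines:
        raise ValidationError(
            f"image too narrow for {n_lines} distinct search lines (got columns {cols})"
        )
    return MatchSet(tuple(match_on_line(img, tmpl, c) for c in cols))


def reject_outliers(
    matches: MatchSet,
    img: GrayImage,
    agreement_mm: float = 2.0,
    min_agree: int = 4,
) -> MatchSet:
    """Flag mismatched points by mutual vertical agreement.

    A point is valid iff its row differs by at most ``agreement_mm``
    (converted to fractional pixels, inclusive comparison) from at least
    ``min_agree - 1`` other points.  Fewer than ``min_agree`` valid
    points means the IMC could not be located and the image cannot be
    processed.
    """
    tol_px = mm_to_px(agreement_mm, img)
    rows = np.array([p.row for p in matches.points], dtype=float)
    diff = np.abs(rows[:, None] - rows[None, :])
    partners = (diff <= tol_px).sum(axis=1) - 1  # exclude self
    flags = partners >= (min_agree - 1)
    flagged = MatchSet(
        tuple(replace(p, valid=bool(f)) for p, f in zip(matches.points, flags))
    )
    n_valid = int(flags.sum())
    if n_valid < min_agree:
        raise RoiFailure(
            f"only {n_valid} of {len(rows)} template matches agree within "
            f"{agreement_mm} mm; need {min_agree}"
        )
    return flagged


def extract_roi(
    img: GrayImage, matches: MatchSet, d: int = DEFAULT_ROI_HALF_HEIGHT
) -> tuple[GrayImage, ROIBox]:
    """Cut the rectangular ROI around the validated matches.

    Columns span the valid matches' column range; rows span
    ``row_ref - d .. row_ref + d`` where ``row_ref`` is the median row of
    the valid points (robust to residual mislocation).  The rectangle is
    clipped to the image.
    """
    if d <= 0:
        raise ValidationError(f"ROI half-height must be > 0, got {d}")
    valid = matches.valid_points
    if len(valid) < 2:
        raise RoiFailure("need at least two valid matches to span a ROI")
    rows = np.array([p.row for p in valid], dtype=float)
    row_ref = _round_half_up(float(np.median(rows)))
    col_min = min(p.col for p in valid)
    col_max = max(p.col for p in valid)
    row_lo = max(0, row_ref - d)
    row_hi = min(img.n_rows - 1, row_ref + d)
    if row_hi - row_lo < 1 or col_max - col_min < 1:
        raise ValidationError("ROI rectangle degenerate after clipping")
    box = ROIBox(row_lo, row_hi, col_min, col_max, d)
    sub = img.pixels[row_lo : row_hi + 1, col_min : col_max + 1]
    return GrayImage(sub.copy(), img.pixel_density), box


def build_template(
    img: GrayImage,
    center: tuple[int, int],
    size: tuple[int, int],
    bilateral: BilateralParams | None = BilateralParams(),
) -> Template:
    """Cut a template patch from an image and smooth it.

    The patch should be centered on an IMC strip of medium thickness
    (about 0.7 mm) and include some lumen above and adventitia below.
    The cut patch is bilaterally smoothed so residual speckle in the
    reference image does not bias later SAD scores (pass
    ``bilateral=None`` to skip smoothing).
    """
    t_r, t_c = size
    if t_r % 2 == 0 or t_c % 2 == 0:
        raise ValidationError(f"template size must be odd, got {size}")
    row, col = center
    hr, hc = (t_r - 1) // 2, (t_c - 1) // 2
    if row - hr < 0 or row + hr >= img.n_rows or col - hc < 0 or col + hc >= img.n_cols:
        raise ValidationError(f"template footprint at {center} exceeds image {img.shape}")
    patch = img.pixels[row - hr : row + hr + 1, col - hc : col + hc + 1].copy()
    if bilateral is not None and min(t_r, t_c) >= 3:
        patch = bilateral_filter(GrayImage(patch, img.pixel_density), bilateral).pixels
    return Template(patch, pixel_density=img.pixel_density)


def save_template(tmpl: Template, path: str | Path) -> None:
    """Write a template as an 8-bit PNG plus a YAML sidecar recording the
    source pixel density."""
    path = Path(path)
    save_image(GrayImage(tmpl.pixels, tmpl.pixel_density or 1.0), path)
    sidecar = path.with_suffix(path.suffix + ".yaml")
    sidecar.write_text(yaml.safe_dump({"pixel_density": tmpl.pixel_density}))


def load_template(path: str | Path) -> Template:
    """Load a template written by :func:`save_template`."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".yaml")
    density = None
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
        density = meta.get("pixel_density")
    img = load_image(path, pixel_density=density or 1.0)
    return Template(img.pixels, pixel_density=density)
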