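"""Seeded synthetic carotid B-mode phantoms with known ground truth.

A longitudinal far-wall scan is emulated as a stack of four horizontal
tissue layers — dark lumen, medium-bright intima band, dark media,
bright adventitia — separated by near-horizontal, possibly sloped or
gently sinusoidal interfaces.  The lumen-intima interface (LII) is the
top of the intima band; the media-adventitia interface (MAI) is the top
of the adventitia; the IMT is their vertical distance.  Each interface
carries a one-pixel linear intensity ramp so the derivative-of-Gaussian
edge response has a well-defined peak, and ground-truth boundaries are
returned at sub-pixel precision.

Speckle is modeled as clipped multiplicative noise (Gaussian by default,
a unit-mean Rayleigh field as a variant), after which the image is
quantized to 256 gray levels like an 8-bit acquisition.  Failure cases —
an intima locally erased over a column interval, or absent altogether —
are constructible on demand.

This generator is the test substrate standing in for a clinical image
archive; it reproduces the layered geometry the measurement pipeline
relies on, not the physics of ultrasound formation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .boundary_init import Boundary
from .errors import ValidationError
from .image_io import DEFAULT_PIXEL_DENSITY, GrayImage, save_image

#: Layer mean intensities: lumen, intima, media, adventitia.
DEFAULT_LAYER_MEANS = (0.05, 0.45, 0.15, 0.85)


def constant_profile(value: float, n_cols: int) -> np.ndarray:
    """A horizontal interface."""
    return np.full(n_cols, float(value))


def sloped_profile(center: float, slope: float, n_cols: int) -> np.ndarray:
    """A straight interface through ``center`` at the middle column with
    the given slope in px per column."""
    x = np.arange(n_cols) - (n_cols - 1) / 2.0
    return center + slope * x


def sinusoidal_profile(
    center: float, amplitude: float, period_cols: float, n_cols: int
) -> np.ndarray:
    """A gently undulating interface."""
    x = np.arange(n_cols)
    return center + amplitude * np.sin(2.0 * np.pi * x / period_cols)


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth geometry, intensities and noise of one phantom.

    ``lii_row`` and ``imt_mm`` may be scalars (constant interface /
    thickness) or per-column arrays.  ``intima_fraction`` splits the IMT
    into intima band (top) and media band (bottom).  ``speckle_sigma``
    scales the multiplicative noise; 0 gives a noiseless phantom.
    """

    shape: tuple[int, int] = (256, 384)
    pixel_density: float = DEFAULT_PIXEL_DENSITY
    lii_row: float | np.ndarray | None = None  # default: 46% of image height
    imt_mm: float | np.ndarray = 0.7
    layer_means: tuple[float, float, float, float] = DEFAULT_LAYER_MEANS
    intima_fraction: float = 0.5
    speckle_sigma: float = 0.0
    noise_model: str = "gaussian"  # or "rayleigh"
    intima_gap_cols: tuple[int, int] | None = None  # half-open column interval
    missing_intima: bool = False
    quantize: bool = True
    seed: int = 0

    def resolved_lii(self) -> np.ndarray:
        n_cols = self.shape[1]
        lii = self.lii_row
        if lii is None:
            lii = 0.46 * self.shape[0]
        return np.broadcast_to(np.asarray(lii, dtype=float), (n_cols,)).copy()

    def resolved_imt_px(self) -> np.ndarray:
        n_cols = self.shape[1]
        imt = np.broadcast_to(np.asarray(self.imt_mm, dtype=float), (n_cols,)).copy()
        return imt * self.pixel_density


def _ramp(row_grid: np.ndarray, interface_rows: np.ndarray) -> np.ndarray:
    """Per-pixel blend weight: 0 above the interface, 1 below, with a
    1-px linear ramp centered on the (sub-pixel) interface row."""
    return np.clip(row_grid - (interface_rows[None, :] - 0.5), 0.0, 1.0)


def generate_phantom(spec: PhantomSpec) -> tuple[GrayImage, Boundary, Boundary]:
    """Render one phantom; returns the image and the sub-pixel GT
    boundaries (LII, MAI) covering every column."""
    n_rows, n_cols = spec.shape
    lum, inti, med, adv = spec.layer_means
    if not (lum < inti and med < adv):
        raise ValidationError("interfaces must be dark-to-bright going down")
    if not 0.0 < spec.intima_fraction < 1.0:
        raise ValidationError(f"intima_fraction must be in (0,1), got {spec.intima_fraction}")
    lii = spec.resolved_lii()
    imt_px = spec.resolved_imt_px()
    if np.any(imt_px <= 0):
        raise ValidationError("IMT profile must be positive")
    mai = lii + imt_px
    intima_bottom = lii + spec.intima_fraction * imt_px
    margin = 2.0  # room for the 1-px interface ramps
    if np.any(lii < margin) or np.any(mai > n_rows - 1 - margin):
        raise ValidationError("boundary profiles leave the image (or its ramp margin)")

    rows = np.arange(n_rows, dtype=float)[:, None]
    intima_present = np.ones(n_cols, dtype=bool)
    if spec.missing_intima:
        intima_present[:] = False
    if spec.intima_gap_cols is not None:
        a, b = spec.intima_gap_cols
        if not (0 <= a < b <= n_cols):
            raise ValidationError(f"bad intima gap interval {spec.intima_gap_cols}")
        intima_present[a:b] = False

    # Layered rendering as a sum of ramped transitions.  Where the intima
    # is absent the whole intima-media complex is echolucent (that is what
    # makes such images fail clinically), so those columns run from lumen
    # straight into the bright adventitia at the MAI.
    img = np.full((n_rows, n_cols), lum)
    img += np.where(intima_present, inti - lum, 0.0)[None, :] * _ramp(rows, lii)
    img += np.where(intima_present, med - inti, 0.0)[None, :] * _ramp(rows, intima_bottom)
    img += np.where(intima_present, adv - med, adv - lum)[None, :] * _ramp(rows, mai)

    if spec.speckle_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        if spec.noise_model == "gaussian":
            fieldv = 1.0 + spec.speckle_sigma * rng.standard_normal(img.shape)
        elif spec.noise_model == "rayleigh":
            ray = rng.rayleigh(scale=1.0, size=img.shape) * np.sqrt(2.0 / np.pi)
            fieldv = 1.0 + spec.speckle_sigma * (ray - 1.0)
        else:
            raise ValidationError(f"unknown noise model {spec.noise_model!r}")
        img = img * fieldv
    img = np.clip(img, 0.0, 1.0)
    if spec.quantize:
        img = np.rint(img * 255.0) / 255.0

    image = GrayImage(img, spec.pixel_density)
    return image, Boundary(0, lii), Boundary(0, mai)


@dataclass(frozen=True)
class CohortSample:
    """One phantom of a simulated cohort with its ground truth."""

    image: GrayImage
    gt_lii: Boundary
    gt_mai: Boundary
    gt_imt_mm: float
    spec: PhantomSpec = field(repr=False, default=None)


def gt_imt_mm(gt_lii: Boundary, gt_mai: Boundary, pixel_density: float) -> float:
    """Ground-truth IMT of a phantom: mean absolute boundary distance in mm."""
    return float(np.abs(gt_mai.rows - gt_lii.rows).mean() / pixel_density)


def generate_cohort(
    n: int,
    base_spec: PhantomSpec = PhantomSpec(),
    imt_distribution: tuple[float, float] = (0.67, 0.13),
    seed: int = 0,
    slope_range: float = 0.02,
    center_jitter_px: float = 5.0,
    missing_intima_fraction: float = 0.0,
) -> list[CohortSample]:
    """Simulate a cohort of phantoms with varying IMT and geometry.

    Per-phantom IMT is drawn from a normal distribution truncated to the
    measurable 0.2-1.6 mm range; each phantom additionally gets a random
    interface slope (uniform within ``±slope_range`` px/col) and vertical
    offset.  Sub-seeds are derived deterministically from ``seed``, so
    identical seeds reproduce identical cohorts.  A leading fraction of
    phantoms can be rendered without an intima to exercise the failure
    path.
    """
    if n < 1:
        raise ValidationError(f"cohort size must be >= 1, got {n}")
    mu, sd = imt_distribution
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    a, b = (0.2 - mu) / sd, (1.6 - mu) / sd
    imts = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)
    slopes = rng.uniform(-slope_range, slope_range, size=n)
    offsets = rng.uniform(-center_jitter_px, center_jitter_px, size=n)
    sub_seeds = [int(s) % (2**31) for s in ss.generate_state(n)]
    n_missing = int(round(missing_intima_fraction * n))

    samples = []
    n_cols = base_spec.shape[1]
    for i in range(n):
        center = (
            0.46 * base_spec.shape[0] + offsets[i]
            if base_spec.lii_row is None
            else np.asarray(base_spec.lii_row, dtype=float) + offsets[i]
        )
        profile = sloped_profile(float(np.mean(center)), slopes[i], n_cols)
        spec = replace(
            base_spec,
            lii_row=profile,
            imt_mm=float(imts[i]),
            missing_intima=(i < n_missing),
            seed=sub_seeds[i],
        )
        image, gl, gm = generate_phantom(spec)
        samples.append(CohortSample(image, gl, gm, gt_imt_mm(gl, gm, spec.pixel_density), spec))
    return samples


def write_cohort(samples: list[CohortSample], out_dir: str | Path) -> Path:
    """Write cohort phantoms as PNGs plus a ground-truth CSV; returns the
    CSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for i, s in enumerate(samples):
        name = f"phantom_{i:04d}.png"
        save_image(s.image, out_dir / name)
        records.append(
            {
                "path": name,
                "gt_imt_mm": s.gt_imt_mm,
                "pixel_density": s.image.pixel_density,
            }
        )
    csv_path = out_dir / "ground_truth.csv"
    pd.DataFrame.from_records(records).to_csv(csv_path, index=False)
    return csv_path
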