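"""IMT computation, the validity gate, and agreement statistics.

The intima-media thickness of one image is the mean absolute vertical
distance between the refined LII and MAI boundaries, converted to mm:

    IMT = (1/N) * sum_k |MAI(k) - LII(k)| / pixel_density

A measurement is accepted only when every per-column distance lies in
the physiologically plausible 0.2-1.6 mm range; boundaries that collapse
onto each other (missing intima) or fly apart (artifact capture) are
rejected rather than reported as a spurious thickness.

For cohort validation against ground truth, the module provides the
Pearson product-moment correlation and Bland-Altman agreement analysis
(bias, SD of differences, and bias ± 1.96 SD limits of agreement).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .boundary_init import Boundary
from .errors import MeasurementError, ValidationError

#: Per-column distance range (mm) outside which a measurement is rejected.
DEFAULT_VALID_RANGE_MM = (0.2, 1.6)


@dataclass(frozen=True)
class IMTResult:
    """Per-image IMT measurement with the validity verdict."""

    per_column_mm: np.ndarray
    mean_mm: float
    min_mm: float
    max_mm: float
    valid: bool
    failure_reason: str = ""

    @classmethod
    def failed(cls, reason: str) -> "IMTResult":
        return cls(np.array([]), float("nan"), float("nan"), float("nan"), False, reason)


@dataclass(frozen=True)
class AgreementStats:
    """Cohort agreement between automatic (AS) and ground-truth (GT) IMT."""

    n: int
    pearson_r: float
    bias_mm: float
    sd_mm: float
    loa_low_mm: float
    loa_high_mm: float


def compute_imt(
    lii: Boundary,
    mai: Boundary,
    pixel_density: float,
    valid_range_mm: tuple[float, float] = DEFAULT_VALID_RANGE_MM,
) -> IMTResult:
    """Measure IMT from two boundaries sharing the same column range.

    Distances are absolute, so the measurement is symmetric in its
    boundary arguments.  The gate tests the min and max per-column
    distance against ``valid_range_mm``.
    """
    if lii.n != mai.n or lii.col_start != mai.col_start:
        raise ValidationError(
            f"boundaries must share columns: ({lii.col_start}, n={lii.n}) vs "
            f"({mai.col_start}, n={mai.n})"
        )
    if not pixel_density > 0:
        raise ValidationError(f"pixel_density must be > 0, got {pixel_density}")
    dist_mm = np.abs(mai.rows - lii.rows) / pixel_density
    mean_mm = float(dist_mm.mean())
    min_mm = float(dist_mm.min())
    max_mm = float(dist_mm.max())
    lo, hi = valid_range_mm
    valid = (min_mm >= lo) and (max_mm <= hi)
    reason = ""
    if not valid:
        reason = (
            f"per-column distance range [{min_mm:.3f}, {max_mm:.3f}] mm outside "
            f"[{lo}, {hi}] mm"
        )
    return IMTResult(dist_mm, mean_mm, min_mm, max_mm, valid, reason)


def pearson_r(as_values: np.ndarray, gt_values: np.ndarray) -> float:
    """Pearson product-moment correlation between paired IMT sets."""
    a = np.asarray(as_values, dtype=float)
    g = np.asarray(gt_values, dtype=float)
    if a.shape != g.shape or a.ndim != 1 or a.size < 2:
        raise ValidationError("need two equal-length 1-D sequences of >= 2 values")
    if np.ptp(a) == 0 or np.ptp(g) == 0:
        raise MeasurementError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(a, g).statistic)


def bland_altman(as_values: np.ndarray, gt_values: np.ndarray) -> AgreementStats:
    """Bland-Altman agreement between paired IMT sets.

    bias = mean(AS - GT); sd = sample SD (n-1 denominator) of the
    differences; limits of agreement = bias ± 1.96 sd.  The Pearson
    correlation is included for convenience (NaN when undefined).
    """
    a = np.asarray(as_values, dtype=float)
    g = np.asarray(gt_values, dtype=float)
    if a.shape != g.shape or a.ndim != 1 or a.size < 2:
        raise ValidationError("need two equal-length 1-D sequences of >= 2 values")
    d = a - g
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    try:
        r = pearson_r(a, g)
    except MeasurementError:
        r = float("nan")
    return AgreementStats(
        n=a.size,
        pearson_r=r,
        bias_mm=bias,
        sd_mm=sd,
        loa_low_mm=bias - 1.96 * sd,
        loa_high_mm=bias + 1.96 * sd,
    )


def write_agreement_csv(stats_: AgreementStats, path: str | Path) -> None:
    """Write a one-row cohort agreement summary CSV."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "n": stats_.n,
                "pearson_r": stats_.pearson_r,
                "bias_mm": stats_.bias_mm,
                "sd_mm": stats_.sd_mm,
                "loa_low_mm": stats_.loa_low_mm,
                "loa_high_mm": stats_.loa_high_mm,
            }
        ]
    ).to_csv(Path(path), index=False)


def bland_altman_plot(
    as_values: np.ndarray, gt_values: np.ndarray, path: str | Path
) -> AgreementStats:
    """Save a Bland-Altman plot (difference vs pair mean) as an image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.asarray(as_values, dtype=float)
    g = np.asarray(gt_values, dtype=float)
    st = bland_altman(a, g)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + g) / 2, a - g, s=14)
    for y, style in ((st.bias_mm, "-"), (st.loa_low_mm, "--"), (st.loa_high_mm, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=0.8)
    ax.set_xlabel("mean of AS and GT IMT (mm)")
    ax.set_ylabel("AS - GT IMT (mm)")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
    return st


def scatter_plot(as_values: np.ndarray, gt_values: np.ndarray, path: str | Path) -> None:
    """Save an AS-vs-GT scatter plot with the identity line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.asarray(as_values, dtype=float)
    g = np.asarray(gt_values, dtype=float)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(g, a, s=14)
    lim = [min(g.min(), a.min()), max(g.max(), a.max())]
    ax.plot(lim, lim, "k--", linewidth=0.8)
    ax.set_xlabel("GT IMT (mm)")
    ax.set_ylabel("AS IMT (mm)")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
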