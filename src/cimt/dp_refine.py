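"""Boundary refinement by banded dynamic programming.

Both interfaces are nearly straight lines lying on strong vertical-edge
responses, so the "best boundary" maximizes a weighted sum of cumulative
edge strength and (negatively weighted) cumulative curvature:

    h(x_1..x_N) = sum_k g(x_k) + lambda * sum_{k=2}^{N-1} c(x_{k-1}, x_k, x_{k+1})

where g is the signed edge response at the boundary point, lambda <= 0,
and c is the discrete three-point curvature of Williams-Shah type: the
squared magnitude of the difference of the normalized segment vectors.

Each refinement pass lets every column move up or down by at most
``band_halfwidth`` pixels (default one) around its current position and
finds the *exact* optimum over that banded candidate set by dynamic
programming whose state is the row pair of two consecutive columns —
the pair state is what makes the three-point curvature term
stage-decomposable.  Passes are iterated until a fixed point, so an
initial boundary several pixels off is walked onto the edge ridge one
pixel per pass while each pass remains globally optimal in its band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .boundary_init import Boundary, EdgeMap
from .errors import ValidationError

Point = Sequence[float]  # (row, col)


@dataclass(frozen=True)
class DPConfig:
    """Refinement parameters.

    curvature_weight (lambda) is the non-positive weight of the
    curvature term; band_halfwidth is the per-pass vertical search band;
    squared_curvature selects the squared magnitude of the
    normalized-vector difference (the plain magnitude is available as a
    variant).
    """

    curvature_weight: float = -0.2
    band_halfwidth: int = 1
    max_passes: int = 20
    squared_curvature: bool = True

    def __post_init__(self) -> None:
        if self.curvature_weight > 0:
            raise ValidationError(
                f"curvature weight must be <= 0, got {self.curvature_weight}"
            )
        if self.band_halfwidth < 1:
            raise ValidationError(f"band_halfwidth must be >= 1, got {self.band_halfwidth}")
        if self.max_passes < 1:
            raise ValidationError(f"max_passes must be >= 1, got {self.max_passes}")


def curvature(p_prev: Point, p: Point, p_next: Point, squared: bool = True) -> float:
    """Discrete curvature of the polyline through three points.

    With v1 = p - p_prev and v2 = p_next - p, returns
    ``|| v1/|v1| - v2/|v2| ||^2`` (or its square root when
    ``squared=False``).  Zero for collinear points, maximal (4) for a
    reversal.  Consecutive coincident points have no direction and are
    rejected.
    """
    a = np.asarray(p_prev, dtype=float)
    b = np.asarray(p, dtype=float)
    c = np.asarray(p_next, dtype=float)
    v1 = b - a
    v2 = c - b
    n1 = float(np.hypot(*v1))
    n2 = float(np.hypot(*v2))
    if n1 == 0.0 or n2 == 0.0:
        raise ValidationError("coincident consecutive boundary points")
    d = v1 / n1 - v2 / n2
    sq = float(d @ d)
    return sq if squared else float(np.sqrt(sq))


def _curvature_rows(d1: np.ndarray, d2: np.ndarray, squared: bool) -> np.ndarray:
    """Vectorized curvature for boundary points on consecutive columns.

    d1, d2 are row differences across unit column spacing, so the segment
    vectors are (d1, 1) and (d2, 1) and can never be zero.
    """
    n1 = np.sqrt(d1 * d1 + 1.0)
    n2 = np.sqrt(d2 * d2 + 1.0)
    dr = d1 / n1 - d2 / n2
    dc = 1.0 / n1 - 1.0 / n2
    sq = dr * dr + dc * dc
    return sq if squared else np.sqrt(sq)


def _edge_values(boundary: Boundary, emap: EdgeMap) -> np.ndarray:
    rows = np.floor(boundary.rows + 0.5).astype(int)
    n_rows, n_cols = emap.shape
    cols = boundary.cols
    if rows.min() < 0 or rows.max() >= n_rows or cols.min() < 0 or cols.max() >= n_cols:
        raise ValidationError("boundary outside the edge map")
    return emap.values[rows, cols]


def boundary_energy(boundary: Boundary, emap: EdgeMap, cfg: DPConfig = DPConfig()) -> float:
    """Evaluate the edge-strength + weighted-curvature objective.

    Endpoints contribute edge strength only; the curvature term runs
    over interior columns.
    """
    if boundary.n < 3:
        raise ValidationError("boundary energy needs at least 3 columns")
    g = _edge_values(boundary, emap)
    rows = np.floor(boundary.rows + 0.5)
    diffs = np.diff(rows)
    curv = _curvature_rows(diffs[:-1], diffs[1:], cfg.squared_curvature)
    return float(g.sum() + cfg.curvature_weight * curv.sum())


def _candidate_rows(boundary: Boundary, emap: EdgeMap, b: int) -> list[np.ndarray]:
    """Per-column candidate rows: current row ± band, clipped in-bounds,
    deduplicated, ascending."""
    n_rows = emap.shape[0]
    base = np.floor(boundary.rows + 0.5).astype(int)
    return [
        np.unique(np.clip(r + np.arange(-b, b + 1), 0, n_rows - 1)) for r in base
    ]


def dp_pass(boundary: Boundary, emap: EdgeMap, cfg: DPConfig = DPConfig()) -> Boundary:
    """One exact banded optimization pass.

    Maximizes the objective over all boundaries whose column-k row lies
    within ``band_halfwidth`` of the current one, via dynamic programming
    on consecutive-row-pair states.  Among equal-energy optima the
    lexicographically smallest row sequence is returned, realized by a
    backward value recursion followed by a greedy forward selection that
    always takes the smallest row consistent with an optimal completion.
    """
    n = boundary.n
    if n < 3:
        raise ValidationError("dp_pass needs at least 3 columns")
    lam = cfg.curvature_weight
    cand = _candidate_rows(boundary, emap, cfg.band_halfwidth)
    cols = boundary.cols
    g = [emap.values[c, col] for c, col in zip(cand, cols)]

    # Backward recursion: value[k][a, b] = best energy of columns k..N-1
    # given rows (a at k-1, b at k), counting g from column k on and all
    # curvature terms centered at columns >= k.
    value: list[np.ndarray | None] = [None] * n
    value[n - 1] = np.broadcast_to(g[n - 1][None, :], (cand[n - 2].size, cand[n - 1].size)).copy()
    for k in range(n - 2, 0, -1):
        a = cand[k - 1][:, None, None].astype(float)
        b = cand[k][None, :, None].astype(float)
        c = cand[k + 1][None, None, :].astype(float)
        curv = _curvature_rows(b - a, c - b, cfg.squared_curvature)
        total = lam * curv + value[k + 1][None, :, :]
        value[k] = g[k][None, :] + total.max(axis=2)

    start = g[0][:, None] + value[1]
    best = start.max()
    # Row-major argwhere over ascending candidate lists -> lexicographic min.
    i, j = np.argwhere(start == best)[0]
    chosen = [int(cand[0][i]), int(cand[1][j])]
    ai, bi = int(i), int(j)
    for k in range(1, n - 1):
        a = float(cand[k - 1][ai])
        b = float(cand[k][bi])
        c = cand[k + 1].astype(float)
        vals = lam * _curvature_rows(b - a, c - b, cfg.squared_curvature) + value[k + 1][bi, :]
        ci = int(np.flatnonzero(vals == vals.max())[0])
        chosen.append(int(cand[k + 1][ci]))
        ai, bi = bi, ci
    return Boundary(boundary.col_start, np.array(chosen, dtype=np.float64))


def refine(
    boundary: Boundary, emap: EdgeMap, cfg: DPConfig = DPConfig()
) -> tuple[Boundary, list[float]]:
    """Iterate :func:`dp_pass` to a fixed point (or ``max_passes``).

    The current boundary is always inside its own band, so the energy is
    non-decreasing across passes; this is asserted defensively.  Returns
    the refined boundary and the per-pass energy trace (starting energy
    first).
    """
    current = boundary.rounded()
    energies = [boundary_energy(current, emap, cfg)]
    for _ in range(cfg.max_passes):
        nxt = dp_pass(current, emap, cfg)
        e = boundary_energy(nxt, emap, cfg)
        if e < energies[-1] - 1e-9:
            raise RuntimeError(
                f"energy decreased across a refinement pass ({energies[-1]} -> {e})"
            )
        if np.array_equal(nxt.rows, current.rows):
            break
        current = nxt
        energies.append(e)
    return current, energies
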