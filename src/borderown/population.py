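"""Population-level comparison of natural-scene and square signals.

Each cell contributes a point (x, y): its normalized square-test effect and
its normalized natural-scene effect (full, patch, or context).  Because the
sign assigned to a cell's preferred side is arbitrary, any analysis must be
invariant to reflecting individual points through the origin; the relative
strength of the two signals is therefore summarized by a line through the
origin fitted by orthogonal (total) least squares, whose slope is invariant
under such reflections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from borderown.effects import EffectEstimate


@dataclass
class SlopeFit:
    """Through-origin orthogonal-regression slope with bootstrap CI."""

    slope: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_cells: int = 0
    degenerate: bool = False
    infinite: bool = False


def scatter_points(
    effects: list[EffectEstimate], kind: str = "full", canonicalize: bool = True
) -> np.ndarray:
    """Per-cell (square, scene-kind) normalized effect pairs.

    With ``canonicalize`` the pair is jointly reflected through the origin
    so the square effect is non-negative (cosmetic; slope-invariant).
    """
    pts = np.array(
        [[e.square_norm, getattr(e, f"{kind}_norm")] for e in effects], dtype=float
    )
    if canonicalize and len(pts):
        flip = np.where(pts[:, 0] < 0, -1.0, 1.0)
        pts = pts * flip[:, None]
    return pts


def orthogonal_slope_through_origin(points: np.ndarray) -> SlopeFit:
    """Slope of the through-origin line minimizing total squared orthogonal
    distance: the leading eigenvector of the uncentered second-moment matrix.

    Invariant under reflection of any subset of points through the origin.
    An isotropic moment matrix is reported as slope 1 with ``degenerate``
    set; a vertical optimum as ``infinite``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need at least 2 (x, y) points")
    if not np.any(pts):
        raise ValueError("all points at the origin; slope undefined")
    S = pts.T @ pts
    evals, evecs = np.linalg.eigh(S)
    if np.isclose(evals[0], evals[1], rtol=1e-12, atol=1e-12 * max(evals[1], 1.0)):
        return SlopeFit(slope=1.0, n_cells=len(pts), degenerate=True)
    v = evecs[:, -1]  # leading eigenvector
    if abs(v[0]) < 1e-12:
        return SlopeFit(slope=np.inf, n_cells=len(pts), infinite=True)
    return SlopeFit(slope=float(v[1] / v[0]), n_cells=len(pts))


def absolute_orthogonal_slope(points: np.ndarray, n_grid: int = 3142) -> float:
    """Through-origin slope minimizing total *absolute* orthogonal deviation
    (grid search over line angle); provided as a robustness check."""
    pts = np.asarray(points, dtype=float)
    angles = np.linspace(0.0, np.pi, n_grid, endpoint=False)
    normals = np.stack([-np.sin(angles), np.cos(angles)])  # unit normal per angle
    cost = np.abs(pts @ normals).sum(axis=0)
    best = angles[int(np.argmin(cost))]
    return float(np.tan(best))


def bootstrap_slope_ci(
    points: np.ndarray, B: int = 1000, seed=0, level: float = 0.95
) -> SlopeFit:
    """Percentile bootstrap CI for the orthogonal slope, resampling cells
    with replacement."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pts = np.asarray(points, dtype=float)
    fit = orthogonal_slope_through_origin(pts)
    n = len(pts)
    slopes = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            slopes[b] = orthogonal_slope_through_origin(pts[idx]).slope
        except ValueError:
            slopes[b] = np.nan
    lo, hi = np.nanpercentile(slopes, [50 * (1 - level), 50 * (1 + level)])
    return SlopeFit(
        slope=fit.slope,
        ci_low=float(lo),
        ci_high=float(hi),
        n_cells=n,
        degenerate=fit.degenerate,
        infinite=fit.infinite,
    )


def preference_consistency(
    effects: list[EffectEstimate],
    kind: str = "context",
    alpha: float = 0.01,
) -> tuple[float, int, int]:
    """Among cells significant in both the square test and the scene-kind
    test, the fraction whose effects have the same sign.

    Returns ``(proportion, n_consistent, n_both_significant)``.
    """
    n_both = n_same = 0
    for e in effects:
        p_kind = getattr(e, f"p_{kind}")
        if e.p_square < alpha and p_kind < alpha:
            n_both += 1
            if np.sign(getattr(e, kind)) == np.sign(e.square):
                n_same += 1
    prop = n_same / n_both if n_both else np.nan
    return prop, n_same, n_both


def rotation_invariance_check(cells) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test of per-cell mean transformed
    counts, upright (original side) vs rotated displays.

    Returns ``(statistic, p)``.  A non-significant result supports pooling
    data collected with upright and rotated presentation schemes.
    """
    from borderown.effects import prepare_counts

    upright, rotated = [], []
    for cell in cells:
        tab = prepare_counts(cell)
        sc = tab[tab["test"] == "scene"]
        upright.append(sc.loc[sc["side"] == "original", "y"].mean())
        rotated.append(sc.loc[sc["side"] == "rotated", "y"].mean())
    res = stats.wilcoxon(upright, rotated, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
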