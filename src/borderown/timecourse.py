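"""Population time-course analysis and two-phase-regression latencies.

Latencies of response onset and of border-ownership signals are estimated
from cumulative spike-count curves at 1-ms resolution, pooled over cells
and presentations:

- *onset*: total counts (preferred + nonpreferred side), cumulated over
  0–80 ms, two free regression legs;
- *border-ownership* (full, patch, or square): preferred minus nonpreferred
  counts, cumulated over 30–150 ms, first leg forced to zero (the two
  conditions cancel before the signal exists);
- *context*: the full-condition differential minus the patch-condition
  differential, same window, first leg forced to zero.

The two-phase fit grid-searches integer-ms breakpoints, fits a line to each
side (without imposing continuity at the breakpoint), and defines the
latency as the intersection of the two legs.  Bootstrap SDs resample
presentations with replacement within cell and condition, keeping the
number of presentations fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from borderown.simulate import TRIAL_MS, CellDataset

WINDOWS = {
    "onset": (0, 80),
    "bo_full": (30, 150),
    "bo_patch": (30, 150),
    "bo_square": (30, 150),
    "context": (30, 150),
}
FORCE_ZERO = {
    "onset": False,
    "bo_full": True,
    "bo_patch": True,
    "bo_square": True,
    "context": True,
}


# ---------------------------------------------------------------------------
# PSTHs


@dataclass
class PSTH:
    """Population spike-rate histogram in 1-ms bins over [0, 300) ms."""

    rate_hz: np.ndarray
    n_presentations: int
    smoothed: bool = False
    span: float | None = None

    def __post_init__(self):
        if len(self.rate_hz) != TRIAL_MS:
            raise ValueError(f"PSTH must have {TRIAL_MS} bins")


def estimate_pref_signs(cells) -> dict[str, int]:
    """Per-cell preferred-side sign (+1: 'original') from the square test's
    transformed-count marginal difference."""
    from borderown.effects import marginal_mean_diff, prepare_counts

    signs = {}
    for cell in cells:
        tab = prepare_counts(cell)
        sq = tab[tab["test"] == "square"]
        d = marginal_mean_diff(sq, others=["polarity", "size_deg"])
        signs[cell.cell_id] = 1 if d >= 0 else -1
    return signs


def _trial_selection(cell: CellDataset, kind: str, pref_sign: int):
    """Boolean mask of contributing trials and their +/-1 pooling signs."""
    t = cell.trials
    is_scene = t["test"] == "scene"
    side_sign = np.where(
        (t["side"] == "original") == (pref_sign == 1), 1.0, -1.0
    )
    if kind == "onset":
        mask = is_scene & (t["extent"] == "full")
        signs = np.ones(len(t))
    elif kind == "bo_full":
        mask = is_scene & (t["extent"] == "full")
        signs = side_sign
    elif kind == "bo_patch":
        mask = is_scene & (t["extent"] == "patch")
        signs = side_sign
    elif kind == "bo_square":
        mask = (t["test"] == "square").to_numpy()
        signs = side_sign
    elif kind == "context":
        mask = is_scene.to_numpy()
        signs = side_sign * np.where(t["extent"] == "full", 1.0, -1.0)
    else:
        raise ValueError(f"unknown curve kind {kind!r}")
    return np.asarray(mask, dtype=bool), signs


def population_psth(
    cells,
    kind: str = "onset",
    pref_signs: dict | None = None,
) -> PSTH:
    """Pooled per-ms firing rate (Hz per presentation) for a condition kind.

    For differential kinds the value is the signed pooled count per
    presentation-pair, expressed in Hz.
    """
    if pref_signs is None:
        pref_signs = estimate_pref_signs(cells)
    total = np.zeros(TRIAL_MS)
    n_pres = 0
    for cell in cells:
        mask, signs = _trial_selection(cell, kind, pref_signs[cell.cell_id])
        total += (signs[mask, None] * cell.spikes[mask]).sum(axis=0)
        n_pres += int(mask.sum())
    denom = n_pres if kind == "onset" else max(n_pres // 2, 1)
    return PSTH(rate_hz=total / denom * 1000.0, n_presentations=n_pres)


def lowess_smooth(psth: PSTH, span: float = 0.12) -> PSTH:
    """Lowess smoothing of the PSTH (span = fraction of bins per window)."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    t = np.arange(TRIAL_MS) + 0.5
    sm = lowess(psth.rate_hz, t, frac=span, return_sorted=False)
    return PSTH(
        rate_hz=sm, n_presentations=psth.n_presentations, smoothed=True, span=span
    )


# ---------------------------------------------------------------------------
# cumulative curves


@dataclass
class CumulativeCurve:
    """Cumulative pooled spike count at 1-ms resolution over a window."""

    t: np.ndarray
    y: np.ndarray
    kind: str
    n_presentations: int


def pooled_histogram(cells, kind: str, pref_signs: dict | None = None):
    """Per-ms pooled (signed) spike counts over the whole 300-ms trial."""
    if pref_signs is None:
        pref_signs = estimate_pref_signs(cells)
    total = np.zeros(TRIAL_MS)
    n_pres = 0
    for cell in cells:
        mask, signs = _trial_selection(cell, kind, pref_signs[cell.cell_id])
        total += (signs[mask, None] * cell.spikes[mask]).sum(axis=0)
        n_pres += int(mask.sum())
    return total, n_pres


def cumulative_curve(
    cells, kind: str, pref_signs: dict | None = None
) -> CumulativeCurve:
    """Cumulative spike-count curve for a condition kind over its window."""
    hist, n_pres = pooled_histogram(cells, kind, pref_signs)
    lo, hi = WINDOWS[kind]
    t = np.arange(lo, hi + 1, dtype=float)
    # y[i] = spikes with lo <= time < t[i], so a rate change at tau puts the
    # slope change exactly at t = tau
    y = np.concatenate([[0.0], np.cumsum(hist[lo:hi])])
    return CumulativeCurve(t=t, y=y, kind=kind, n_presentations=n_pres)


# ---------------------------------------------------------------------------
# two-phase regression


@dataclass
class TwoPhaseFit:
    """Two straight legs with a grid-searched breakpoint; the latency is the
    legs' intersection (continuity at the breakpoint is not imposed)."""

    latency_ms: float
    breakpoint_ms: float
    leg1: tuple[float, float]  # (slope, intercept); (0, 0) when forced
    leg2: tuple[float, float]
    ss: float
    forced_zero: bool
    no_onset: bool = False


def _segment_stats(t: np.ndarray, Y: np.ndarray):
    """Prefix sums for closed-form line fits on every [0..i] and [i..n-1]."""
    n = len(t)
    ones = np.ones(n)
    c = {
        "n": np.cumsum(ones),
        "t": np.cumsum(t),
        "tt": np.cumsum(t * t),
        "y": np.cumsum(Y, axis=-1),
        "ty": np.cumsum(t * Y, axis=-1),
        "yy": np.cumsum(Y * Y, axis=-1),
    }
    return c


def _line_fit(S0, S1, S2, Sy, Sty, Syy):
    det = S0 * S2 - S1 * S1
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (S0 * Sty - S1 * Sy) / det
        b = (Sy - a * S1) / S0
    ss = Syy - a * Sty - b * Sy
    return a, b, np.clip(ss, 0.0, None)


def _two_phase_grid(t: np.ndarray, Y: np.ndarray, force_zero: bool):
    """Vectorized two-phase fit of each row of Y against t.

    Returns (latency, breakpoint, leg1, leg2, ss, no_onset) arrays.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = len(t)
    if n < 10:
        raise ValueError("window too short for two-phase regression")
    c = _segment_stats(t, Y)
    idx = np.arange(2, n - 2)  # candidate breakpoints, >=3 points per leg

    # left leg over [0..i]
    L = {k: c[k][..., idx] for k in c}
    if force_zero:
        a1 = b1 = np.zeros((Y.shape[0], len(idx)))
        ss1 = L["yy"]
    else:
        a1, b1, ss1 = _line_fit(L["n"], L["t"], L["tt"], L["y"], L["ty"], L["yy"])

    # right leg over [i..n-1] (breakpoint sample shared)
    tot = {k: c[k][..., -1:] for k in c}
    R = {k: tot[k] - c[k][..., idx - 1] for k in c}
    a2, b2, ss2 = _line_fit(R["n"], R["t"], R["tt"], R["y"], R["ty"], R["yy"])

    ss_tot = ss1 + ss2
    best = np.nanargmin(ss_tot, axis=-1)
    rows = np.arange(Y.shape[0])
    bp = t[idx[best]]
    if force_zero:
        A1 = np.zeros(Y.shape[0])
        B1 = np.zeros(Y.shape[0])
    else:
        A1, B1 = a1[rows, best], b1[rows, best]
    A2, B2 = a2[rows, best], b2[rows, best]
    SS = ss_tot[rows, best]

    with np.errstate(divide="ignore", invalid="ignore"):
        lat = np.where(
            np.abs(A1 - A2) > 1e-12, (B2 - B1) / (A1 - A2), np.nan
        )

    # single free line over the whole window, for the no-onset check
    aL, bL, ssL = _line_fit(
        c["n"][-1], c["t"][-1], c["tt"][-1], c["y"][..., -1], c["ty"][..., -1], c["yy"][..., -1]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        improvement = np.where(ssL > 0, (ssL - SS) / ssL, 0.0)
    no_onset = improvement <= 0.01
    return lat, bp, (A1, B1), (A2, B2), SS, no_onset


def two_phase_fit(
    curve: CumulativeCurve | tuple, force_zero_first_leg: bool = False
) -> TwoPhaseFit:
    """Two-phase regression of one cumulative curve."""
    if isinstance(curve, CumulativeCurve):
        t, y = curve.t, curve.y
    else:
        t, y = curve
        t = np.asarray(t, dtype=float)
    lat, bp, (a1, b1), (a2, b2), ss, no_onset = _two_phase_grid(
        t, y, force_zero_first_leg
    )
    return TwoPhaseFit(
        latency_ms=float(lat[0]),
        breakpoint_ms=float(bp[0]),
        leg1=(float(a1[0]), float(b1[0])),
        leg2=(float(a2[0]), float(b2[0])),
        ss=float(ss[0]),
        forced_zero=force_zero_first_leg,
        no_onset=bool(no_onset[0]),
    )


def latency(cells, kind: str, pref_signs: dict | None = None) -> TwoPhaseFit:
    """Pooled-population two-phase latency for a condition kind."""
    curve = cumulative_curve(cells, kind, pref_signs)
    return two_phase_fit(curve, force_zero_first_leg=FORCE_ZERO[kind])


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class LatencyEstimate:
    """A latency with its presentation-bootstrap standard deviation."""

    kind: str
    latency_ms: float
    sd_ms: float
    n_boot: int
    n_valid: int


def _condition_groups(trials: pd.DataFrame) -> list[np.ndarray]:
    cols = ["test", "scene_id", "size_deg", "side", "polarity", "extent"]
    return [
        idx.to_numpy()
        for _, idx in trials.groupby(cols, dropna=False, observed=True).groups.items()
    ]


def latency_bootstrap_sd(
    cells,
    kind: str,
    B: int = 1000,
    seed=0,
    pref_signs: dict | None = None,
) -> LatencyEstimate:
    """Bootstrap SD of the pooled latency, resampling presentations with
    replacement within cell and condition (presentation counts preserved).

    Uses multinomial presentation weights so each replicate's pooled
    histogram is a single weighted sum over trials.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if pref_signs is None:
        pref_signs = estimate_pref_signs(cells)
    point = latency(cells, kind, pref_signs)

    lo, hi = WINDOWS[kind]
    hists = np.zeros((B, hi - lo + 1))
    for cell in cells:
        mask, signs = _trial_selection(cell, kind, pref_signs[cell.cell_id])
        sub_idx = np.flatnonzero(mask)
        if len(sub_idx) == 0:
            continue
        spikes = cell.spikes[sub_idx, lo : hi + 1].astype(float)
        signed = signs[sub_idx, None] * spikes
        groups = _condition_groups(cell.trials.loc[sub_idx])
        pos = {g: i for i, g in enumerate(sub_idx)}
        W = np.zeros((B, len(sub_idx)))
        for g in groups:
            cols = [pos[j] for j in g]
            W[:, cols] = rng.multinomial(len(g), np.full(len(g), 1.0 / len(g)), size=B)
        hists += W @ signed

    Y = np.cumsum(hists, axis=1)
    t = np.arange(lo, hi + 1, dtype=float)
    lat, *_ , no_onset = _two_phase_grid(t, Y, FORCE_ZERO[kind])
    valid = np.isfinite(lat)
    sd = float(np.std(lat[valid], ddof=1)) if valid.sum() > 1 else float("nan")
    return LatencyEstimate(
        kind=kind,
        latency_ms=point.latency_ms,
        sd_ms=sd,
        n_boot=B,
        n_valid=int(valid.sum()),
    )


def latency_table(cells, kinds=None, B: int = 200, seed=0) -> pd.DataFrame:
    """Latency summary across condition kinds with bootstrap SDs."""
    kinds = kinds or ["onset", "bo_full", "bo_patch", "context"]
    pref = estimate_pref_signs(cells)
    rows = []
    for kind in kinds:
        est = latency_bootstrap_sd(cells, kind, B=B, seed=seed, pref_signs=pref)
        rows.append((kind, est.latency_ms, est.sd_ms, est.n_boot))
    return pd.DataFrame(rows, columns=["kind", "latency_ms", "sd_ms", "n_boot"])
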