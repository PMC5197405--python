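"""Per-cell spike-count statistics and factorial effect models.

Spike counts in the 40–300 ms window are variance-stabilized with the
Anscombe transform sqrt(x + 3/8), then analyzed per cell with fixed-effects
ordinary-least-squares factorial models including all interactions:

- square test: border-ownership side x edge-contrast polarity x square size;
- natural scenes: side x polarity x extent (full/patch) x scene ID.

Per-term significance uses Type-II sums of squares (marginality-respecting
model comparison, F against the full-model residual), which on balanced
data coincide with classical balanced-ANOVA sums of squares.

Border-ownership *effects* are preferred-minus-nonpreferred marginal-mean
differences on the transformed scale; the context effect is the full-image
effect minus the patch effect (equivalently the side x extent interaction).
Each cell's effects are normalized by the square root of its square-model
residual variance, so they are expressed in multiples of the SD of its
trial-to-trial response variability.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from borderown.simulate import CellDataset

ALPHA = 0.01
COUNT_WINDOW = (40.0, 300.0)


def count_window(train, t_lo: float = 40.0, t_hi: float = 300.0) -> int:
    """Number of spikes with ``t_lo <= t < t_hi`` (ms)."""
    t = np.asarray(train, dtype=float)
    return int(np.count_nonzero((t >= t_lo) & (t < t_hi)))


def anscombe(x):
    """Variance-stabilizing transform sqrt(x + 3/8) for Poisson counts."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    return np.sqrt(x + 0.375)


def omi(r_pref: float, r_orth: float) -> float:
    """Orientation modulation index (R_pref - R_orth) / (R_pref + R_orth)."""
    if r_pref < 0 or r_orth < 0:
        raise ValueError("mean responses must be non-negative")
    total = r_pref + r_orth
    if total == 0:
        raise ValueError("both responses are zero; OMI undefined")
    return (r_pref - r_orth) / total


def filter_orientation_selective(cells, omis=None, min_omi: float = 0.20):
    """Keep cells with orientation modulation index of at least ``min_omi``.

    ``omis`` may be a sequence aligned with ``cells``; by default the
    generator's ``params.omi_value`` is used.
    """
    cells = list(cells)
    if omis is None:
        omis = [c.params.omi_value for c in cells]
    return [c for c, v in zip(cells, omis) if v >= min_omi]


# ---------------------------------------------------------------------------
# factorial model


@dataclass
class FactorialFit:
    """OLS fit of a full-factorial model with Type-II per-term tests."""

    factors: list[str]
    levels: dict[str, list]
    table: pd.DataFrame  # one row per trial: factor columns + response
    response: str
    anova: pd.DataFrame  # index: term; columns: ss, df, F, p
    coef: np.ndarray
    term_slices: dict[tuple, slice]
    design: np.ndarray
    residual_var: float
    df_resid: int

    @property
    def fitted(self) -> np.ndarray:
        return self.design @ self.coef

    def fitted_excluding(self, factor: str) -> np.ndarray:
        """Fitted values with the coefficients of every term containing
        ``factor`` set to zero (the surrogate-null mean structure)."""
        beta = self.coef.copy()
        for term, sl in self.term_slices.items():
            if factor in term:
                beta[sl] = 0.0
        return self.design @ beta

    def p_value(self, *factors: str) -> float:
        """Type-II p-value of a main effect or interaction term."""
        key = ":".join(sorted(factors))
        return float(self.anova.loc[key, "p"])


def _coding_columns(values: np.ndarray, levels: list) -> np.ndarray:
    """Sum-to-zero (deviation) coding: L-1 columns; last level codes -1."""
    n = len(values)
    cols = np.zeros((n, len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[:, j] = np.where(values == lev, 1.0, 0.0)
    cols[values == levels[-1]] = -1.0
    return cols


def _interaction(cols_list) -> np.ndarray:
    out = cols_list[0]
    for cols in cols_list[1:]:
        out = (out[:, :, None] * cols[:, None, :]).reshape(len(out), -1)
    return out


def fit_factorial(
    table: pd.DataFrame,
    factors: list[str],
    response: str = "y",
    _force_general: bool = False,
) -> FactorialFit:
    """Fit the all-interactions fixed-effects model and compute Type-II SS.

    For each term T, the Type-II sum of squares is the residual-SS drop when
    T joins the model containing every term that does not include T; F uses
    the full model's residual variance (the classical marginality-respecting
    comparison).  Raises on rank-deficient designs, naming aliased terms.
    """
    y = table[response].to_numpy(dtype=float)
    n = len(y)
    levels = {f: sorted(pd.unique(table[f])) for f in factors}
    for f in factors:
        if len(levels[f]) < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    main_cols = {f: _coding_columns(table[f].to_numpy(), levels[f]) for f in factors}

    terms: list[tuple] = []
    for k in range(1, len(factors) + 1):
        terms.extend(itertools.combinations(factors, k))

    blocks = {t: _interaction([main_cols[f] for f in t]) for t in terms}
    intercept = np.ones((n, 1))

    # assemble full design
    slices: dict[tuple, slice] = {}
    parts = [intercept]
    start = 1
    for t in terms:
        b = blocks[t]
        slices[t] = slice(start, start + b.shape[1])
        parts.append(b)
        start += b.shape[1]
    X = np.hstack(parts)

    # On a complete balanced design the term subspaces are mutually
    # orthogonal under sum-to-zero coding, so every SS type coincides and
    # each term's SS is a plain projection — orders of magnitude faster
    # than nested model comparisons for many-level factors.
    sizes = table.groupby(factors, observed=True).size()
    n_cells_expected = int(np.prod([len(levels[f]) for f in factors]))
    if not _force_general and len(sizes) == n_cells_expected and sizes.nunique() == 1:
        return _fit_balanced(
            table, factors, response, y, levels, terms, blocks, slices, X
        )

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = []
        acc = intercept
        for t in terms:
            cand = np.hstack([acc, blocks[t]])
            if np.linalg.matrix_rank(cand) < acc.shape[1] + blocks[t].shape[1]:
                aliased.append(":".join(t))
            acc = cand
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")

    rss_cache: dict[frozenset, float] = {}

    def rss(included: frozenset) -> float:
        if included not in rss_cache:
            Xs = np.hstack([intercept] + [blocks[t] for t in terms if t in included])
            beta, res, *_ = np.linalg.lstsq(Xs, y, rcond=None)
            r = y - Xs @ beta
            rss_cache[included] = float(r @ r)
        return rss_cache[included]

    all_terms = frozenset(terms)
    beta_full, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_full
    rss_full = float(resid @ resid)
    df_resid = n - X.shape[1]
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom (need replicates)")
    s2 = rss_full / df_resid

    rows = []
    for t in terms:
        tset = set(t)
        excluded_relatives = {s for s in terms if tset < set(s)}
        base = frozenset(all_terms - excluded_relatives - {t})
        ss = max(rss(base) - rss(base | {t}), 0.0)
        df_t = int(np.prod([len(levels[f]) - 1 for f in t]))
        F, p = _f_and_p(ss, df_t, s2, df_resid)
        rows.append((":".join(sorted(t)), ss, df_t, F, p))
    anova = pd.DataFrame(rows, columns=["term", "ss", "df", "F", "p"]).set_index("term")

    return FactorialFit(
        factors=list(factors),
        levels=levels,
        table=table.reset_index(drop=True),
        response=response,
        anova=anova,
        coef=beta_full,
        term_slices=slices,
        design=X,
        residual_var=s2,
        df_resid=df_resid,
    )


def _f_and_p(ss: float, df_t: int, s2: float, df_resid: int) -> tuple[float, float]:
    """F and p, tolerating a zero residual variance (noise-free fixtures)."""
    if s2 == 0.0:
        return (np.inf, 0.0) if ss > 0 else (0.0, 1.0)
    F = (ss / df_t) / s2
    return F, float(stats.f.sf(F, df_t, df_resid))


def _fit_balanced(table, factors, response, y, levels, terms, blocks, slices, X):
    """Projection-based fit for complete balanced designs (see above)."""
    from scipy.linalg import solve_triangular

    n = len(y)
    ybar = float(y.mean())
    yy = float(y @ y)
    coef = np.zeros(X.shape[1])
    coef[0] = ybar
    ss_terms = {}
    for t in terms:
        Q, R = np.linalg.qr(blocks[t])
        qty = Q.T @ y
        ss_terms[t] = float(qty @ qty)
        coef[slices[t]] = solve_triangular(R, qty)
    rss = yy - n * ybar**2 - sum(ss_terms.values())
    df_model = sum(b.shape[1] for b in blocks.values())
    df_resid = n - 1 - df_model
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom (need replicates)")
    s2 = max(rss, 0.0) / df_resid
    rows = []
    for t in terms:
        df_t = blocks[t].shape[1]
        F, p = _f_and_p(ss_terms[t], df_t, s2, df_resid)
        rows.append((":".join(sorted(t)), ss_terms[t], df_t, F, p))
    anova = pd.DataFrame(rows, columns=["term", "ss", "df", "F", "p"]).set_index("term")
    return FactorialFit(
        factors=list(factors),
        levels=levels,
        table=table.reset_index(drop=True),
        response=response,
        anova=anova,
        coef=coef,
        term_slices=slices,
        design=X,
        residual_var=s2,
        df_resid=df_resid,
    )


# ---------------------------------------------------------------------------
# effect extraction


def marginal_mean_diff(
    table: pd.DataFrame,
    y: str = "y",
    factor: str = "side",
    hi="original",
    lo="rotated",
    others: list[str] | None = None,
) -> float:
    """Marginal-mean difference ``hi - lo``: condition-cell means averaged
    with equal weight over the other factors, then differenced."""
    if others is None:
        others = [c for c in table.columns if c not in (factor, y)]
    cells = table.groupby([factor] + others, observed=True)[y].mean()
    marg = cells.groupby(level=0, observed=True).mean()
    return float(marg[hi] - marg[lo])


def _diff_se(s2: float, n_hi: int, n_lo: int) -> float:
    return float(np.sqrt(s2 * (1.0 / n_hi + 1.0 / n_lo)))


@dataclass
class CellFits:
    """The two factorial fits for one cell, on transformed counts."""

    cell_id: str
    square: FactorialFit
    scene: FactorialFit
    full_only: FactorialFit
    patch_only: FactorialFit


@dataclass
class EffectEstimate:
    """Per-cell border-ownership effects on the Anscombe scale.

    Effects are in the original-minus-rotated (side A - side B) convention;
    ``preferred_side`` (+1/-1) is the sign of the square effect, anchoring
    the cell's sign convention.  ``*_norm`` are divided by the square-model
    residual SD.
    """

    cell_id: str
    square: float
    full: float
    patch: float
    context: float
    se_square: float
    se_full: float
    se_patch: float
    se_context: float
    p_square: float
    p_full: float
    p_patch: float
    p_context: float
    p_scene_bo: float
    preferred_side: int
    resid_var_square: float
    square_by_size: dict = field(default_factory=dict)

    @property
    def norm_scale(self) -> float:
        return float(np.sqrt(self.resid_var_square))

    def _norm(self, v: float) -> float:
        return v / self.norm_scale

    @property
    def square_norm(self) -> float:
        return self._norm(self.square)

    @property
    def full_norm(self) -> float:
        return self._norm(self.full)

    @property
    def patch_norm(self) -> float:
        return self._norm(self.patch)

    @property
    def context_norm(self) -> float:
        return self._norm(self.context)


def prepare_counts(cell: CellDataset) -> pd.DataFrame:
    """Trial table with raw 40–300 ms counts and Anscombe-transformed ``y``."""
    table = cell.trials.copy()
    table["count"] = cell.counts(*COUNT_WINDOW)
    table["y"] = anscombe(table["count"])
    return table


def fit_cell(cell: CellDataset) -> CellFits:
    """Fit the square-test 3-way model, the natural-scene 4-way model, and
    the extent-restricted 3-way models for one cell."""
    table = prepare_counts(cell)
    sq = table[table["test"] == "square"]
    sc = table[table["test"] == "scene"]
    square = fit_factorial(sq[["side", "polarity", "size_deg", "y"]], ["side", "polarity", "size_deg"])
    scene = fit_factorial(
        sc[["side", "polarity", "extent", "scene_id", "y"]],
        ["side", "polarity", "extent", "scene_id"],
    )
    full_only = fit_factorial(
        sc.loc[sc["extent"] == "full", ["side", "polarity", "scene_id", "y"]],
        ["side", "polarity", "scene_id"],
    )
    patch_only = fit_factorial(
        sc.loc[sc["extent"] == "patch", ["side", "polarity", "scene_id", "y"]],
        ["side", "polarity", "scene_id"],
    )
    return CellFits(cell.cell_id, square, scene, full_only, patch_only)


def extract_effects(
    fits: CellFits, size_average: str = "mean"
) -> EffectEstimate:
    """Border-ownership effects from the fitted models.

    ``size_average='mean'`` averages the two size-specific square contrasts
    (default); ``'pooled'`` uses the pooled-model marginal difference (they
    coincide on balanced data).
    """
    sq_tab = fits.square.table
    by_size = {
        float(s): marginal_mean_diff(sub, others=["polarity"])
        for s, sub in sq_tab.groupby("size_deg", observed=True)
    }
    if size_average == "mean":
        square_eff = float(np.mean(list(by_size.values())))
    elif size_average == "pooled":
        square_eff = marginal_mean_diff(sq_tab, others=["polarity", "size_deg"])
    else:
        raise ValueError("size_average must be 'mean' or 'pooled'")

    sc_tab = fits.scene.table
    full_tab = sc_tab[sc_tab["extent"] == "full"]
    patch_tab = sc_tab[sc_tab["extent"] == "patch"]
    full_eff = marginal_mean_diff(full_tab, others=["polarity", "scene_id"])
    patch_eff = marginal_mean_diff(patch_tab, others=["polarity", "scene_id"])

    s2_sq = fits.square.residual_var
    s2_sc = fits.scene.residual_var
    n_side_sq = (sq_tab["side"] == "original").sum()
    n_side_full = (full_tab["side"] == "original").sum()
    n_side_patch = (patch_tab["side"] == "original").sum()
    se_full = _diff_se(s2_sc, n_side_full, len(full_tab) - n_side_full)
    se_patch = _diff_se(s2_sc, n_side_patch, len(patch_tab) - n_side_patch)

    return EffectEstimate(
        cell_id=fits.cell_id,
        square=square_eff,
        full=full_eff,
        patch=patch_eff,
        context=full_eff - patch_eff,
        se_square=_diff_se(s2_sq, n_side_sq, len(sq_tab) - n_side_sq),
        se_full=se_full,
        se_patch=se_patch,
        se_context=float(np.hypot(se_full, se_patch)),
        p_square=fits.square.p_value("side"),
        p_full=fits.full_only.p_value("side"),
        p_patch=fits.patch_only.p_value("side"),
        p_context=fits.scene.p_value("side", "extent"),
        p_scene_bo=fits.scene.p_value("side"),
        preferred_side=1 if square_eff >= 0 else -1,
        resid_var_square=s2_sq,
        square_by_size=by_size,
    )


def cell_effects(cell: CellDataset, **kwargs) -> EffectEstimate:
    """Convenience: fit both models and extract effects for one cell."""
    return extract_effects(fit_cell(cell), **kwargs)


def classify_significance(effects: EffectEstimate, alpha: float = ALPHA) -> dict:
    """Significance flags at the study threshold (default p < 0.01)."""
    return {
        "square": effects.p_square < alpha,
        "full": effects.p_full < alpha,
        "patch": effects.p_patch < alpha,
        "context": effects.p_context < alpha,
        "scene_bo": effects.p_scene_bo < alpha,
    }
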