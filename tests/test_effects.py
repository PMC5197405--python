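import itertools

import numpy as np
import pandas as pd
import pytest

from borderown import effects as eff
from borderown import simulate as sim


class TestCountWindow:
    @pytest.mark.parametrize(
        "train,expected",
        [
            ([], 0),
            ([10.0, 39.9], 0),
            ([40.0, 150.0, 299.9, 300.0], 3),  # closed-open [40, 300)
        ],
    )
    def test_boundary_convention(self, train, expected):
        assert eff.count_window(train) == expected


class TestAnscombe:
    def test_reference_values(self):
        assert eff.anscombe(0) == pytest.approx(np.sqrt(0.375))
        assert eff.anscombe(1) == pytest.approx(np.sqrt(1.375))

    def test_stabilizes_poisson_variance(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(20.0, size=20000)
        assert np.var(eff.anscombe(x)) == pytest.approx(0.25, rel=0.1)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            eff.anscombe(-1)


class TestOMI:
    def test_examples(self):
        assert eff.omi(10.0, 10.0) == 0.0
        assert eff.omi(10.0, 0.0) == 1.0

    def test_threshold_is_inclusive(self):
        cells = ["a", "b", "c"]
        kept = eff.filter_orientation_selective(cells, omis=[0.19, 0.20, 0.5])
        assert kept == ["b", "c"]


def _balanced_table(effect=1.0, noise=0.0, seed=0, reps=4):
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in itertools.product(["A1", "A2"], ["B1", "B2"]):
        for _ in range(reps):
            y = 5.0 + (effect / 2 if a == "A1" else -effect / 2)
            rows.append((a, b, y + noise * rng.normal()))
    return pd.DataFrame(rows, columns=["fa", "fb", "y"])


class TestFitFactorial:
    def test_pure_main_effect_recovered_under_sum_to_zero_coding(self):
        tab = _balanced_table(effect=1.0)
        fit = eff.fit_factorial(tab, ["fa", "fb"])
        # coefficient of fa's single deviation column is delta/2
        assert fit.coef[fit.term_slices[("fa",)]][0] == pytest.approx(0.5)
        assert fit.anova.loc["fb", "ss"] == pytest.approx(0.0, abs=1e-20)
        assert fit.anova.loc["fa:fb", "ss"] == pytest.approx(0.0, abs=1e-20)

    def test_constant_shift_leaves_factor_ss_unchanged(self):
        tab = _balanced_table(effect=0.7, noise=0.3, seed=1)
        fit1 = eff.fit_factorial(tab, ["fa", "fb"])
        tab2 = tab.assign(y=tab["y"] + 11.0)
        fit2 = eff.fit_factorial(tab2, ["fa", "fb"])
        assert np.allclose(fit1.anova["ss"], fit2.anova["ss"])

    def test_unbalanced_type2_matches_brute_force_rss_oracle(self):
        """Type-II SS must equal explicit residual-SS differences between
        marginality-respecting nested models, fitted independently here."""
        tab = _balanced_table(effect=0.5, noise=0.5, seed=3).drop(index=[0, 5, 9])
        fit = eff.fit_factorial(tab, ["fa", "fb"])

        def rss_of(terms):
            cols = [np.ones(len(tab))]
            xa = np.where(tab["fa"] == "A1", 1.0, -1.0)
            xb = np.where(tab["fb"] == "B1", 1.0, -1.0)
            mapping = {"a": xa, "b": xb, "ab": xa * xb}
            cols += [mapping[t] for t in terms]
            X = np.column_stack(cols)
            beta, *_ = np.linalg.lstsq(X, tab["y"].to_numpy(), rcond=None)
            r = tab["y"].to_numpy() - X @ beta
            return float(r @ r)

        ss_a = rss_of(["b"]) - rss_of(["a", "b"])
        ss_b = rss_of(["a"]) - rss_of(["a", "b"])
        ss_ab = rss_of(["a", "b"]) - rss_of(["a", "b", "ab"])
        assert fit.anova.loc["fa", "ss"] == pytest.approx(ss_a, abs=1e-8)
        assert fit.anova.loc["fb", "ss"] == pytest.approx(ss_b, abs=1e-8)
        assert fit.anova.loc["fa:fb", "ss"] == pytest.approx(ss_ab, abs=1e-8)

    def test_matches_statsmodels_type2_on_4way_cell(self, small_cell_fits):
        import statsmodels.api as smapi
        import statsmodels.formula.api as smf

        fit = small_cell_fits.scene
        m = smf.ols(
            "y ~ C(side)*C(polarity)*C(extent)*C(scene_id)", data=fit.table
        ).fit()
        a = smapi.stats.anova_lm(m, typ=2)
        for idx in a.index:
            if idx == "Residual":
                continue
            key = ":".join(sorted(idx.replace("C(", "").replace(")", "").split(":")))
            assert fit.anova.loc[key, "ss"] == pytest.approx(
                a.loc[idx, "sum_sq"], abs=1e-8
            )
        assert fit.residual_var == pytest.approx(float(m.mse_resid), rel=1e-10)

    def test_balanced_fast_path_agrees_with_general_path(self, small_cell):
        """On balanced data the projection route and the nested-model route
        must produce identical sums of squares, F values and residuals."""
        tab = eff.prepare_counts(small_cell)
        sc = tab[tab["test"] == "scene"][["side", "polarity", "extent", "scene_id", "y"]]
        factors = ["side", "polarity", "extent", "scene_id"]
        fast = eff.fit_factorial(sc, factors)
        general = eff.fit_factorial(sc, factors, _force_general=True)
        assert np.allclose(fast.anova["ss"], general.anova["ss"], atol=1e-8)
        assert np.allclose(fast.anova["F"], general.anova["F"], rtol=1e-8)
        assert fast.residual_var == pytest.approx(general.residual_var, rel=1e-10)
        assert np.allclose(fast.coef, general.coef, atol=1e-8)

    def test_rank_deficiency_reports_aliased_terms(self):
        tab = _balanced_table(effect=1.0, noise=0.1, seed=2)
        tab["fc"] = tab["fa"]  # perfectly aliased factor
        with pytest.raises(ValueError, match="aliased"):
            eff.fit_factorial(tab, ["fa", "fb", "fc"])


class TestExtractEffects:
    def test_context_is_full_minus_patch_exactly(self, small_cell_fits):
        e = eff.extract_effects(small_cell_fits)
        assert e.context == pytest.approx(e.full - e.patch, abs=1e-12)

    def test_identical_full_and_patch_data_give_zero_context(self, small_cell):
        cell = small_cell
        trials = cell.trials.copy()
        spikes = cell.spikes.copy()
        sc_full = (trials["test"] == "scene") & (trials["extent"] == "full")
        sc_patch = (trials["test"] == "scene") & (trials["extent"] == "patch")
        spikes[np.flatnonzero(sc_patch)] = spikes[np.flatnonzero(sc_full)]
        clone = sim.CellDataset("clone", trials, spikes)
        e = eff.cell_effects(clone)
        assert e.context == pytest.approx(0.0, abs=1e-12)

    def test_injected_square_effect_recovered_within_2se(self):
        p = sim.preset_paper_calibrated(n_scenes=4, n_reps=16)
        rng = np.random.default_rng(8)
        cell = sim.simulate_cell(p, rng)
        e = eff.cell_effects(cell)
        # expected square effect on the transformed scale from the rate model
        t = np.arange(300) + 0.5
        win = (t >= 40) & (t < 300)
        delta = sim.bo_difference(p, "square", t)[win].sum() / 1000.0
        base = np.where(t < p.onset_ms["square"], p.baseline_hz,
                        p.evoked_hz * (1 + p.polarity_gain) / 2)[win].sum() / 1000.0
        expected = eff.anscombe(base + delta / 2) - eff.anscombe(base - delta / 2)
        assert abs(e.square - expected) < 2 * e.se_square + 0.05

    def test_sign_convention_anchored_to_square(self):
        p = sim.preset_paper_calibrated(n_scenes=4, preferred_side=-1)
        rng = np.random.default_rng(3)
        cell = sim.simulate_cell(p, rng)
        e = eff.cell_effects(cell)
        assert e.preferred_side == -1
        assert e.square < 0  # A-minus-B convention; cell prefers B

    def test_normalization_uses_square_residual_only(self, small_cell_fits):
        e = eff.extract_effects(small_cell_fits)
        assert e.full_norm == pytest.approx(
            e.full / np.sqrt(small_cell_fits.square.residual_var)
        )

    def test_size_average_options_agree_on_balanced_data(self, small_cell_fits):
        a = eff.extract_effects(small_cell_fits, size_average="mean")
        b = eff.extract_effects(small_cell_fits, size_average="pooled")
        assert a.square == pytest.approx(b.square, abs=1e-12)

    def test_classify_significance_flags(self, small_cell_fits):
        e = eff.extract_effects(small_cell_fits)
        flags = eff.classify_significance(e, alpha=0.01)
        assert flags["square"] and flags["full"]


class TestNullBehaviour:
    def test_null_cells_give_centered_normalized_effects(self):
        p = sim.preset_paper_calibrated(
            local_amp_hz=0.0, ctx_amp_hz=0.0, n_scenes=5, n_reps=4
        )
        rng = np.random.default_rng(12)
        vals = []
        for child in rng.spawn(30):
            cell = sim.simulate_cell(p, child)
            e = eff.cell_effects(cell)
            vals.append(e.full / e.se_full)
        vals = np.array(vals)
        # standardized null effects: mean near 0, spread near 1
        assert abs(vals.mean()) < 0.6
        assert 0.6 < vals.std() < 1.6
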