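"""Factorial ANOVA of pooled predictive abilities and lsmeans."""

import itertools

import numpy as np
import pandas as pd
import pytest

import hologen as hg


def make_grid(rng, traits=2, stages=2, models=2, complexities=2, folds=2,
              effects=None, noise=0.05):
    rows = []
    effects = effects or {}
    for t, s, m, c, f in itertools.product(
        range(traits), range(stages), range(models), range(complexities),
        range(folds),
    ):
        r = (
            0.3
            + effects.get("trait", 0.0) * t
            + effects.get("model", 0.0) * m
            + effects.get("stage", 0.0) * s
            + rng.normal(0, noise)
        )
        rows.append(
            dict(trait=f"T{t}", stage=f"S{s}", model=f"M{m}",
                 complexity=f"C{c}", fold=f + 1, r=r)
        )
    return pd.DataFrame(rows)


class TestFactorialAnova:
    def test_balanced_type3_equals_sequential(self, rng):
        grid = make_grid(rng, effects={"model": 0.1, "trait": 0.05})
        fit = hg.fit_factorial_anova(grid)
        import statsmodels.api as sm

        seq = sm.stats.anova_lm(fit.result, typ=1)
        seq.index = [t.replace("C(", "").replace(", Sum)", "") for t in seq.index]
        for term in fit.anova_table.index:
            if term == "Residual":
                continue
            assert fit.anova_table.loc[term, "sum_sq"] == pytest.approx(
                seq.loc[term, "sum_sq"], abs=1e-8
            ), term

    def test_matches_normal_equations_oracle(self, rng):
        """Toy grid varying stage and model only: type-III SS from an
        independently built sum-coded design and the Wald identity
        SS = b' (L (X'X)^-1 L')^-1 b."""
        grid = make_grid(
            rng, traits=1, stages=3, models=2, complexities=1, folds=4,
            effects={"model": 0.12, "stage": 0.04},
        )
        # unbalance it: drop two rows
        grid = grid.drop(index=[0, 7]).reset_index(drop=True)
        fit = hg.fit_factorial_anova(grid)

        # independent sum-coded design: intercept, stage (2 cols),
        # model (1 col), stage:model (2 cols)
        def sum_code(values, levels):
            out = np.zeros((len(values), len(levels) - 1))
            for i, v in enumerate(values):
                j = levels.index(v)
                if j < len(levels) - 1:
                    out[i, j] = 1.0
                else:
                    out[i, :] = -1.0
            return out

        s_levels, m_levels = ["S0", "S1", "S2"], ["M0", "M1"]
        f_levels = ["1", "2", "3", "4"]
        Xs = sum_code(grid["stage"].tolist(), s_levels)
        Xm = sum_code(grid["model"].tolist(), m_levels)
        Xf = sum_code(grid["fold"].astype(str).tolist(), f_levels)
        Xi = np.column_stack([Xs[:, j] * Xm[:, 0] for j in range(2)])
        X = np.column_stack([np.ones(len(grid)), Xs, Xm, Xf, Xi])
        y = grid["r"].to_numpy()
        XtX_inv = np.linalg.inv(X.T @ X)
        b = XtX_inv @ X.T @ y
        resid = y - X @ b
        df_resid = len(y) - X.shape[1]

        def type3_ss(cols):
            L = np.zeros((len(cols), X.shape[1]))
            for i, c in enumerate(cols):
                L[i, c] = 1.0
            bL = L @ b
            return float(bL @ np.linalg.solve(L @ XtX_inv @ L.T, bL))

        expected = {
            "stage": type3_ss([1, 2]),
            "model": type3_ss([3]),
            "fold": type3_ss([4, 5, 6]),
            "stage:model": type3_ss([7, 8]),
            "Residual": float(resid @ resid),
        }
        for term, ss in expected.items():
            assert fit.anova_table.loc[term, "sum_sq"] == pytest.approx(
                ss, abs=1e-8
            ), term
        assert fit.anova_table.loc["Residual", "df"] == df_resid

    def test_constant_response_handled(self, rng):
        grid = make_grid(rng, noise=0.0)
        grid["r"] = 0.42
        fit = hg.fit_factorial_anova(grid)
        assert np.isnan(fit.anova_table.loc["model", "F"])

    def test_empty_cells_flagged_not_dropped(self, rng):
        grid = make_grid(rng)
        grid = grid[~((grid["stage"] == "S1") & (grid["model"] == "M1"))]
        fit = hg.fit_factorial_anova(grid)
        assert "stage:model" in fit.anova_table.index
        assert not fit.anova_table.loc["stage:model", "estimable"]

    def test_missing_columns_rejected(self):
        with pytest.raises(hg.HologenError, match="missing columns"):
            hg.fit_factorial_anova(pd.DataFrame({"r": [1.0]}))

    def test_nonnegative_sums_of_squares(self, rng):
        grid = make_grid(rng, effects={"model": 0.2})
        fit = hg.fit_factorial_anova(grid)
        assert (fit.anova_table["sum_sq"] >= -1e-12).all()


class TestLsmeans:
    def test_balanced_lsmeans_equal_cell_means(self, rng):
        grid = make_grid(rng, effects={"model": 0.15})
        fit = hg.fit_factorial_anova(grid)
        means, _ = hg.lsmeans_contrasts(fit, "model")
        raw = grid.groupby("model")["r"].mean()
        for _, row in means.iterrows():
            assert row["estimate"] == pytest.approx(raw[row["level"]], abs=1e-8)

    def test_duplicate_levels_contrast_is_null(self, rng):
        grid = make_grid(rng, models=1)
        dup = grid.copy()
        dup["model"] = "M1"
        both = pd.concat([grid, dup], ignore_index=True)
        fit = hg.fit_factorial_anova(both)
        _, contrasts = hg.lsmeans_contrasts(fit, "model")
        row = contrasts.iloc[0]
        assert row["estimate"] == pytest.approx(0.0, abs=1e-10)
        assert row["p_value"] > 0.99

    def test_relabeling_other_factors_invariant(self, rng):
        grid = make_grid(rng, effects={"model": 0.1, "trait": 0.03})
        fit1 = hg.fit_factorial_anova(grid)
        means1, _ = hg.lsmeans_contrasts(fit1, "model")
        relabeled = grid.copy()
        relabeled["trait"] = relabeled["trait"].map({"T0": "ZZ", "T1": "AA"})
        fit2 = hg.fit_factorial_anova(relabeled)
        means2, _ = hg.lsmeans_contrasts(fit2, "model")
        assert np.allclose(
            means1["estimate"].to_numpy(), means2["estimate"].to_numpy(),
            atol=1e-8,
        )

    def test_interaction_term_lsmeans(self, rng):
        grid = make_grid(rng, effects={"model": 0.1, "stage": 0.05})
        fit = hg.fit_factorial_anova(grid)
        means, contrasts = hg.lsmeans_contrasts(fit, "stage:model")
        assert len(means) == 4
        assert len(contrasts) == 6

    def test_unknown_term_rejected(self, rng):
        fit = hg.fit_factorial_anova(make_grid(rng))
        with pytest.raises(hg.HologenError):
            hg.lsmeans_contrasts(fit, "nonexistent")
        with pytest.raises(hg.HologenError):
            hg.lsmeans_contrasts(fit, "fold:trait")

    def test_bonferroni_adjustment_larger_than_none(self, rng):
        grid = make_grid(rng, effects={"stage": 0.04})
        fit = hg.fit_factorial_anova(grid)
        _, none = hg.lsmeans_contrasts(fit, "stage", adjust="none")
        _, bonf = hg.lsmeans_contrasts(fit, "stage", adjust="bonferroni")
        assert (bonf["p_value"] >= none["p_value"] - 1e-12).all()


def test_report_text_contains_terms(rng):
    grid = make_grid(rng, effects={"model": 0.1})
    fit = hg.fit_factorial_anova(grid)
    txt = hg.report_text(fit)
    assert "model" in txt and "Residual" in txt and "F value" in txt
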