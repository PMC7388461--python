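"""Factorial post-analysis of pooled predictive abilities.

The cross-validation grid (trait x stage x model x complexity x fold, one
predictive ability per cell) is analyzed with a fixed-effects linear model

    r ~ T + S + M + C + F + S:M + S:C + M:C + T:S + T:M + T:C

under sum-to-zero factor coding, with a type-III ANOVA table, estimated
marginal means (lsmeans) and pairwise contrasts (Tukey-adjusted by
default).  Sum-to-zero coding is required for type-III sums of squares to
test the usual main-effect hypotheses.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .datatypes import HologenError

#: factor columns of the results grid, in the model's term order
GRID_FACTORS = ("trait", "stage", "model", "complexity", "fold")

#: two-way interactions fitted alongside the main effects
GRID_INTERACTIONS = (
    ("stage", "model"),
    ("stage", "complexity"),
    ("model", "complexity"),
    ("trait", "stage"),
    ("trait", "model"),
    ("trait", "complexity"),
)


def _formula(response: str, active: set[str]) -> str:
    """Model formula; factors with a single observed level carry no
    information and are excluded from the fit (reported as df-0 terms)."""
    terms = [f"C({f}, Sum)" for f in GRID_FACTORS if f in active]
    terms += [
        f"C({a}, Sum):C({b}, Sum)"
        for a, b in GRID_INTERACTIONS
        if a in active and b in active
    ]
    return f"{response} ~ " + " + ".join(terms)


def _term_label(term: str) -> str:
    """'C(stage, Sum):C(model, Sum)' -> 'stage:model'."""
    return term.replace("C(", "").replace(", Sum)", "")


@dataclass
class FactorialFit:
    """Fitted factorial model plus its type-III ANOVA table."""

    result: object  # statsmodels RegressionResults
    anova_table: pd.DataFrame
    grid: pd.DataFrame
    response: str

    def levels(self, factor: str) -> list:
        return sorted(self.grid[factor].unique())


def _flag_estimability(grid: pd.DataFrame) -> dict[str, bool]:
    """A term is flagged inestimable if any crossed cell is empty."""
    flags = {}
    for f in GRID_FACTORS:
        flags[f] = grid[f].nunique() >= 2
    for a, b in GRID_INTERACTIONS:
        counts = grid.groupby([a, b], observed=False).size()
        full = grid[a].nunique() * grid[b].nunique()
        flags[f"{a}:{b}"] = len(counts) == full and (counts > 0).all()
    return flags


def fit_factorial_anova(grid: pd.DataFrame, response: str = "r") -> FactorialFit:
    """Fit the factorial model and compute type-III sums of squares.

    Expects the tidy cross-validation output (columns trait, stage, model,
    complexity, fold and the response).  Rows with a missing response
    (not-estimable CV cells) are dropped.  Returns a FactorialFit whose
    ``anova_table`` has one row per term: sum_sq, df, mean_sq, F, p_value,
    estimable.
    """
    missing = [c for c in (*GRID_FACTORS, response) if c not in grid.columns]
    if missing:
        raise HologenError(f"results grid missing columns: {missing}")
    data = grid.dropna(subset=[response]).copy()
    if len(data) == 0:
        raise HologenError("no finite responses in the results grid")
    for f in GRID_FACTORS:
        data[f] = data[f].astype(str)

    active = {f for f in GRID_FACTORS if data[f].nunique() >= 2}
    if not active:
        raise HologenError("no factor in the grid has two or more levels")
    fit = smf.ols(_formula(response, active), data=data).fit()
    degenerate = fit.ssr <= max(1e-12, 1e-12 * float(np.abs(data[response]).max()) ** 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = sm.stats.anova_lm(fit, typ=3)

    table = table.rename(
        columns={"sum_sq": "sum_sq", "F": "F", "PR(>F)": "p_value"}
    )
    table.index = [_term_label(t) for t in table.index]
    table = table.loc[[t for t in table.index if t != "Intercept"]]
    table["mean_sq"] = table["sum_sq"] / table["df"]
    if degenerate:
        # constant response: no residual variation, F ratios undefined
        table.loc[table.index != "Residual", ["F", "p_value"]] = np.nan
    flags = _flag_estimability(data)
    # report excluded degenerate terms explicitly rather than dropping them
    all_terms = list(GRID_FACTORS) + [f"{a}:{b}" for a, b in GRID_INTERACTIONS]
    for term in all_terms:
        if term not in table.index:
            table.loc[term] = {
                "sum_sq": 0.0, "df": 0.0, "mean_sq": np.nan,
                "F": np.nan, "p_value": np.nan,
            }
            flags[term] = False
    order = [t for t in all_terms if t in table.index] + ["Residual"]
    table = table.loc[order]
    table["estimable"] = [flags.get(t, True) for t in table.index]
    table = table[["sum_sq", "df", "mean_sq", "F", "p_value", "estimable"]]
    return FactorialFit(result=fit, anova_table=table, grid=data, response=response)


def _parse_term(term) -> tuple[str, ...]:
    if isinstance(term, str):
        parts = tuple(term.split(":"))
    else:
        parts = tuple(term)
    unknown = [p for p in parts if p not in GRID_FACTORS]
    if unknown:
        raise HologenError(f"unknown factors in term: {unknown}")
    if len(parts) > 1 and parts not in GRID_INTERACTIONS and tuple(reversed(parts)) not in GRID_INTERACTIONS:
        raise HologenError(f"interaction {parts} was not in the fitted model")
    return parts


def lsmeans_contrasts(
    fit: FactorialFit, term, adjust: str = "tukey"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimated marginal means and pairwise contrasts for a model term.

    Marginal means average model predictions over the levels of all other
    factors with equal weights.  Contrast p-values are adjusted with the
    chosen method: ``tukey`` (studentized range), ``bonferroni`` or
    ``none``.

    Returns (means, contrasts): means has level / estimate / se; contrasts
    has level_a / level_b / estimate / se / t / p_value.
    """
    if adjust not in ("tukey", "bonferroni", "none"):
        raise HologenError(f"unknown adjustment {adjust!r}")
    parts = _parse_term(term)
    res = fit.result
    design_info = res.model.data.design_info

    level_sets = {f: fit.levels(f) for f in GRID_FACTORS}
    ref_grid = pd.DataFrame(
        list(itertools.product(*[level_sets[f] for f in GRID_FACTORS])),
        columns=list(GRID_FACTORS),
    )
    (X_grid,) = patsy.build_design_matrices([design_info], ref_grid)
    X_grid = np.asarray(X_grid)

    params = res.params.to_numpy()
    cov = res.cov_params().to_numpy()
    df_resid = float(res.df_resid)

    combos = list(itertools.product(*[level_sets[p] for p in parts]))
    rows_means, cvecs = [], {}
    for combo in combos:
        mask = np.ones(len(ref_grid), dtype=bool)
        for p, lev in zip(parts, combo):
            mask &= (ref_grid[p] == lev).to_numpy()
        c = X_grid[mask].mean(axis=0)
        cvecs[combo] = c
        est = float(c @ params)
        se = float(np.sqrt(c @ cov @ c))
        rows_means.append(
            {"level": ":".join(map(str, combo)), "estimate": est, "se": se}
        )
    means = pd.DataFrame(rows_means)

    k = len(combos)
    n_pairs = k * (k - 1) // 2
    rows_c = []
    for (a, b) in itertools.combinations(combos, 2):
        d = cvecs[a] - cvecs[b]
        est = float(d @ params)
        se = float(np.sqrt(max(d @ cov @ d, 0.0)))
        if se == 0.0:
            t = 0.0 if est == 0 else np.inf
        else:
            t = est / se
        if adjust == "tukey":
            p = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df_resid))
        else:
            p = 2.0 * float(stats.t.sf(abs(t), df_resid))
            if adjust == "bonferroni":
                p = min(1.0, p * n_pairs)
        rows_c.append(
            {
                "level_a": ":".join(map(str, a)),
                "level_b": ":".join(map(str, b)),
                "estimate": est,
                "se": se,
                "t": t,
                "p_value": p,
            }
        )
    return means, pd.DataFrame(rows_c)


def report_text(fit: FactorialFit) -> str:
    """Plain-text ANOVA report (term, Sum square, Mean square, F, P)."""
    lines = [f"Type III ANOVA of predictive ability ({fit.response})", ""]
    header = f"{'Term':<24}{'Sum sq':>10}{'Mean sq':>10}{'F value':>10}{'P-value':>12}"
    lines.append(header)
    lines.append("-" * len(header))
    for term, row in fit.anova_table.iterrows():
        if term == "Residual":
            continue
        p = row["p_value"]
        ptxt = "< 0.001" if np.isfinite(p) and p < 0.001 else (
            f"{p:.3f}" if np.isfinite(p) else "NA"
        )
        lines.append(
            f"{term:<24}{row['sum_sq']:>10.2f}{row['mean_sq']:>10.2f}"
            f"{row['F'] if np.isfinite(row['F']) else float('nan'):>10.2f}{ptxt:>12}"
        )
    resid = fit.anova_table.loc["Residual"]
    lines.append(
        f"{'Residual':<24}{resid['sum_sq']:>10.2f}{resid['mean_sq']:>10.2f}"
    )
    return "\n".join(lines)
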