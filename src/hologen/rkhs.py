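"""Bayesian RKHS regression for multi-kernel variance partitioning.

The model family (M0–M4) decomposes a phenotype into fixed effects (dam
line, sex, contemporary group), an iid pen effect, up to three
kernel-structured random animal effects — genomic (G), microbial (M) and
genome-by-microbiome interaction (G∘M) — and an iid residual:

    y = Wb + Z pen + a + o + ao + e,
    a ~ N(0, G s2_a),  o ~ N(0, M s2_o),  ao ~ N(0, (G∘M) s2_ao).

All linear kernels, so the model is equivalent to multi-kernel BLUP with
unknown variances.  Fitting is by Gibbs sampling: each kernel effect is
sampled in the eigenbasis of its kernel (one O(n^3) eigendecomposition,
then O(n·rank) per sweep), variances from scaled-inverse-chi-square full
conditionals, and missing phenotypes are imputed by data augmentation so
that masked animals receive predictions from the joint fit.

Variance fractions are reported per draw as each variance divided by the
sum of all random-effect variances plus the residual (pen included):
heritability h2 from G, microbiability m2 from M, i2 from G∘M.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, solve_triangular
from sklearn.base import BaseEstimator, RegressorMixin

from .datatypes import HologenError, RelationshipKernel, check_same_animals
from .kernels import interaction_kernel

#: which kernels each model id attaches
MODEL_KERNELS: dict[str, tuple[str, ...]] = {
    "M0": (),
    "M1": ("G",),
    "M2": ("M",),
    "M3": ("G", "M"),
    "M4": ("G", "M", "GxM"),
}

#: human-readable fraction name per variance component
FRACTION_NAMES = {"G": "h2", "M": "m2", "GxM": "i2", "pen": "pen2", "residual": "e2"}

FIXED_FACTORS = ("dam_line", "sex", "contemporary_group")


@dataclass
class McmcSettings:
    """Gibbs-chain settings; defaults follow the long-chain convention of
    120,000 sweeps, 20,000 burn-in, thinning of 5."""

    n_iter: int = 120_000
    burn_in: int = 20_000
    thin: int = 5
    seed: int = 0
    prior_df: float = 5.0
    prior_r2: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise HologenError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise HologenError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    @classmethod
    def fast(cls, seed: int = 0, **kw) -> "McmcSettings":
        """Reduced profile (12,000/2,000/5) for cross-validation sweeps."""
        kw.setdefault("n_iter", 12_000)
        kw.setdefault("burn_in", 2_000)
        return cls(seed=seed, **kw)


@dataclass
class ModelSpec:
    """A model id plus its attached kernels and bookkeeping labels."""

    model_id: str
    kernels: dict = field(default_factory=dict)
    stage: str | None = None
    complexity: str = "FULL"

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_KERNELS:
            raise HologenError(f"unknown model id {self.model_id!r}")
        expected = set(MODEL_KERNELS[self.model_id])
        got = set(self.kernels)
        if got != expected:
            raise HologenError(
                f"{self.model_id} requires kernels {sorted(expected)}, got {sorted(got)}"
            )


def make_model_spec(
    model_id: str,
    G: RelationshipKernel | None = None,
    M: RelationshipKernel | None = None,
    stage: str | None = None,
    complexity: str = "FULL",
) -> ModelSpec:
    """Assemble the kernel set a model id requires from G and M."""
    needed = MODEL_KERNELS[model_id]
    kernels: dict[str, RelationshipKernel] = {}
    if "G" in needed:
        if G is None:
            raise HologenError(f"{model_id} needs a genomic kernel")
        kernels["G"] = G
    if "M" in needed:
        if M is None:
            raise HologenError(f"{model_id} needs a microbial kernel")
        kernels["M"] = M
    if "GxM" in needed:
        kernels["GxM"] = interaction_kernel(G, M)
    return ModelSpec(model_id, kernels, stage=stage, complexity=complexity)


@dataclass
class PosteriorSummary:
    """Variance-component posterior: draws, derived fractions, ESS."""

    draws: pd.DataFrame  # retained draws x components (variances)
    fraction_draws: pd.DataFrame  # same shape, per-draw fractions
    table: pd.DataFrame  # per component: mean, sd, ess, frac_mean, frac_sd

    @property
    def components(self) -> list[str]:
        return list(self.draws.columns)

    def fraction_mean(self, component: str) -> float:
        if component not in self.fraction_draws.columns:
            return 0.0
        return float(self.fraction_draws[component].mean())

    @property
    def heritability(self) -> float:
        return self.fraction_mean("G")

    @property
    def microbiability(self) -> float:
        return self.fraction_mean("M")

    @property
    def interaction_fraction(self) -> float:
        return self.fraction_mean("GxM")


def effective_sample_size(x: np.ndarray) -> float:
    """ESS of a single chain by autocorrelation time (arviz bulk ESS)."""
    import arviz as az

    x = np.asarray(x, dtype=float)
    if x.size < 4 or np.allclose(x, x[0]):
        return float(x.size)
    return float(az.ess(x[None, :]))


def summarize_posterior(draws: pd.DataFrame) -> PosteriorSummary:
    """Posterior means/SDs of variances and derived fractions.

    Per draw, a component's fraction is its variance over the total of all
    random-effect variances plus the residual.
    """
    if len(draws) < 1:
        raise HologenError("no retained draws to summarize")
    total = draws.sum(axis=1)
    fractions = draws.div(total, axis=0)
    table = pd.DataFrame(
        {
            "mean": draws.mean(axis=0),
            "sd": draws.std(axis=0, ddof=1) if len(draws) > 1 else 0.0,
            "ess": [effective_sample_size(draws[c].to_numpy()) for c in draws],
            "frac_mean": fractions.mean(axis=0),
            "frac_sd": fractions.std(axis=0, ddof=1) if len(draws) > 1 else 0.0,
        }
    )
    return PosteriorSummary(draws=draws, fraction_draws=fractions, table=table)


def _fixed_design(design: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Full-rank fixed-effect design: intercept + drop-first dummies."""
    cols = [np.ones(len(design))]
    names = ["intercept"]
    for factor in FIXED_FACTORS:
        levels = sorted(pd.unique(design[factor]))
        for level in levels[1:]:
            cols.append((design[factor] == level).to_numpy(dtype=float))
            names.append(f"{factor}[{level}]")
    return np.column_stack(cols), names


class RKHSGibbsRegressor(BaseEstimator, RegressorMixin):
    """Multi-kernel Bayesian RKHS regression fitted by Gibbs sampling.

    Parameters
    ----------
    kernels : dict[str, RelationshipKernel] or None
        Kernel-structured random effects, keyed e.g. ``G``, ``M``, ``GxM``.
        None or empty fits the baseline model (fixed effects + pen only).
    n_iter, burn_in, thin : int
        Chain length, discarded sweeps, thinning interval.
    prior_df : float
        Degrees of freedom of every scaled-inverse-chi-square variance prior.
    prior_r2 : float
        Prior proportion of phenotypic variance assigned, in equal shares,
        to the non-residual terms (kernels + pen); sets the prior scales.
    fix_variance_components : dict or None
        Map component name -> variance; listed components are held fixed
        (not sampled), turning the fit into BLUP with known variances.
    random_state : int
        Seed of the Gibbs chain.

    Attributes (after fit)
    ----------------------
    posterior_ : PosteriorSummary
    variance_components_ : dict of posterior-mean variances
    fixed_effects_ : pd.Series of posterior-mean fixed-effect coefficients
    random_effects_ : dict kernel name -> pd.Series per animal
    pen_effects_ : pd.Series per pen
    fitted_values_ : pd.Series posterior-mean linear predictor per animal
    """

    def __init__(
        self,
        kernels=None,
        n_iter: int = 12_000,
        burn_in: int = 2_000,
        thin: int = 5,
        prior_df: float = 5.0,
        prior_r2: float = 0.5,
        eig_tol: float = 1e-10,
        fix_variance_components=None,
        random_state: int = 0,
    ):
        self.kernels = kernels
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.prior_df = prior_df
        self.prior_r2 = prior_r2
        self.eig_tol = eig_tol
        self.fix_variance_components = fix_variance_components
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------

    def _settings(self) -> McmcSettings:
        return McmcSettings(
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.random_state,
            prior_df=self.prior_df,
            prior_r2=self.prior_r2,
        )

    def _prepare_kernels(self, animal_ids: np.ndarray):
        """Eigendecompose each kernel; truncate eigenvalues <= eig_tol."""
        bases = {}
        kernels = self.kernels or {}
        for name, K in kernels.items():
            if not isinstance(K, RelationshipKernel):
                K = RelationshipKernel(animal_ids, np.asarray(K), kind=name)
            if not np.array_equal(K.animal_ids, animal_ids):
                raise HologenError(
                    f"kernel {name!r} is not indexed by the fitted animals "
                    "in the same order"
                )
            lam, U = np.linalg.eigh(K.matrix)
            if lam.min() < RelationshipKernel.PSD_TOL:
                raise HologenError(
                    f"kernel {name!r} not PSD after clipping: min eig {lam.min():.3e}"
                )
            keep = lam > self.eig_tol
            if not keep.any():
                raise HologenError(f"kernel {name!r} has no usable eigenvalues")
            bases[name] = (
                np.ascontiguousarray(U[:, keep]),
                np.sqrt(lam[keep]),
                float(np.mean(np.diag(K.matrix))),
            )
        return bases

    # -- fit ---------------------------------------------------------------

    def fit(self, X: pd.DataFrame, y):
        """Run the Gibbs chain.

        X is the design table (index animal id; columns dam_line, sex,
        contemporary_group, pen); y may contain NaN for animals whose
        phenotype is masked — they contribute nothing to the likelihood
        but receive predictions.
        """
        settings = self._settings()
        design = X
        y = np.asarray(pd.Series(y), dtype=float)
        n = len(design)
        if y.shape != (n,):
            raise HologenError("y length does not match design table")
        obs = np.isfinite(y)
        if obs.sum() < 1:
            raise HologenError("need at least one non-missing phenotype")
        for factor in FIXED_FACTORS:
            all_levels = set(pd.unique(design[factor]))
            obs_levels = set(pd.unique(design.loc[obs, factor]))
            if all_levels - obs_levels:
                raise HologenError(
                    f"factor {factor!r} has levels with no observed records: "
                    f"{sorted(all_levels - obs_levels)}"
                )

        animal_ids = design.index.to_numpy()
        bases = self._prepare_kernels(animal_ids)
        knames = list(bases)

        W, coef_names = _fixed_design(design)
        WtW = W.T @ W
        Lw = np.linalg.cholesky(WtW)
        chol = (Lw, True)

        pen_levels, pen_codes = np.unique(design["pen"].to_numpy(), return_inverse=True)
        n_pens = len(pen_levels)
        pen_counts = np.bincount(pen_codes, minlength=n_pens).astype(float)
        observed_pens = np.unique(pen_codes[obs])

        rng = np.random.default_rng(settings.seed)
        fixed = dict(self.fix_variance_components or {})
        var_y = float(np.var(y[obs], ddof=1)) if obs.sum() > 1 else 1.0
        n_terms = len(knames) + 1  # kernels + pen
        df0 = settings.prior_df
        share = settings.prior_r2 * var_y / n_terms

        def prior_scale(target: float) -> float:
            # scaled-inv-chi2(df, S) has mode df*S/(df+2): match the target
            return target * (df0 + 2.0) / df0

        S_k = {
            name: prior_scale(share / bases[name][2]) for name in knames
        }
        S_pen = prior_scale(share)
        S_e = prior_scale((1.0 - settings.prior_r2) * var_y)

        # state
        var_k = {
            name: fixed.get(name, share / bases[name][2]) for name in knames
        }
        var_pen = fixed.get("pen", share)
        var_e = fixed.get("residual", (1.0 - settings.prior_r2) * var_y)
        beta, *_ = np.linalg.lstsq(W[obs], y[obs], rcond=None)
        alpha = {name: np.zeros(bases[name][0].shape[1]) for name in knames}
        u = {name: np.zeros(n) for name in knames}
        pen_eff = np.zeros(n_pens)
        y_aug = y.copy()
        y_aug[~obs] = float(np.mean(y[obs]))
        eta = W @ beta + pen_eff[pen_codes]
        miss = ~obs

        n_ret = settings.n_retained
        draws = np.zeros((n_ret, len(knames) + 2))
        acc_beta = np.zeros(len(beta))
        acc_u = {name: np.zeros(n) for name in knames}
        acc_pen = np.zeros(n_pens)
        kept = 0

        all_fixed = set(fixed) >= set(knames) | {"pen", "residual"}
        if all_fixed:
            # With every variance fixed the location effects form one
            # Gaussian block whose full conditional given the observed
            # records is exact: sample it jointly (precision fixed, one
            # Cholesky); the conditional mean is the posterior mean.
            Zp = np.zeros((n, n_pens))
            Zp[np.arange(n), pen_codes] = 1.0
            blocks = [W, Zp] + [bases[nm][0] * bases[nm][1][None, :] for nm in knames]
            C = np.hstack(blocks)
            sizes = [W.shape[1], n_pens] + [bases[nm][0].shape[1] for nm in knames]
            offsets = np.cumsum([0] + sizes)
            prior_prec = np.concatenate(
                [np.zeros(W.shape[1]), np.full(n_pens, 1.0 / var_pen)]
                + [np.full(bases[nm][0].shape[1], 1.0 / var_k[nm]) for nm in knames]
            )
            Co = C[obs]
            P = Co.T @ Co / var_e + np.diag(prior_prec)
            Lp = np.linalg.cholesky(P)
            mean_theta = cho_solve((Lp, True), Co.T @ y[obs] / var_e)
            for it in range(1, settings.n_iter + 1):
                z = rng.standard_normal(len(mean_theta))
                theta = mean_theta + solve_triangular(Lp.T, z, lower=False)
                if (
                    it > settings.burn_in
                    and (it - settings.burn_in) % settings.thin == 0
                ):
                    draws[kept, : len(knames)] = [var_k[nm] for nm in knames]
                    draws[kept, len(knames)] = var_pen
                    draws[kept, len(knames) + 1] = var_e
                    kept += 1
            acc_beta = mean_theta[offsets[0] : offsets[1]] * kept
            acc_pen = mean_theta[offsets[1] : offsets[2]] * kept
            for i, name in enumerate(knames):
                a = mean_theta[offsets[2 + i] : offsets[3 + i]]
                acc_u[name] = bases[name][0] @ (bases[name][1] * a) * kept
            return self._finalize(
                draws[:kept], knames, acc_beta, acc_pen, acc_u, kept,
                coef_names, pen_levels, observed_pens, animal_ids, design,
                obs, W, pen_codes,
            )

        for it in range(1, settings.n_iter + 1):
            # data augmentation for masked phenotypes
            if miss.any():
                y_aug[miss] = eta[miss] + rng.standard_normal(miss.sum()) * np.sqrt(
                    var_e
                )

            # fixed effects: flat prior, joint conditional normal
            r = y_aug - eta + W @ beta
            mean_beta = cho_solve(chol, W.T @ r)
            z = rng.standard_normal(len(beta))
            beta_new = mean_beta + np.sqrt(var_e) * solve_triangular(
                Lw.T, z, lower=False
            )
            eta += W @ (beta_new - beta)
            beta = beta_new

            # pen effects: iid normal prior
            r = y_aug - eta + pen_eff[pen_codes]
            sums = np.bincount(pen_codes, weights=r, minlength=n_pens)
            prec = pen_counts / var_e + 1.0 / var_pen
            mean_pen = (sums / var_e) / prec
            pen_new = mean_pen + rng.standard_normal(n_pens) / np.sqrt(prec)
            eta += pen_new[pen_codes] - pen_eff[pen_codes]
            pen_eff = pen_new

            # kernel effects in the eigenbasis
            mean_u = {}
            for name in knames:
                U, sqrt_lam, _ = bases[name]
                r = y_aug - eta + u[name]
                v = U.T @ r
                prec_a = (sqrt_lam**2) / var_e + 1.0 / var_k[name]
                cvar = 1.0 / prec_a
                m_a = cvar * sqrt_lam * v / var_e
                a_new = m_a + np.sqrt(cvar) * rng.standard_normal(len(m_a))
                u_new = U @ (sqrt_lam * a_new)
                eta += u_new - u[name]
                alpha[name] = a_new
                u[name] = u_new
                mean_u[name] = U @ (sqrt_lam * m_a)

            # variances from scaled-inverse-chi-square full conditionals
            for name in knames:
                if name in fixed:
                    continue
                a = alpha[name]
                var_k[name] = (df0 * S_k[name] + a @ a) / rng.chisquare(
                    df0 + len(a)
                )
            if "pen" not in fixed:
                var_pen = (df0 * S_pen + pen_eff @ pen_eff) / rng.chisquare(
                    df0 + n_pens
                )
            if "residual" not in fixed:
                e = y_aug - eta
                var_e = (df0 * S_e + e @ e) / rng.chisquare(df0 + n)

            if it > settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
                draws[kept, : len(knames)] = [var_k[nm] for nm in knames]
                draws[kept, len(knames)] = var_pen
                draws[kept, len(knames) + 1] = var_e
                # Rao-Blackwellized accumulation of effect posterior means
                acc_beta += mean_beta
                acc_pen += mean_pen
                for name in knames:
                    acc_u[name] += mean_u[name]
                kept += 1

        return self._finalize(
            draws[:kept], knames, acc_beta, acc_pen, acc_u, kept, coef_names,
            pen_levels, observed_pens, animal_ids, design, obs, W, pen_codes,
        )

    def _finalize(
        self, draws, knames, acc_beta, acc_pen, acc_u, kept, coef_names,
        pen_levels, observed_pens, animal_ids, design, obs, W, pen_codes,
    ):
        draws_df = pd.DataFrame(draws, columns=knames + ["pen", "residual"])
        self.posterior_ = summarize_posterior(draws_df)
        self.variance_components_ = draws_df.mean(axis=0).to_dict()
        self.fixed_effects_ = pd.Series(acc_beta / kept, index=coef_names)
        self.random_effects_ = {
            name: pd.Series(acc_u[name] / kept, index=animal_ids) for name in knames
        }
        self.pen_effects_ = pd.Series(acc_pen / kept, index=pen_levels)
        self.observed_pens_ = set(pen_levels[observed_pens])
        self.animal_ids_ = animal_ids
        self.design_ = design
        self.masked_animals_ = animal_ids[~obs]
        self._W = W
        self._pen_codes = pen_codes
        fitted = W @ self.fixed_effects_.to_numpy() + self.pen_effects_.to_numpy()[
            pen_codes
        ]
        for name in knames:
            fitted = fitted + self.random_effects_[name].to_numpy()
        self.fitted_values_ = pd.Series(fitted, index=animal_ids)
        return self

    # -- predict -----------------------------------------------------------

    def predict(self, X=None) -> np.ndarray:
        """Posterior-mean phenotype predictions.

        X may be None (all fitted animals) or a sequence of animal ids that
        were present in the fit (the masked-record convention: held-out
        animals are included in the fit with y = NaN).  Pens never observed
        in training contribute 0, their conditional mean.
        """
        pred = self._prediction_series()
        if X is None:
            return pred.to_numpy()
        ids = np.asarray(X)
        missing = [i for i in ids if i not in pred.index]
        if missing:
            raise HologenError(f"animals absent from the fit: {missing[:5]}")
        return pred.loc[ids].to_numpy()

    def _prediction_series(self) -> pd.Series:
        pen_term = np.array(
            [
                self.pen_effects_[p] if p in self.observed_pens_ else 0.0
                for p in self.design_["pen"]
            ]
        )
        pred = self._W @ self.fixed_effects_.to_numpy() + pen_term
        for eff in self.random_effects_.values():
            pred = pred + eff.to_numpy()
        return pd.Series(pred, index=self.animal_ids_)


@dataclass
class FitResult:
    """Output bundle of fit_rkhs: posterior summary, effect posterior
    means, and the fitted estimator for prediction."""

    summary: PosteriorSummary
    random_effects: dict
    fixed_effects: pd.Series
    model: RKHSGibbsRegressor

    def __iter__(self):
        return iter((self.summary, self.random_effects, self.fixed_effects))


def fit_rkhs(
    records: pd.DataFrame,
    trait: str,
    spec: ModelSpec,
    mcmc: McmcSettings | None = None,
) -> FitResult:
    """Fit one model on one trait from a records table.

    ``records`` holds the design factors plus trait columns, indexed by
    animal id; NaN trait values mark animals to predict.
    """
    mcmc = mcmc or McmcSettings()
    reg = RKHSGibbsRegressor(
        kernels=spec.kernels,
        n_iter=mcmc.n_iter,
        burn_in=mcmc.burn_in,
        thin=mcmc.thin,
        prior_df=mcmc.prior_df,
        prior_r2=mcmc.prior_r2,
        random_state=mcmc.seed,
    )
    reg.fit(records, records[trait])
    return FitResult(
        summary=reg.posterior_,
        random_effects=reg.random_effects_,
        fixed_effects=reg.fixed_effects_,
        model=reg,
    )


def predict_masked(result: FitResult, records: pd.DataFrame) -> pd.Series:
    """Predictions for the animals whose trait was masked in the fit."""
    model = result.model
    ids = model.masked_animals_
    return pd.Series(model.predict(ids), index=ids)
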