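"""Single-feature association scans and FULL / IR / RR feature reduction.

Each marker (additive allele count) or OTU (raw relative abundance) is
tested one at a time in a fixed-effects least-squares model

    y = mu + dam_line + contemporary_group + sex + pen + sire + beta*feature + e

and features passing a Bonferroni-corrected Wald test form the
"informatively reduced" (IR) set; a size-matched uniform random sample
forms the "randomly reduced" (RR) control.  The scan residualizes y and
all features against the design once (a single orthogonal projection),
which is algebraically identical to refitting the full model per feature.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import HologenError, NoInformativeFeaturesError

logger = logging.getLogger(__name__)

SCAN_FACTORS = ("dam_line", "contemporary_group", "sex", "pen", "sire")


def _design_basis(design: pd.DataFrame) -> tuple[np.ndarray, int]:
    """Orthonormal basis of the scan's fixed-effect design column space."""
    cols = [np.ones(len(design))]
    for factor in SCAN_FACTORS:
        if factor not in design.columns:
            raise HologenError(f"scan design missing factor {factor!r}")
        levels = pd.unique(design[factor])
        for level in levels:
            cols.append((design[factor] == level).to_numpy(dtype=float))
    D = np.column_stack(cols)
    U, s, _ = np.linalg.svd(D, full_matrices=False)
    rank = int((s > s[0] * max(D.shape) * np.finfo(float).eps).sum())
    return U[:, :rank], rank


def scan_features(
    records: pd.DataFrame,
    features: pd.DataFrame,
    trait: str,
    feature_type: str = "marker",
    stage: str | None = None,
    fold: int | None = None,
) -> pd.DataFrame:
    """Per-feature effect estimates, standard errors and Wald p-values.

    ``records`` carries the design factors and the trait; ``features`` is
    an animals x features matrix sharing the same index.  Features that are
    collinear with the design (zero residual variance after projection)
    get NaN estimates and are logged.

    Returns a tidy frame: feature, feature_type, beta, se, p_value, trait,
    stage, fold.
    """
    if records["sire"].nunique() < 2:
        raise HologenError("scan requires at least two sire levels")
    if not features.index.equals(records.index):
        raise HologenError("feature matrix and records are not aligned")
    y = records[trait].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise HologenError("scan requires complete phenotypes in the training fold")

    Q, rank = _design_basis(records)
    n = len(y)
    df_resid = n - rank - 1
    if df_resid < 1:
        raise HologenError("not enough residual degrees of freedom for the scan")

    F = features.to_numpy(dtype=float)
    y_t = y - Q @ (Q.T @ y)
    F_t = F - Q @ (Q.T @ F)

    ssq = np.einsum("ij,ij->j", F_t, F_t)
    xty = F_t.T @ y_t
    yty = float(y_t @ y_t)

    ok = ssq > n * np.finfo(float).eps * np.maximum(1.0, np.abs(F).max(axis=0)) ** 2
    beta = np.full(F.shape[1], np.nan)
    se = np.full(F.shape[1], np.nan)
    pval = np.full(F.shape[1], np.nan)
    beta[ok] = xty[ok] / ssq[ok]
    sse = yty - beta[ok] * xty[ok]
    sigma2 = np.maximum(sse, 0.0) / df_resid
    se[ok] = np.sqrt(sigma2 / ssq[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[ok] / se[ok]
    pval[ok] = 2.0 * stats.t.sf(np.abs(tstat), df_resid)
    n_collinear = int((~ok).sum())
    if n_collinear:
        logger.warning(
            "%d feature(s) collinear with the scan design; p-values set missing",
            n_collinear,
        )

    return pd.DataFrame(
        {
            "feature": features.columns,
            "feature_type": feature_type,
            "beta": beta,
            "se": se,
            "p_value": pval,
            "trait": trait,
            "stage": stage,
            "fold": fold,
        }
    )


def select_informative(scan: pd.DataFrame, alpha: float = 0.05) -> list:
    """Bonferroni selection: keep features with p < alpha / n_tested.

    The correction denominator is the number of tested features of each
    feature type within the scan (markers and OTUs corrected separately).
    Raises NoInformativeFeaturesError if nothing passes.
    """
    if len(scan) == 0:
        raise HologenError("empty scan result")
    selected: list = []
    for _, group in scan.groupby("feature_type", sort=False):
        threshold = alpha / len(group)
        hits = group.loc[group["p_value"] < threshold, "feature"]
        selected.extend(hits.tolist())
    if not selected:
        raise NoInformativeFeaturesError(
            "no feature passed the Bonferroni-corrected threshold"
        )
    return selected


def select_random(feature_ids, k: int, seed: int = 0) -> list:
    """Uniform sample of k feature ids without replacement (RR sets)."""
    ids = list(feature_ids)
    if k > len(ids):
        raise HologenError(f"cannot sample {k} from {len(ids)} features")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(ids), size=k, replace=False)
    return [ids[i] for i in sorted(pick)]


class InformativeSelector(BaseEstimator):
    """Estimator wrapper for the scan + Bonferroni selection.

    fit(features, y=None, records=...) runs the scan on the given training
    records and stores ``selected_features_`` and ``scan_result_``.
    """

    def __init__(self, alpha: float = 0.05, feature_type: str = "marker"):
        self.alpha = alpha
        self.feature_type = feature_type

    def fit(self, X: pd.DataFrame, y=None, records: pd.DataFrame | None = None, trait: str | None = None):
        if records is None or trait is None:
            raise HologenError("InformativeSelector.fit needs records= and trait=")
        self.scan_result_ = scan_features(
            records, X, trait, feature_type=self.feature_type
        )
        self.selected_features_ = select_informative(self.scan_result_, self.alpha)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[:, self.selected_features_]
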