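"""Relationship kernels: genomic G, microbial M, interaction G∘M.

G follows VanRaden's method 1 on centered additive dosages; M is the linear
kernel XX'/q on log-transformed, centered and scaled OTU relative
abundances; the genome-by-microbiome interaction kernel is the Hadamard
(element-wise) product G∘M, positive semidefinite by the Schur product
theorem.  The three kernels define the covariance structures of the nested
model family M0–M4 (baseline; +genomic; +microbial; both; both plus
interaction).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import (
    GenotypePanel,
    HologenError,
    RelationshipKernel,
    StandardizedOtuMatrix,
    check_same_animals,
)


def build_grm(
    panel: GenotypePanel, allele_freq: pd.Series | None = None
) -> RelationshipKernel:
    """Genomic relationship matrix G = ZZ' / (2 Σ p_j (1 − p_j)).

    Z holds dosages centered by twice the allele frequency.  ``allele_freq``
    may be supplied externally (e.g. estimated on a training fold); by
    default it is estimated in-sample, in which case Z's columns sum to zero
    and the grand mean of G is exactly zero.
    """
    dos = panel.dosages
    if dos.isna().any().any():
        raise HologenError("genotype panel has missing values; run QC first")
    p = panel.allele_frequency() if allele_freq is None else allele_freq.loc[dos.columns]
    p = p.to_numpy(dtype=float)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise HologenError("all markers monomorphic: VanRaden denominator is zero")
    Z = dos.to_numpy(dtype=float) - 2.0 * p[None, :]
    G = (Z @ Z.T) / denom
    return RelationshipKernel(
        panel.animal_ids,
        G,
        kind="G",
        meta={"n_markers": int(dos.shape[1]), "denominator": denom},
    )


class OtuLogStandardizer(BaseEstimator, TransformerMixin):
    """Log-transform, center and scale OTU relative abundances.

    A pseudocount is added to every element of S before logging.  Two
    centering conventions are supported for column j:

    - ``mean-of-logs`` (default): subtract mean(log S_.j) — true
      standardization; retained columns of X have zero mean and, with the
      n−1 divisor, unit variance, which yields trace(XX'/q) = n−1.
    - ``log-of-mean``: subtract log(mean S_.j), the literal reading of the
      construction formula.

    Both divide by the standard deviation of the logged column.  Columns
    with zero variance are dropped and reported in ``dropped_otus_``.
    Statistics are learned in ``fit`` (training animals) and applied in
    ``transform``.
    """

    def __init__(
        self,
        pseudocount: float = 0.001,
        centering: str = "mean-of-logs",
        sd_divisor: str = "n-1",
    ):
        self.pseudocount = pseudocount
        self.centering = centering
        self.sd_divisor = sd_divisor

    def _check(self, S: pd.DataFrame) -> None:
        vals = S.to_numpy(dtype=float)
        if vals.size == 0:
            raise HologenError("empty abundance matrix")
        if vals.min() < 0 or vals.max() > 1:
            raise HologenError("relative abundances must lie in [0, 1]")
        if self.centering not in ("mean-of-logs", "log-of-mean"):
            raise HologenError(f"unknown centering {self.centering!r}")
        if self.sd_divisor not in ("n-1", "n"):
            raise HologenError(f"unknown sd divisor {self.sd_divisor!r}")

    def fit(self, S: pd.DataFrame, y=None):
        self._check(S)
        logs = np.log(S.to_numpy(dtype=float) + self.pseudocount)
        ddof = 1 if self.sd_divisor == "n-1" else 0
        scale = logs.std(axis=0, ddof=ddof)
        keep = scale > 0
        if not keep.any():
            raise HologenError("every OTU column has zero variance after logging")
        if self.centering == "mean-of-logs":
            center = logs.mean(axis=0)
        else:
            center = np.log(S.to_numpy(dtype=float).mean(axis=0) + self.pseudocount)
        self.column_center_ = pd.Series(center[keep], index=S.columns[keep])
        self.column_scale_ = pd.Series(scale[keep], index=S.columns[keep])
        self.dropped_otus_ = S.columns[~keep].tolist()
        return self

    def transform(self, S: pd.DataFrame) -> StandardizedOtuMatrix:
        self._check(S)
        cols = self.column_center_.index
        logs = np.log(S.loc[:, cols].to_numpy(dtype=float) + self.pseudocount)
        X = (logs - self.column_center_.to_numpy()[None, :]) / self.column_scale_.to_numpy()[
            None, :
        ]
        out = pd.DataFrame(X, index=S.index, columns=cols)
        out.attrs.update(S.attrs)
        return StandardizedOtuMatrix(
            values=out,
            centering=self.centering,
            sd_divisor=self.sd_divisor,
            dropped_otus=list(self.dropped_otus_),
            column_center=self.column_center_,
            column_scale=self.column_scale_,
        )


def log_standardize_otu(
    S: pd.DataFrame,
    pseudocount: float = 0.001,
    centering: str = "mean-of-logs",
    sd_divisor: str = "n-1",
) -> StandardizedOtuMatrix:
    """One-shot log-standardization of an abundance matrix (in-sample)."""
    return OtuLogStandardizer(pseudocount, centering, sd_divisor).fit_transform(S)


def build_microbial_kernel(X: StandardizedOtuMatrix) -> RelationshipKernel:
    """Microbial relationship matrix M = XX' / q.

    Under mean-of-logs centering with the n−1 divisor (in-sample),
    trace(M) = n − 1.
    """
    q = X.n_otus
    if q < 1:
        raise HologenError("no OTU columns retained")
    V = X.values.to_numpy(dtype=float)
    M = (V @ V.T) / q
    return RelationshipKernel(
        X.animal_ids,
        M,
        kind="M",
        meta={
            "n_otu": int(q),
            "centering": X.centering,
            "sd_divisor": X.sd_divisor,
            "stage": X.values.attrs.get("stage"),
        },
    )


def interaction_kernel(
    G: RelationshipKernel, M: RelationshipKernel
) -> RelationshipKernel:
    """Hadamard product kernel (G∘M)_ij = G_ij · M_ij.

    Models the genome-by-microbiome interaction covariance; PSD is
    guaranteed by the Schur product theorem and asserted numerically.
    The product is not rescaled — its variance parameter absorbs scale.
    """
    check_same_animals(G, M)
    K = RelationshipKernel(
        G.animal_ids,
        G.matrix * M.matrix,
        kind="GxM",
        meta={"from": (G.kind, M.kind)},
    )
    K.check_psd()
    return K
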