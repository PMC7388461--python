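"""Quality control of genotypes and OTU counts.

Transformers follow the scikit-learn fit/transform contract so that QC
statistics (marker call rates, allele frequencies, OTU totals) can be
learned on a training fold and applied to held-out animals without leakage.
Module-level functions are one-shot conveniences over the estimators.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import EmptyResultError, GenotypePanel, HologenError, OtuCountTable

logger = logging.getLogger(__name__)


class GenotypeQC(BaseEstimator, TransformerMixin):
    """Marker QC: call-rate and MAF filters plus mean imputation.

    Markers with call rate strictly below ``min_call_rate`` or minor allele
    frequency strictly below ``min_maf`` are removed; remaining missing
    dosages are imputed to twice the (counted) allele frequency, which
    leaves per-marker allele frequencies unchanged.

    Parameters
    ----------
    min_call_rate : float, default 0.90
        Markers below this fraction of non-missing calls are dropped.
    min_maf : float, default 0.05
        Markers with minor allele frequency below this are dropped.
    """

    def __init__(self, min_call_rate: float = 0.90, min_maf: float = 0.05):
        self.min_call_rate = min_call_rate
        self.min_maf = min_maf

    def fit(self, X: GenotypePanel, y=None):
        call_rate = X.call_rate()
        p = X.allele_frequency()
        maf = np.minimum(p, 1.0 - p)
        keep = (call_rate >= self.min_call_rate) & (maf >= self.min_maf)
        kept = X.dosages.columns[keep.to_numpy()]
        if len(kept) == 0:
            raise EmptyResultError("genotype QC removed every marker")
        self.kept_markers_ = kept.to_numpy()
        self.allele_freq_ = p.loc[kept]
        self.n_removed_ = int((~keep).sum())
        logger.info(
            "genotype QC: kept %d of %d markers (removed %d)",
            len(kept),
            X.n_markers,
            self.n_removed_,
        )
        return self

    def transform(self, X: GenotypePanel) -> GenotypePanel:
        dos = X.dosages.loc[:, self.kept_markers_].copy()
        impute = 2.0 * self.allele_freq_
        dos = dos.fillna(impute)
        return GenotypePanel(dos)


class SparseOtuFilter(BaseEstimator, TransformerMixin):
    """Remove OTUs whose total raw count across samples is below a minimum.

    The threshold is inclusive: an OTU with total exactly
    ``min_total_count`` is retained.
    """

    def __init__(self, min_total_count: int = 1200):
        self.min_total_count = min_total_count

    def fit(self, X: OtuCountTable, y=None):
        totals = X.counts.sum(axis=0)
        keep = totals >= self.min_total_count
        if not keep.any():
            raise EmptyResultError("sparse-OTU filter removed every OTU")
        self.kept_otus_ = X.counts.columns[keep.to_numpy()].to_numpy()
        self.n_removed_ = int((~keep).sum())
        logger.info(
            "sparse-OTU filter: kept %d of %d OTUs (removed %d)",
            len(self.kept_otus_),
            X.n_otus,
            self.n_removed_,
        )
        return self

    def transform(self, X: OtuCountTable) -> OtuCountTable:
        return OtuCountTable(X.counts.loc[:, self.kept_otus_], stage=X.stage)


class Rarefier(BaseEstimator, TransformerMixin):
    """Subsample each sample's counts without replacement to a fixed depth.

    Samples whose total count is below ``depth`` cannot be rarefied and are
    dropped with a warning.  Subsampling is multivariate hypergeometric, so
    an OTU observed zero times stays zero.
    """

    def __init__(self, depth: int = 10_000, seed: int = 0):
        self.depth = depth
        self.seed = seed

    def fit(self, X: OtuCountTable, y=None):
        if self.depth < 1:
            raise HologenError("rarefaction depth must be >= 1")
        return self

    def transform(self, X: OtuCountTable) -> OtuCountTable:
        self.fit(X)
        rng = np.random.default_rng(self.seed)
        counts = X.counts.to_numpy()
        totals = counts.sum(axis=1)
        keep = totals >= self.depth
        n_drop = int((~keep).sum())
        if n_drop:
            dropped = X.counts.index[~keep].tolist()
            msg = (
                f"{n_drop} sample(s) below rarefaction depth {self.depth} "
                f"dropped: {dropped[:5]}{'...' if n_drop > 5 else ''}"
            )
            logger.warning(msg)
            warnings.warn(msg, UserWarning, stacklevel=2)
        if not keep.any():
            raise EmptyResultError("every sample is below the rarefaction depth")
        out = np.empty((int(keep.sum()), counts.shape[1]), dtype=np.int64)
        for i, row in enumerate(counts[keep]):
            out[i] = rng.multivariate_hypergeometric(row, self.depth)
        return OtuCountTable(
            pd.DataFrame(out, index=X.counts.index[keep], columns=X.counts.columns),
            stage=X.stage,
        )


def qc_genotypes(
    panel: GenotypePanel, min_call_rate: float = 0.90, min_maf: float = 0.05
) -> GenotypePanel:
    """One-shot genotype QC (filter + mean imputation) on a full panel."""
    return GenotypeQC(min_call_rate, min_maf).fit_transform(panel)


def filter_sparse_otus(
    table: OtuCountTable, min_total_count: int = 1200
) -> OtuCountTable:
    """One-shot sparse-OTU filter on raw counts."""
    return SparseOtuFilter(min_total_count).fit_transform(table)


def rarefy(table: OtuCountTable, depth: int = 10_000, seed: int = 0) -> OtuCountTable:
    """One-shot rarefaction to a constant per-sample depth."""
    return Rarefier(depth, seed).fit_transform(table)


def relative_abundance(table: OtuCountTable) -> pd.DataFrame:
    """Counts to relative abundances; every row sums to one.

    Raises on zero-total samples — rarefy (or otherwise filter) first.
    """
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        bad = table.counts.index[totals <= 0].tolist()
        raise HologenError(f"samples with zero total count: {bad[:5]}")
    S = pd.DataFrame(
        counts / totals[:, None], index=table.counts.index, columns=table.counts.columns
    )
    S.attrs["stage"] = table.stage
    return S
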