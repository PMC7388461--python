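"""Core containers shared across the pipeline.

All containers are thin, validated wrappers around pandas/numpy objects.
Animal/sample identity is always explicit: kernels and tables carry ordered
id vectors and alignment is by exact id match, never by silent reindexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

STAGES = ("Wean", "Mid-test", "Off-test")


class HologenError(ValueError):
    """Base class for domain errors raised by this package."""


class EmptyResultError(HologenError):
    """A filter or QC step removed every marker/OTU/sample."""


class IndexMismatchError(HologenError):
    """Two aligned objects do not carry identical ordered ids."""


class NoInformativeFeaturesError(HologenError):
    """An informative-reduction step selected zero features."""


@dataclass
class GenotypePanel:
    """Animals x markers additive dosages (0/1/2), NaN = missing call."""

    dosages: pd.DataFrame  # index: animal ids, columns: marker ids, float

    def __post_init__(self) -> None:
        if self.dosages.index.has_duplicates or self.dosages.columns.has_duplicates:
            raise HologenError("duplicate animal or marker ids in genotype panel")
        vals = self.dosages.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise HologenError("dosages must lie in [0, 2]")

    @property
    def animal_ids(self) -> np.ndarray:
        return self.dosages.index.to_numpy()

    @property
    def marker_ids(self) -> np.ndarray:
        return self.dosages.columns.to_numpy()

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def call_rate(self) -> pd.Series:
        """Fraction of non-missing dosages per marker."""
        return self.dosages.notna().mean(axis=0)

    def allele_frequency(self) -> pd.Series:
        """Counted-allele frequency per marker from non-missing entries."""
        return self.dosages.mean(axis=0, skipna=True) / 2.0

    def subset_markers(self, marker_ids) -> "GenotypePanel":
        return GenotypePanel(self.dosages.loc[:, list(marker_ids)])

    def subset_animals(self, animal_ids) -> "GenotypePanel":
        return GenotypePanel(self.dosages.loc[list(animal_ids)])


@dataclass
class OtuCountTable:
    """Samples x OTU non-negative integer counts for one growth stage."""

    counts: pd.DataFrame  # index: sample/animal ids, columns: OTU ids
    stage: str = STAGES[0]

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise HologenError("OTU counts must be integers")
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if vals.size and vals.min() < 0:
            raise HologenError("OTU counts must be non-negative")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise HologenError("duplicate sample or OTU ids in count table")

    @property
    def sample_ids(self) -> np.ndarray:
        return self.counts.index.to_numpy()

    @property
    def otu_ids(self) -> np.ndarray:
        return self.counts.columns.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]


@dataclass
class RelationshipKernel:
    """Symmetric PSD animal x animal covariance structure.

    kind is one of ``G`` (genomic, VanRaden method 1), ``M`` (microbial,
    XX'/q on log-standardized abundances) or ``GxM`` (Hadamard interaction).
    """

    animal_ids: np.ndarray
    matrix: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    SYM_TOL = 1e-10
    PSD_TOL = -1e-8

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids)
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.animal_ids)
        if self.matrix.shape != (n, n):
            raise HologenError("kernel matrix shape does not match id count")
        if len(set(self.animal_ids.tolist())) != n:
            raise HologenError("duplicate animal ids in kernel")
        if not np.isfinite(self.matrix).all():
            raise HologenError("kernel contains non-finite entries")
        asym = np.abs(self.matrix - self.matrix.T).max() if n else 0.0
        if asym > self.SYM_TOL:
            raise HologenError(f"kernel asymmetry {asym:.2e} exceeds tolerance")
        self.matrix = 0.5 * (self.matrix + self.matrix.T)

    def min_eigenvalue(self) -> float:
        from scipy.linalg import eigvalsh

        return float(eigvalsh(self.matrix, subset_by_index=(0, 0))[0])

    def check_psd(self) -> None:
        lam = self.min_eigenvalue()
        if lam < self.PSD_TOL:
            raise HologenError(f"kernel not PSD: min eigenvalue {lam:.3e}")

    @property
    def n(self) -> int:
        return len(self.animal_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.animal_ids, columns=self.animal_ids)


def check_same_animals(a: RelationshipKernel, b: RelationshipKernel) -> None:
    """Hard failure on any id or ordering mismatch between two kernels."""
    if len(a.animal_ids) != len(b.animal_ids) or not np.array_equal(
        a.animal_ids, b.animal_ids
    ):
        raise IndexMismatchError(
            "kernels are indexed by different animals or orderings; "
            "reorder explicitly before combining"
        )


@dataclass
class StandardizedOtuMatrix:
    """Log-transformed, centered, scaled OTU abundances (animals x OTU)."""

    values: pd.DataFrame
    centering: str
    sd_divisor: str
    dropped_otus: list = field(default_factory=list)
    column_center: pd.Series | None = None
    column_scale: pd.Series | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise HologenError("standardized OTU matrix contains non-finite entries")

    @property
    def n_otus(self) -> int:
        return self.values.shape[1]

    @property
    def animal_ids(self) -> np.ndarray:
        return self.values.index.to_numpy()


DESIGN_COLUMNS = ("sire", "dam_line", "sex", "contemporary_group", "pen")


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check the fixed/random design factors of a phenotype table.

    Requires the columns in DESIGN_COLUMNS, indexed by animal id; every pen
    must map to exactly one contemporary group (pens are nested).
    """
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise HologenError(f"design table missing columns: {missing}")
    if design.index.has_duplicates:
        raise HologenError("duplicate animal ids in design table")
    ncg = design.groupby("pen", observed=True)["contemporary_group"].nunique()
    if (ncg > 1).any():
        bad = ncg[ncg > 1].index.tolist()
        raise HologenError(f"pens mapped to multiple contemporary groups: {bad}")
    return design
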