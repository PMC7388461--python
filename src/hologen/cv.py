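"""Sire-grouped fourfold cross-validation of the model family.

Whole half-sib families are held out together: sires are partitioned into
folds (optionally grouping the most-related sires into the same fold), and
every progeny of a test sire is masked during fitting.  Within each
training fold the pipeline re-derives everything that could leak —
allele frequencies, OTU standardization statistics, and the IR/RR feature
sets — before kernels are built for the train+test animals and each model
is fitted with test phenotypes masked.  Predictions are scored on raw
phenotypes by Pearson correlation (predictive ability) and MSE.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    GenotypePanel,
    HologenError,
    NoInformativeFeaturesError,
    OtuCountTable,
)
from .kernels import OtuLogStandardizer, build_grm, build_microbial_kernel
from .preprocessing import relative_abundance
from .rkhs import McmcSettings, fit_rkhs, make_model_spec, predict_masked, MODEL_KERNELS
from .selection import scan_features, select_informative, select_random

logger = logging.getLogger(__name__)

COMPLEXITIES = ("FULL", "IR", "RR")


@dataclass
class FoldPlan:
    """Assignment of each sire to the single fold where it is tested."""

    sire_to_fold: pd.Series  # index: sire id, value: fold id (1-based)
    n_folds: int

    def __post_init__(self) -> None:
        folds = self.sire_to_fold.to_numpy()
        if set(folds) != set(range(1, self.n_folds + 1)):
            raise HologenError("every fold must test at least one sire")

    def test_sires(self, fold: int) -> list:
        return self.sire_to_fold.index[self.sire_to_fold == fold].tolist()

    def split_animals(self, design: pd.DataFrame, fold: int):
        """(train_ids, test_ids) for one fold, from the design's sire column."""
        test_sires = set(self.test_sires(fold))
        is_test = design["sire"].isin(test_sires).to_numpy()
        ids = design.index.to_numpy()
        return ids[~is_test], ids[is_test]

    @property
    def folds(self) -> range:
        return range(1, self.n_folds + 1)


def make_fold_plan(
    sires,
    n_folds: int = 4,
    grouping: pd.DataFrame | np.ndarray | None = None,
    seed: int = 0,
) -> FoldPlan:
    """Partition sires into equal-size folds.

    Without ``grouping``, the split is a random equal partition.  With a
    symmetric sire-relatedness matrix, a greedy agglomerative rule packs
    the most-related sires into the same fold (so close relatives never
    straddle the train/test boundary): each fold is seeded with the
    most-related unassigned pair and filled with the sire of highest mean
    relatedness to the current fold members.
    """
    sires = list(sires)
    n = len(sires)
    if n % n_folds != 0:
        raise HologenError(
            f"{n} sires are not divisible into {n_folds} folds "
            f"(remainder {n % n_folds})"
        )
    per_fold = n // n_folds
    if grouping is None:
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        assign = np.empty(n, dtype=int)
        for f in range(n_folds):
            assign[order[f * per_fold : (f + 1) * per_fold]] = f + 1
    else:
        R = (
            grouping.loc[sires, sires].to_numpy(dtype=float)
            if isinstance(grouping, pd.DataFrame)
            else np.asarray(grouping, dtype=float)
        )
        if R.shape != (n, n) or not np.allclose(R, R.T):
            raise HologenError("grouping must be a symmetric sires x sires matrix")
        assign = np.zeros(n, dtype=int)
        unassigned = set(range(n))
        for f in range(1, n_folds + 1):
            members: list[int] = []
            if per_fold >= 2 and len(unassigned) >= 2:
                best, pair = -np.inf, None
                for i in sorted(unassigned):
                    for j in sorted(unassigned):
                        if j <= i:
                            continue
                        if R[i, j] > best:
                            best, pair = R[i, j], (i, j)
                members = list(pair)
            else:
                members = [min(unassigned)]
            unassigned -= set(members)
            while len(members) < per_fold:
                cand = sorted(unassigned)
                scores = [R[k, members].mean() for k in cand]
                pick = cand[int(np.argmax(scores))]
                members.append(pick)
                unassigned.remove(pick)
            assign[members] = f
    return FoldPlan(pd.Series(assign, index=pd.Index(sires, name="sire")), n_folds)


def evaluate_predictions(y_obs, y_hat) -> tuple[float, float]:
    """Predictive ability (Pearson r) and MSE on raw phenotypes.

    With zero variance in either vector r is undefined; it is returned as
    NaN with a warning while the MSE is still computed.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y_obs.shape != y_hat.shape or y_obs.size < 3:
        raise HologenError("need equal-length vectors with at least 3 entries")
    mse = float(np.mean((y_obs - y_hat) ** 2))
    if np.var(y_obs) == 0 or np.var(y_hat) == 0:
        warnings.warn(
            "zero variance in observed or predicted values: r undefined",
            UserWarning,
            stacklevel=2,
        )
        return float("nan"), mse
    r = float(stats.pearsonr(y_obs, y_hat).statistic)
    return r, mse


@dataclass
class CvData:
    """Inputs of a cross-validation run.

    records: design factors + trait columns, indexed by animal id;
    panel: QC'd genotype panel (no missing values);
    otu_tables: rarefied count table per stage.
    """

    records: pd.DataFrame
    panel: GenotypePanel
    otu_tables: dict[str, OtuCountTable]
    traits: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.traits:
            raise HologenError("CvData needs at least one trait name")
        ids = self.records.index.to_numpy()
        if not np.array_equal(self.panel.animal_ids, ids):
            raise HologenError("genotype panel and records are not aligned")
        for stage, tab in self.otu_tables.items():
            if not np.array_equal(tab.sample_ids, ids):
                raise HologenError(f"OTU table for {stage} not aligned with records")


def _cell_seed(base_seed: int, *parts) -> int:
    tag = "|".join(str(p) for p in parts)
    return (int(base_seed) ^ zlib.crc32(tag.encode())) % (2**31 - 1)


def run_cv(
    data: CvData,
    plan: FoldPlan,
    model_ids=("M0", "M1", "M2", "M3", "M4"),
    complexities=("FULL",),
    mcmc: McmcSettings | None = None,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Full cross-validation sweep over trait x stage x model x complexity.

    Returns a tidy frame (trait, stage, model, complexity, fold, r, mse,
    n_test, note).  M0 carries no stage, kernel or feature-set dependence,
    so it is fitted once per fold x trait and its score replicated across
    stages and complexities.  Cells whose IR selection is empty are
    recorded as not estimable (NaN scores) and the run continues.
    """
    mcmc = mcmc or McmcSettings.fast()
    stages = list(data.otu_tables)
    rows = []
    for fold in plan.folds:
        train_ids, test_ids = plan.split_animals(data.records, fold)
        train_records = data.records.loc[train_ids]
        mask_records = data.records.copy()
        mask_records.loc[test_ids, data.traits] = np.nan

        # stage-wise raw relative abundances (needed for scans and kernels)
        S_all = {st: relative_abundance(data.otu_tables[st]) for st in stages}

        # baseline model once per trait
        m0_scores = {}
        if "M0" in model_ids:
            for trait in data.traits:
                spec = make_model_spec("M0", complexity="FULL")
                cell_mcmc = McmcSettings(
                    n_iter=mcmc.n_iter,
                    burn_in=mcmc.burn_in,
                    thin=mcmc.thin,
                    seed=_cell_seed(mcmc.seed, fold, trait, "M0"),
                    prior_df=mcmc.prior_df,
                    prior_r2=mcmc.prior_r2,
                )
                res = fit_rkhs(mask_records, trait, spec, cell_mcmc)
                yhat = predict_masked(res, mask_records)
                m0_scores[trait] = evaluate_predictions(
                    data.records.loc[yhat.index, trait], yhat
                )

        for trait in data.traits:
            # per-complexity feature sets (IR/RR re-derived inside the fold)
            feature_sets: dict[str, dict] = {}
            for cx in complexities:
                if cx == "FULL":
                    feature_sets[cx] = {
                        "markers": list(data.panel.marker_ids),
                        "otus": {st: list(S_all[st].columns) for st in stages},
                        "note": "",
                    }
                elif cx in ("IR", "RR"):
                    if "IR" not in feature_sets:
                        feature_sets["IR"] = _informative_sets(
                            data, train_ids, train_records, S_all, trait, stages,
                            alpha, fold,
                        )
                    if cx == "RR":
                        feature_sets["RR"] = _random_sets(
                            data, S_all, feature_sets["IR"], stages,
                            _cell_seed(seed, fold, trait, "RR"),
                        )
                else:
                    raise HologenError(f"unknown complexity {cx!r}")

            for cx in complexities:
                fs = feature_sets[cx]
                for stage in stages:
                    kernels = _fold_kernels(data, S_all, fs, stage, train_ids)
                    for model_id in model_ids:
                        if model_id == "M0":
                            r, mse = m0_scores[trait]
                            rows.append(
                                dict(
                                    trait=trait, stage=stage, model="M0",
                                    complexity=cx, fold=fold, r=r, mse=mse,
                                    n_test=len(test_ids), note="",
                                )
                            )
                            continue
                        note = _missing_kernel_note(model_id, kernels, fs)
                        if note:
                            rows.append(
                                dict(
                                    trait=trait, stage=stage, model=model_id,
                                    complexity=cx, fold=fold, r=np.nan,
                                    mse=np.nan, n_test=len(test_ids), note=note,
                                )
                            )
                            continue
                        spec = make_model_spec(
                            model_id,
                            G=kernels.get("G"),
                            M=kernels.get("M"),
                            stage=stage,
                            complexity=cx,
                        )
                        cell_mcmc = McmcSettings(
                            n_iter=mcmc.n_iter,
                            burn_in=mcmc.burn_in,
                            thin=mcmc.thin,
                            seed=_cell_seed(mcmc.seed, fold, trait, stage, model_id, cx),
                            prior_df=mcmc.prior_df,
                            prior_r2=mcmc.prior_r2,
                        )
                        res = fit_rkhs(mask_records, trait, spec, cell_mcmc)
                        yhat = predict_masked(res, mask_records)
                        r, mse = evaluate_predictions(
                            data.records.loc[yhat.index, trait], yhat
                        )
                        rows.append(
                            dict(
                                trait=trait, stage=stage, model=model_id,
                                complexity=cx, fold=fold, r=r, mse=mse,
                                n_test=len(test_ids), note="",
                            )
                        )
    return pd.DataFrame(rows)


def _informative_sets(data, train_ids, train_records, S_all, trait, stages, alpha, fold):
    """IR marker and OTU sets from scans on the training fold only."""
    out = {"markers": [], "otus": {}, "note": ""}
    marker_scan = scan_features(
        train_records,
        data.panel.dosages.loc[train_ids],
        trait,
        feature_type="marker",
        fold=fold,
    )
    try:
        out["markers"] = select_informative(marker_scan, alpha)
    except NoInformativeFeaturesError:
        out["note"] = "no informative markers"
    for st in stages:
        otu_scan = scan_features(
            train_records,
            S_all[st].loc[train_ids],
            trait,
            feature_type="OTU",
            stage=st,
            fold=fold,
        )
        try:
            out["otus"][st] = select_informative(otu_scan, alpha)
        except NoInformativeFeaturesError:
            out["otus"][st] = []
    return out


def _random_sets(data, S_all, ir_sets, stages, seed):
    """RR sets: random features, size-matched to the IR sets."""
    out = {"markers": [], "otus": {}, "note": ir_sets["note"]}
    k_m = len(ir_sets["markers"])
    if k_m:
        out["markers"] = select_random(data.panel.marker_ids, k_m, seed=seed)
    for i, st in enumerate(stages):
        k_o = len(ir_sets["otus"].get(st, []))
        if k_o:
            out["otus"][st] = select_random(S_all[st].columns, k_o, seed=seed + i + 1)
        else:
            out["otus"][st] = []
    return out


def _fold_kernels(data, S_all, fs, stage, train_ids):
    """G and M over train+test animals with training-only statistics."""
    kernels = {}
    if fs["markers"]:
        sub = data.panel.subset_markers(fs["markers"])
        p_train = sub.subset_animals(train_ids).allele_frequency()
        if float(np.sum(p_train * (1 - p_train))) > 0:
            kernels["G"] = build_grm(sub, allele_freq=p_train)
    otus = fs["otus"].get(stage, [])
    if otus:
        S = S_all[stage].loc[:, otus]
        std = OtuLogStandardizer().fit(S.loc[train_ids])
        kernels["M"] = build_microbial_kernel(std.transform(S))
    return kernels


def _missing_kernel_note(model_id, kernels, fs) -> str:
    need = MODEL_KERNELS[model_id]
    if "G" in need and "G" not in kernels:
        return "not estimable: no marker kernel"
    if "M" in need and "M" not in kernels:
        return "not estimable: no OTU kernel"
    return ""
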