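"""Canonical simulation experiments exercising the whole pipeline.

These functions define the package's reference study conditions — a
half-sib population of 28 sires x 20 progeny (560 animals, two single-sire
pens per sire), dense-chip genotypes in LD blocks, and stage-wise OTU
compositions — and run the standard validation experiments on them:
variance-fraction recovery, null calibration, cross-validated model
ordering, and association-scan calibration.  Both the test suite and the
acceptance script call these, so the conditions are defined in one place.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cv import CvData, make_fold_plan, run_cv
from .datatypes import NoInformativeFeaturesError
from .rkhs import McmcSettings, fit_rkhs, make_model_spec
from .selection import scan_features, select_informative
from .simulate import SimulationConfig, simulate_dataset

#: variance partition of the reference recovery experiment
RECOVERY_FRACTIONS = {
    "additive": 0.30,
    "microbiome": 0.20,
    "interaction": 0.10,
    "pen": 0.05,
    "residual": 0.35,
}


def reference_config(seed: int, **overrides) -> SimulationConfig:
    """The 560-animal reference population (28 sires x 20 progeny, two
    single-sire pens of 10 per sire, 5,000 markers, 500 OTUs)."""
    kw = dict(
        n_sires=28,
        progeny_per_sire=20,
        pigs_per_pen=10,
        n_markers=5000,
        n_otu=500,
        var_fractions=dict(RECOVERY_FRACTIONS),
        seed=seed,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


def recovery_experiment(
    seed: int, n_seeds: int = 5, mcmc_seed_offset: int = 1000
) -> pd.DataFrame:
    """Fit M4 on data with a known variance partition, several replicates.

    Returns one row per replicate with the fitted posterior-mean fractions
    (h2, m2, i2, pen2) and the ESS of each variance chain.
    """
    rows = []
    for i in range(n_seeds):
        cfg = reference_config(seed + i)
        d = simulate_dataset(cfg)
        res = fit_rkhs(
            d.records,
            "trait1",
            make_model_spec("M4", G=d.G, M=d.M),
            McmcSettings.fast(seed=seed + mcmc_seed_offset + i),
        )
        s = res.summary
        rows.append(
            {
                "seed": seed + i,
                "h2": s.heritability,
                "m2": s.microbiability,
                "i2": s.interaction_fraction,
                "pen2": s.fraction_mean("pen"),
                "min_ess": float(s.table["ess"].min()),
            }
        )
    return pd.DataFrame(rows)


def null_fit_experiment(seed: int) -> dict:
    """Fit M4 on data simulated without microbiome or interaction effects.

    The phenotype carries additive (0.30) and pen (0.05) variance only, so
    the fitted m2 and i2 measure the model's null calibration.
    """
    cfg = reference_config(
        seed,
        var_fractions={
            "additive": 0.30,
            "microbiome": 0.0,
            "interaction": 0.0,
            "pen": 0.05,
            "residual": 0.65,
        },
    )
    d = simulate_dataset(cfg)
    res = fit_rkhs(
        d.records,
        "trait1",
        make_model_spec("M4", G=d.G, M=d.M),
        McmcSettings.fast(seed=seed + 777),
    )
    return {
        "m2_null": res.summary.microbiability,
        "i2_null": res.summary.interaction_fraction,
        "h2": res.summary.heritability,
    }


def selection_fwe_experiment(
    seed: int, n_replicates: int = 200, n_animals: int = 240, n_features: int = 400
) -> float:
    """Family-wise error of Bonferroni selection under a global null.

    Each replicate scans iid-noise features against a pure-noise phenotype
    and records whether any feature passes the corrected threshold.
    Returns the fraction of replicates with a non-empty selection.
    """
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(
        n_sires=12, progeny_per_sire=n_animals // 12, pigs_per_pen=10,
        n_markers=10, n_otu=10, seed=seed,
    )
    d = simulate_dataset(cfg)
    records = d.records.copy()
    features = pd.DataFrame(
        rng.normal(size=(len(records), n_features)),
        index=records.index,
        columns=[f"F{j}" for j in range(n_features)],
    )
    hits = 0
    for _ in range(n_replicates):
        records["trait1"] = rng.normal(size=len(records))
        scan = scan_features(records, features, "trait1")
        try:
            select_informative(scan, alpha=0.05)
            hits += 1
        except NoInformativeFeaturesError:
            pass
    return hits / n_replicates


def scan_calibration_experiment(
    seed: int, n_features: int = 2000
) -> dict:
    """Null uniformity and power of the single-feature scan at n = 560.

    Returns the KS distance of null p-values from U(0,1), and the power to
    detect a feature explaining 10% of phenotypic variance at the
    Bonferroni threshold over 20 replicates.
    """
    cfg = reference_config(seed, n_markers=100, n_otu=10)
    d = simulate_dataset(cfg)
    records = d.records.copy()
    n = len(records)
    rng = np.random.default_rng(seed + 1)
    # null: iid features, iid phenotype
    features = pd.DataFrame(
        rng.normal(size=(n, n_features)),
        index=records.index,
        columns=[f"F{j}" for j in range(n_features)],
    )
    records["noise"] = rng.normal(size=n)
    scan = scan_features(records, features, "noise")
    pvals = scan["p_value"].dropna().to_numpy()
    ks = float(stats.kstest(pvals, "uniform").statistic)

    # power: one spiked feature carrying 10% of the phenotypic variance
    threshold = 0.05 / n_features
    detected = 0
    n_rep = 20
    for rep in range(n_rep):
        x = rng.normal(size=n)
        y = np.sqrt(0.10) * (x - x.mean()) / x.std() + np.sqrt(0.90) * rng.normal(
            size=n
        )
        records["spiked"] = y
        feats = features.copy()
        feats["Fspike"] = x
        res = scan_features(records, feats, "spiked")
        p_spike = float(res.loc[res["feature"] == "Fspike", "p_value"].iloc[0])
        if p_spike < threshold:
            detected += 1
    return {"ks_null": ks, "power_10pct": detected / n_rep, "n_features": n_features}


def ordering_experiment(seed: int) -> dict:
    """Cross-validated model ordering on planted-signal data.

    Microbiome-dominated data (m2 = 0.30) compare M2 against the baseline
    M0; genome-dominated data (h2 = 0.35) compare M1 against M2.  Both use
    the fourfold sire-grouped plan and the fast MCMC profile.
    """

    def one(vf, models, s):
        cfg = reference_config(
            s, n_markers=2000, n_stages=1, var_fractions=vf,
        )
        d = simulate_dataset(cfg)
        data = CvData(
            records=d.records, panel=d.panel, otu_tables=d.otu_tables,
            traits=["trait1"],
        )
        plan = make_fold_plan(sorted(d.design["sire"].unique()), 4, seed=s)
        grid = run_cv(data, plan, model_ids=models, mcmc=McmcSettings.fast(seed=s))
        return grid.groupby("model")["r"].mean()

    micro = one(
        {"additive": 0.05, "microbiome": 0.30, "interaction": 0.0,
         "pen": 0.05, "residual": 0.60},
        ("M0", "M2"),
        seed,
    )
    geno = one(
        {"additive": 0.35, "microbiome": 0.05, "interaction": 0.0,
         "pen": 0.05, "residual": 0.55},
        ("M1", "M2"),
        seed + 1,
    )
    return {
        "r_m0_micro": float(micro["M0"]),
        "r_m2_micro": float(micro["M2"]),
        "gain_m2_over_m0": float(micro["M2"] - micro["M0"]),
        "r_m1_geno": float(geno["M1"]),
        "r_m2_geno": float(geno["M2"]),
        "margin_m1_over_m2": float(geno["M1"] - geno["M2"]),
    }
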