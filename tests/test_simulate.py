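"""Synthetic-population generator: structure, determinism, variance bookkeeping."""

import numpy as np
import pandas as pd
import pytest

import hologen as hg
from hologen.simulate import substream


class TestConfigValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(hg.HologenError, match="sum to 1"):
            hg.SimulationConfig(
                var_fractions={"additive": 0.5, "residual": 0.4}
            )

    def test_zero_progeny_rejected(self):
        with pytest.raises(hg.HologenError):
            hg.SimulationConfig(progeny_per_sire=0)

    def test_zero_markers_rejected(self):
        with pytest.raises(hg.HologenError):
            hg.SimulationConfig(n_markers=0)

    def test_bad_maf_range_rejected(self):
        with pytest.raises(hg.HologenError):
            hg.SimulationConfig(maf_range=(0.0, 0.6))


class TestPopulation:
    def test_counts_follow_config(self, small_config, small_dataset):
        assert small_dataset.panel.n_animals == 80
        assert small_dataset.design["sire"].nunique() == 8
        sizes = small_dataset.design.groupby("sire").size()
        assert (sizes == 10).all()

    def test_same_seed_is_byte_identical(self, small_config):
        a, _ = hg.simulate_population(small_config)
        b, _ = hg.simulate_population(small_config)
        assert a.dosages.equals(b.dosages)

    def test_pens_are_single_sire_single_sex(self, small_dataset):
        per_pen = small_dataset.design.groupby("pen").agg(
            {"sire": "nunique", "sex": "nunique", "contemporary_group": "nunique"}
        )
        assert (per_pen == 1).all().all()

    def test_half_sib_dosage_correlation_near_quarter(self):
        cfg = hg.SimulationConfig(
            n_sires=30, progeny_per_sire=8, pigs_per_pen=4, n_markers=5000,
            n_otu=10, seed=21,
        )
        panel, design = hg.simulate_population(cfg)
        X = panel.dosages.to_numpy()
        Xc = (X - X.mean(axis=0)) / X.std(axis=0)
        corrs = []
        sires = design["sire"].to_numpy()
        for s in np.unique(sires):
            idx = np.where(sires == s)[0]
            a, b = idx[0], idx[1]
            corrs.append(np.mean(Xc[a] * Xc[b]))
        assert abs(np.mean(corrs) - 0.25) < 0.03

    def test_markers_in_ld_blocks_are_correlated(self, small_dataset):
        X = small_dataset.panel.dosages.to_numpy()
        X = X - X.mean(axis=0)
        # first two markers share a block, markers 0 and 25 do not
        def corr(j, k):
            return np.corrcoef(X[:, j], X[:, k])[0, 1]

        within = abs(corr(0, 1))
        between = abs(corr(0, 25))
        assert within > 0.5
        assert within > between


class TestOtuTable:
    def test_counts_sum_to_depth(self, small_config):
        tab = hg.simulate_otu_table(small_config, "Wean")
        assert (tab.counts.sum(axis=1) == small_config.sequencing_depth).all()

    def test_deterministic_per_stage(self, small_config):
        a = hg.simulate_otu_table(small_config, "Wean")
        b = hg.simulate_otu_table(small_config, "Wean")
        c = hg.simulate_otu_table(small_config, "Mid-test")
        assert a.counts.equals(b.counts)
        assert not a.counts.equals(c.counts)

    def test_two_otu_symmetric_means(self):
        cfg = hg.SimulationConfig(
            n_sires=25, progeny_per_sire=20, pigs_per_pen=10, n_markers=10,
            n_otu=2, otu_mean_sd=0.0, sequencing_depth=10_000, seed=5,
        )
        tab = hg.simulate_otu_table(cfg, "Wean")
        share = (tab.counts / 10_000).mean(axis=0)
        assert np.allclose(share, 0.5, atol=0.02)

    def test_no_host_covariate_means_no_genotype_association(self, small_dataset):
        """Without the host channel, OTU log-abundance is uncorrelated with
        the leading genotype axis."""
        cfg = small_dataset.config
        X = small_dataset.panel.dosages.to_numpy()
        Xc = X - X.mean(axis=0)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        pc1 = Xc @ vt[0]
        tab = hg.simulate_otu_table(cfg, "Wean")
        logs = np.log(tab.counts.to_numpy() + 1.0)
        cors = [
            np.corrcoef(pc1, logs[:, j])[0, 1]
            for j in range(0, cfg.n_otu, 3)
        ]
        # mean correlation ~ N(0, 1/sqrt(n)) under the null
        assert abs(np.mean(cors)) < 3.0 / np.sqrt(len(pc1))

    def test_host_covariate_induces_association(self, small_dataset):
        cfg = small_dataset.config
        cov = np.linspace(-2, 2, cfg.n_animals)
        tab = hg.simulate_otu_table(cfg, "Wean", host_covariate=cov)
        logs = np.log(tab.counts.to_numpy() + 1.0)
        cors = np.array(
            [np.corrcoef(cov, logs[:, j])[0, 1] for j in range(cfg.n_otu)]
        )
        assert np.abs(cors).max() > 0.4

    def test_negative_depth_rejected(self, small_config):
        import dataclasses

        bad = dataclasses.replace(small_config, sequencing_depth=-1)
        with pytest.raises(hg.HologenError):
            hg.simulate_otu_table(bad, "Wean")


class TestPhenotypes:
    def test_decomposition_is_exact(self, small_dataset):
        for trait in small_dataset.traits:
            y = small_dataset.records[trait]
            total = small_dataset.truth.phenotype(trait)
            assert np.array_equal(y.to_numpy(), total.to_numpy())

    def test_zero_fraction_components_are_zero(self, small_dataset):
        cfg = small_dataset.config
        import dataclasses

        cfg0 = dataclasses.replace(
            cfg,
            var_fractions={
                "additive": 0.5, "microbiome": 0.0, "interaction": 0.0,
                "pen": 0.0, "residual": 0.5,
            },
        )
        records, truth = hg.simulate_phenotypes(
            small_dataset.G, small_dataset.M, small_dataset.design, cfg0
        )
        comp = truth.components["trait1"]
        assert (comp["microbiome"] == 0).all()
        assert (comp["interaction"] == 0).all()
        assert (comp["pen"] == 0).all()

    def test_realized_fractions_near_targets(self):
        """Monte-Carlo: component sample variances track the configured
        fractions at n = 560, averaged over replicates."""
        reps = []
        for seed in range(6):
            cfg = hg.SimulationConfig(
                n_sires=28, progeny_per_sire=20, pigs_per_pen=10,
                n_markers=800, n_otu=200, seed=seed,
            )
            d = hg.simulate_dataset(cfg)
            reps.append(d.truth.realized_fractions("trait1"))
        mean = pd.concat(reps, axis=1).mean(axis=1)
        for comp, target in cfg.var_fractions.items():
            assert abs(mean[comp] - target) < 0.05, comp

    def test_kernel_mismatch_rejected(self, small_dataset):
        K = hg.RelationshipKernel(
            np.array(["x", "y"]), np.eye(2), kind="G"
        )
        with pytest.raises(hg.HologenError):
            hg.simulate_phenotypes(
                K, K, small_dataset.design, small_dataset.config
            )


def test_named_substreams_are_independent():
    a = substream(3, "genotypes").normal(size=5)
    b = substream(3, "phenotypes").normal(size=5)
    a2 = substream(3, "genotypes").normal(size=5)
    assert np.array_equal(a, a2)
    assert not np.array_equal(a, b)
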