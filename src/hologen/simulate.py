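"""Synthetic hologenomic populations with a known variance partition.

Emulates the structure of a commercial swine trial: half-sib families from a
set of purebred sires, single-sire single-sex pens nested in contemporary
groups, SNP genotypes, stage-wise gut microbiome (OTU) compositions, and
phenotypes built as the exact sum of fixed effects plus genomic, microbial,
genome-by-microbiome interaction, pen and residual deviations.

Every random draw comes from a named substream of one root seed, so each
component (genotypes, each stage's OTU table, phenotypes) is individually
reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    STAGES,
    GenotypePanel,
    HologenError,
    OtuCountTable,
    RelationshipKernel,
    check_same_animals,
    validate_design,
)

#: canonical variance-component names used throughout the package
COMPONENTS = ("additive", "microbiome", "interaction", "pen", "residual")


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent RNG stream derived from (root seed, component name)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


@dataclass
class SimulationConfig:
    n_sires: int = 28
    progeny_per_sire: int = 20
    n_markers: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    # markers come in haplotype blocks in strong LD; the number of blocks
    # (n_markers / ld_block_size) sets the effective number of independently
    # segregating segments, as on a dense livestock SNP chip
    ld_block_size: int = 10
    ld_flip_rate: float = 0.1
    n_otu: int = 500
    n_stages: int = 3
    stage_labels: tuple[str, ...] = STAGES
    sequencing_depth: int = 10_000
    n_contemporary_groups: int = 6
    pigs_per_pen: int = 20
    var_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "additive": 0.30,
            "microbiome": 0.20,
            "interaction": 0.10,
            "pen": 0.05,
            "residual": 0.35,
        }
    )
    n_traits: int = 1
    fixed_effect_sizes: Mapping[str, float] = field(
        default_factory=lambda: {
            "dam_line": 0.3,
            "sex": 0.3,
            "contemporary_group": 0.5,
        }
    )
    total_variance: float = 1.0
    # latent OTU community shape: a few shared community axes give the
    # microbiome real between-animal covariance (enterotype-like gradients)
    otu_mean_sd: float = 1.5
    otu_latent_corr: float = 0.3
    n_community_factors: int = 5
    host_effect_size: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sires <= 0 or self.progeny_per_sire <= 0:
            raise HologenError("need at least one sire with at least one progeny")
        if self.n_markers <= 0:
            raise HologenError("need at least one marker")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise HologenError("maf_range must satisfy 0 < low <= high <= 0.5")
        fracs = dict(self.var_fractions)
        unknown = set(fracs) - set(COMPONENTS)
        if unknown:
            raise HologenError(f"unknown variance components: {sorted(unknown)}")
        for name in COMPONENTS:
            fracs.setdefault(name, 0.0)
        if any(v < 0 for v in fracs.values()):
            raise HologenError("variance fractions must be non-negative")
        if abs(sum(fracs.values()) - 1.0) > 1e-12:
            raise HologenError("variance fractions must sum to 1")
        self.var_fractions = fracs
        if self.n_stages > len(self.stage_labels):
            self.stage_labels = tuple(
                f"stage{i + 1}" for i in range(self.n_stages)
            )

    @property
    def n_animals(self) -> int:
        return self.n_sires * self.progeny_per_sire

    @property
    def stages(self) -> tuple[str, ...]:
        return tuple(self.stage_labels[: self.n_stages])

    @property
    def trait_names(self) -> list[str]:
        return [f"trait{i + 1}" for i in range(self.n_traits)]


def _animal_ids(config: SimulationConfig) -> np.ndarray:
    width = max(4, len(str(config.n_animals)))
    return np.array([f"A{i + 1:0{width}d}" for i in range(config.n_animals)])


def simulate_population(
    config: SimulationConfig,
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Half-sib families with single-sire, single-sex pens.

    Each marker segregates independently at an allele frequency drawn
    uniformly from ``maf_range``.  Every progeny inherits one allele sampled
    from its sire's two allele copies and one allele drawn from the
    population, inducing the half-sib genotype covariance of ~0.25.

    Returns the genotype panel and a design table (animal id index with
    sire, dam_line, sex, contemporary_group, pen columns).
    """
    rng = substream(config.seed, "genotypes")
    n_sires, n_prog = config.n_sires, config.progeny_per_sire
    n_animals, n_markers = config.n_animals, config.n_markers

    # haplotype-block LD: markers within a block share one segregating core
    # allele (frequency drawn from maf_range) plus per-marker flip noise,
    # and are transmitted as one unit (no recombination within a block)
    block_size = max(1, min(config.ld_block_size, n_markers))
    n_blocks = int(np.ceil(n_markers / block_size))
    block_of = np.minimum(np.arange(n_markers) // block_size, n_blocks - 1)
    p_block = rng.uniform(*config.maf_range, size=n_blocks)
    p = p_block[block_of]
    eps = rng.uniform(0.0, config.ld_flip_rate, size=n_markers)

    def make_haplotypes(n_h: int, gen: np.random.Generator) -> np.ndarray:
        core = (gen.random((n_h, n_blocks)) < p_block[None, :]).astype(np.int8)
        base = core[:, block_of]
        repl = (gen.random((n_h, n_markers)) < p[None, :]).astype(np.int8)
        use_repl = gen.random((n_h, n_markers)) < eps[None, :]
        return np.where(use_repl, repl, base)

    sire_haps = make_haplotypes(2 * n_sires, rng).reshape(n_sires, 2, n_markers)
    sire_of = np.repeat(np.arange(n_sires), n_prog)
    pick_block = rng.integers(0, 2, size=(n_animals, n_blocks))
    pick = pick_block[:, block_of]
    paternal = sire_haps[sire_of[:, None], pick, np.arange(n_markers)[None, :]]
    maternal = make_haplotypes(n_animals, rng)
    dosages = (paternal + maternal).astype(np.int8)

    animal_ids = _animal_ids(config)
    marker_ids = [f"SNP{j + 1}" for j in range(n_markers)]
    panel = GenotypePanel(
        pd.DataFrame(dosages.astype(float), index=animal_ids, columns=marker_ids)
    )

    rng_design = substream(config.seed, "design")
    # pens are filled within sire so each pen holds one sire's progeny only
    pen_within = np.concatenate(
        [np.arange(n_prog) // config.pigs_per_pen for _ in range(n_sires)]
    )
    pens_per_sire = int(np.ceil(n_prog / config.pigs_per_pen))
    pen_idx = sire_of * pens_per_sire + pen_within
    n_pens = n_sires * pens_per_sire
    # sex alternates within sire (offset by sire so totals balance); pens are
    # shuffled into contemporary groups so sex and group stay unconfounded
    pen_sex = np.array(
        [("M", "F")[(s + w) % 2] for s in range(n_sires) for w in range(pens_per_sire)]
    )
    pen_cg = rng_design.permutation(n_pens) % config.n_contemporary_groups
    design = pd.DataFrame(
        {
            "sire": [f"S{s + 1:02d}" for s in sire_of],
            "dam_line": rng_design.choice(["DL1", "DL2"], size=n_animals),
            "sex": pen_sex[pen_idx],
            "contemporary_group": [f"CG{pen_cg[i] + 1}" for i in pen_idx],
            "pen": [f"P{i + 1:03d}" for i in pen_idx],
        },
        index=pd.Index(animal_ids, name="animal"),
    )
    return panel, validate_design(design)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def simulate_otu_table(
    config: SimulationConfig,
    stage: str,
    host_covariate: np.ndarray | None = None,
) -> OtuCountTable:
    """Logistic-normal OTU compositions sampled as multinomial counts.

    Per animal a latent multivariate-normal vector (exchangeable correlation
    ``otu_latent_corr`` through a shared factor, OTU-level means with spread
    ``otu_mean_sd``) is softmax-transformed to relative abundances and counts
    are drawn as a multinomial at ``sequencing_depth``.  A per-animal
    ``host_covariate`` optionally shifts the latent means along a fixed
    random direction (strength ``host_effect_size``), making the microbiome
    depend on the host.
    """
    if config.n_otu < 2:
        raise HologenError("need at least two OTUs")
    if config.sequencing_depth < 1:
        raise HologenError("sequencing depth must be >= 1")
    rng = substream(config.seed, f"otu:{stage}")
    n, q = config.n_animals, config.n_otu

    mu = rng.normal(0.0, config.otu_mean_sd, size=q)
    rho = config.otu_latent_corr
    k = max(1, config.n_community_factors)
    scores = rng.normal(size=(n, k))  # per-animal positions on community axes
    loadings = rng.normal(size=(q, k)) / np.sqrt(k)  # per-OTU axis loadings
    eps = rng.normal(size=(n, q))
    z = mu[None, :] + np.sqrt(rho) * scores @ loadings.T + np.sqrt(1.0 - rho) * eps
    if host_covariate is not None:
        cov = np.asarray(host_covariate, dtype=float)
        if cov.shape != (n,):
            raise HologenError("host_covariate length must equal number of animals")
        direction = rng.normal(size=q)
        z = z + config.host_effect_size * cov[:, None] * direction[None, :]

    probs = _softmax(z)
    counts = np.vstack(
        [rng.multinomial(config.sequencing_depth, probs[i]) for i in range(n)]
    )
    return OtuCountTable(
        pd.DataFrame(
            counts,
            index=pd.Index(_animal_ids(config), name="animal"),
            columns=[f"OTU{j + 1}" for j in range(q)],
        ),
        stage=stage,
    )


@dataclass
class TrueComponents:
    """Realized per-animal deviations of every phenotype component.

    ``components[trait]`` has columns fixed, additive, microbiome,
    interaction, pen, residual; their row sum reproduces the phenotype to
    machine precision.
    """

    components: dict[str, pd.DataFrame]

    def phenotype(self, trait: str) -> pd.Series:
        return self.components[trait].sum(axis=1)

    def realized_fractions(self, trait: str) -> pd.Series:
        """Sample variance of each random component over animals, as a
        fraction of their summed variance."""
        df = self.components[trait]
        var = df[list(COMPONENTS)].var(axis=0, ddof=1)
        return var / var.sum()


def _kernel_root(K: np.ndarray) -> np.ndarray:
    lam, U = np.linalg.eigh(K)
    lam = np.clip(lam, 0.0, None)
    return U * np.sqrt(lam)[None, :]


def simulate_phenotypes(
    G: RelationshipKernel,
    M: RelationshipKernel,
    design: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, TrueComponents]:
    """Phenotypes as the sum of fixed effects and five random deviations.

    a ~ N(0, G v_a), o ~ N(0, M v_o), ao ~ N(0, (G∘M) v_ao), pen effects and
    residuals iid normal.  Component variances are scaled by each kernel's
    mean diagonal so that the realized variance fractions target
    ``config.var_fractions`` in expectation (draws stay exactly Gaussian
    with the stated covariance; no post-hoc rescaling).

    Returns a records table (design + one column per trait) and the stored
    TrueComponents.
    """
    check_same_animals(G, M)
    if not np.array_equal(G.animal_ids, design.index.to_numpy()):
        raise HologenError("kernel animals do not match design table")
    n = G.n
    rng = substream(config.seed, "phenotypes")
    rng_fx = substream(config.seed, "fixed-effects")
    total = config.total_variance
    fr = config.var_fractions

    GM = RelationshipKernel(G.animal_ids, G.matrix * M.matrix, kind="GxM")
    roots = {}
    for name, K in (("additive", G), ("microbiome", M), ("interaction", GM)):
        if fr[name] > 0:
            mean_diag = float(np.mean(np.diag(K.matrix)))
            if mean_diag <= 0:
                raise HologenError(f"{name} kernel has non-positive mean diagonal")
            roots[name] = (_kernel_root(K.matrix), fr[name] * total / mean_diag)

    # fixed-effect level values, drawn once per config seed
    sizes = config.fixed_effect_sizes
    level_effects: dict[str, dict[str, float]] = {}
    for factor_name in ("dam_line", "sex", "contemporary_group"):
        levels = sorted(design[factor_name].unique())
        size = float(sizes.get(factor_name, 0.0))
        if len(levels) == 2:
            eff = {levels[0]: -size / 2.0, levels[1]: size / 2.0}
        else:
            draws = rng_fx.normal(0.0, size if size > 0 else 0.0, size=len(levels))
            draws -= draws.mean()
            eff = dict(zip(levels, draws))
        level_effects[factor_name] = eff
    fixed = np.zeros(n)
    for factor_name, eff in level_effects.items():
        fixed += design[factor_name].map(eff).to_numpy(dtype=float)

    pens = design["pen"].to_numpy()
    pen_levels, pen_codes = np.unique(pens, return_inverse=True)

    components: dict[str, pd.DataFrame] = {}
    records = design.copy()
    for trait in config.trait_names:
        parts = {"fixed": fixed.copy()}
        for name in ("additive", "microbiome", "interaction"):
            if name in roots:
                L, v = roots[name]
                parts[name] = L @ rng.normal(size=L.shape[1]) * np.sqrt(v)
            else:
                parts[name] = np.zeros(n)
        pen_eff = rng.normal(0.0, np.sqrt(fr["pen"] * total), size=len(pen_levels))
        parts["pen"] = pen_eff[pen_codes]
        parts["residual"] = rng.normal(0.0, np.sqrt(fr["residual"] * total), size=n)
        df = pd.DataFrame(parts, index=design.index)
        components[trait] = df
        records[trait] = df.sum(axis=1)

    return records, TrueComponents(components)


@dataclass
class SimulatedDataset:
    """Bundle of everything one simulation run produces."""

    config: SimulationConfig
    panel: GenotypePanel
    design: pd.DataFrame
    otu_tables: dict[str, OtuCountTable]
    records: pd.DataFrame
    truth: TrueComponents
    G: RelationshipKernel
    M: RelationshipKernel  # causal stage's microbial kernel

    @property
    def traits(self) -> list[str]:
        return self.config.trait_names

    @property
    def causal_stage(self) -> str:
        return self.M.meta.get("stage", self.config.stages[0])


def simulate_dataset(
    config: SimulationConfig, causal_stage: str | None = None
) -> SimulatedDataset:
    """Full simulation: population, OTU tables per stage, phenotypes.

    Phenotypes are generated from the genomic kernel and the microbial
    kernel of ``causal_stage`` (default: first stage), so model-comparison
    experiments know which stage carries the signal.
    """
    from .kernels import build_grm, build_microbial_kernel, log_standardize_otu
    from .preprocessing import relative_abundance

    panel, design = simulate_population(config)
    otu_tables = {
        stage: simulate_otu_table(config, stage) for stage in config.stages
    }
    G = build_grm(panel)
    stage = causal_stage or config.stages[0]
    S = relative_abundance(otu_tables[stage])
    M = build_microbial_kernel(log_standardize_otu(S))
    M.meta["stage"] = stage
    records, truth = simulate_phenotypes(G, M, design, config)
    return SimulatedDataset(
        config=config,
        panel=panel,
        design=design,
        otu_tables=otu_tables,
        records=records,
        truth=truth,
        G=G,
        M=M,
    )
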