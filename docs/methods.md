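# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the known limits of what the package's tests
can show.

## Model family and variance fractions

Phenotypes are modelled as

```
y = Wβ + Z·pen + a + o + ao + e
a ~ N(0, G σ²_a),  o ~ N(0, M σ²_o),  ao ~ N(0, (G∘M) σ²_ao),
pen_l ~ N(0, σ²_pen) iid,  e ~ N(0, σ²_e I)
```

with fixed effects W for dam line (2 levels), sex (2), and contemporary
group; pens are nested in contemporary groups and always random. The five
nested models M0–M4 attach none, {G}, {M}, {G, M}, or {G, M, G∘M} of the
kernel terms. All kernels are linear, so every model is equivalent to a
multi-kernel BLUP with unknown variances.

Per retained draw, a component's variance fraction is its variance divided
by the sum of all random-effect variances plus the residual, pen included.
The microbiability m² and the interaction fraction i² therefore share one
denominator with h²; this choice is recorded in each fit's metadata. The
kernels are constructed so their mean diagonal is ≈ 1, which makes plain
variance ratios and fraction-of-phenotypic-variance agree to O(1/n).

### Kernel construction

* `G` — VanRaden method 1: `Z = dosage − 2p`, `G = ZZ′ / (2Σ pⱼ(1−pⱼ))`.
  Allele frequencies may be supplied externally (training-fold statistics).
* `M` — OTU relative abundances get a pseudocount of 0.001 on every
  element, are log-transformed, centered and scaled per OTU, then
  `M = XX′/q`. Two centering conventions are implemented: `mean-of-logs`
  (default; true standardization, zero-mean columns and trace(M) = n−1
  in-sample) and `log-of-mean` (the literal construction formula). The
  notation in the field is ambiguous between the two; only mean-of-logs
  yields the standardization identities that the Gaussian-kernel
  interpretation assumes, so it is the default, with the alternative one
  flag away. The SD divisor defaults to n−1 and is configurable.
* `G∘M` — element-wise product, not rescaled afterwards: its variance
  parameter absorbs scale. PSD is asserted numerically (Schur theorem).
* Kernel alignment is by exact ordered animal-id match; any mismatch is a
  hard error rather than a silent reindex.

## Gibbs sampler

Fixed effects use a flat prior and a joint Gaussian conditional (one
Cholesky of W′W). Pen effects are conjugate-normal per pen. Each kernel
effect is sampled in the eigenbasis of its kernel: after one
eigendecomposition `K = U Λ U′` (eigenvalues ≤ 1e−10 truncated), the
effect is `u = U √Λ α` with independent conditional updates for α —
O(n·rank) per sweep. Variances follow scaled-inverse-χ² full conditionals.
Missing phenotypes (the masked test animals of cross-validation) are
imputed by data augmentation each sweep; they contribute nothing to the
observed-data likelihood but receive joint-fit predictions. Predictions
for animals in pens never observed in training use pen effect 0, the
conditional mean — by design, pens are training-set-specific.

Priors: every variance gets df = 5 and a scale set by partitioning half of
the phenotypic variance (prior R² = 0.5) equally among the active
non-residual terms, matching the prior mode to its share — the convention
of the standard Bayesian whole-genome regression software. Chain defaults
are 120,000 sweeps / 20,000 burn-in / thin 5; cross-validation sweeps use
a reduced profile (12,000 / 2,000 / 5), which recovery tests show agrees
with long chains within Monte-Carlo error. Effective sample sizes are
estimated by autocorrelation (arviz).

When *all* variance components are fixed (the BLUP-equivalence setting),
the location effects form a single Gaussian block whose full conditional
given the observed records is exact; the sampler then draws that block
jointly and its conditional mean is the exact posterior mean. This removes
the O(1e−2) Monte-Carlo error that componentwise sweeps would leave and
lets the fit be compared with Henderson's mixed-model equations at 1e−3.
The test-suite oracle solves the equations through the independent
V-inverse (GLS/BLUP projection) route.

### Identifiability and the prior floor

The scaled-inverse-χ² prior has zero density at σ² = 0. Whenever the
likelihood is nearly flat along a variance direction — which happens when
a kernel's eigenvalue bulk is close to white, so the term is exchangeable
with the residual — the posterior for that fraction sits near the prior
(≈ 0.10–0.17 under the default equal split), *not* near zero. This
matters most for the interaction kernel: since (G∘M)ᵢⱼ = Gᵢⱼ·Mᵢⱼ is a
product of two quantities each < 0.3 off-diagonal, G∘M is always
near-diagonal, and i² is only weakly likelihood-identified at n ≈ 560
(Fisher-information SD ≥ 0.16 per replicate). Fitted i², and to a lesser
degree m² and h², are therefore shrunk toward the prior's equal share on
data of this size. The recovery and null-calibration experiments report
exactly this behaviour; users should read small fitted fractions at
moderate n as prior-dominated rather than as evidence of real variance.

## Synthetic-data generator

The generator emulates a commercial swine trial: 28 purebred sires with
half-sib progeny in single-sire, single-sex pens of ~20 nested in 6
contemporary groups; ~40k-SNP-chip genotypes; ~1.7k-OTU rarefied 16S
tables at three growth stages (Wean, Mid-test, Off-test); and 15 traits.

* **Genotypes.** Markers come in haplotype blocks (default 10 markers) in
  strong LD: each block carries one segregating core allele (frequency
  uniform on the MAF range) plus small per-marker flip noise, and is
  transmitted as one unit. Each progeny receives one of its sire's two
  block haplotypes and one fresh population haplotype, giving the half-sib
  dosage correlation of ≈ 0.25. The block count (markers/block size ≈ 500 at
  5k markers) plays the role of the effective number of independently
  segregating segments of a dense livestock chip; with fully independent
  markers the GRM bulk spectrum is nearly white and variance fractions
  stop being likelihood-identified at these sample sizes, so LD is both
  more realistic and necessary for meaningful recovery experiments.
* **Microbiome.** Per animal, a latent Gaussian field over OTUs
  (OTU-level means with SD 1.5; 30% of latent variance on 5 shared
  community axes — enterotype-like gradients; the rest iid) is softmaxed
  to a composition and sampled as multinomial counts at the sequencing
  depth (default 10,000). The community axes give M genuine off-diagonal
  structure; a purely exchangeable latent factor would cancel under
  compositional closure and leave M ≈ I. An optional host covariate
  shifts the latent means along a fixed random direction, providing a
  controllable genome→microbiome dependence channel for stress tests.
* **Phenotypes.** `y = fixed + a + o + ao + pen + e` with each random
  vector drawn exactly from its kernel (eigen-root times iid normals) and
  variances scaled by the kernel's mean diagonal so realized fractions
  match the configured ones in expectation — no post-hoc rescaling, so
  draws stay Gaussian with the stated covariance. All components are
  stored; the phenotype equals their sum to machine precision. Fixed
  effect sizes default to 0.3 (dam line), 0.3 (sex) and 0.5 (contemporary
  group) phenotypic SDs, the magnitude typical of carcass traits.
* **RNG.** Every component draws from a named substream of the single
  root seed (`genotypes`, `otu:<stage>`, `phenotypes`, ...), so each
  output is individually reproducible.

What the generator does **not** emulate: linkage maps and recombination
within real chromosomes, multi-generation pedigrees, taxonomy or
phylogenetic structure among OTUs, longitudinal correlation of the
microbiome across stages, and the weight-stratified subsampling of 4–5
pigs per pen for sequencing (the simulator generates microbiomes for all
animals). Passing tests therefore demonstrate correctness of the
estimation machinery under a faithful covariance structure, not that any
particular real dataset has these variance fractions.

## Reference experiment design

The canonical experiments (hologen.experiments) use 28 sires × 20 progeny
= 560 animals with **two** single-sire pens of 10 per sire (56 pens).
The full-scale trial this emulates has ~40 progeny per sire in pens of 20
— i.e. two pens per sire; preserving that pens-per-sire ratio at the
reduced population keeps pen variance estimable, whereas one pen per sire
would confound pen with family entirely. Experiment sizes (5,000 markers,
500 OTUs, 5 replicate seeds, the reduced MCMC profile, 2,000-feature
scans, 200 replicates for family-wise-error calibration) were chosen so
the whole suite runs in minutes on one CPU while keeping Monte-Carlo error
well below the effect sizes being checked.

## Preprocessing rules

* Genotype QC removes markers with call rate strictly below 0.90 or MAF
  strictly below 0.05 (thresholds are "lower than", so boundary values
  are kept); remaining missing dosages are imputed to 2p, which leaves
  allele frequencies invariant (the GBLUP convention).
* Sparse OTUs are filtered on the **raw** count table (total count ≥
  1200, inclusive) before rarefaction to 10,000 counts per sample
  (multivariate hypergeometric, so zeros stay zero). Samples below the
  rarefaction depth cannot be equalized and are dropped with a warning —
  keeping them unrarefied would break the constant-depth invariant the
  downstream transforms assume.
* All filters are idempotent; QC statistics can be learned on a training
  fold and applied to held-out animals (scikit-learn fit/transform).

## Feature preselection and cross-validation

The single-covariate scan fits, per feature, least squares of the trait on
μ + dam line + contemporary group + sex + pen + sire + feature. Pen is
treated as a fixed factor here so the 40k-feature scan reduces to one
orthogonal projection (residualize the trait and all features once, then
regress) — algebraically identical to per-feature full fits, with a
possible slight conservativeness relative to treating pen as random. The
OTU covariate is the raw relative abundance; log-standardization applies
only to kernel construction. Bonferroni correction is per feature type
(markers and OTUs separately), matching their separate kernels. RR sets
are uniform draws without replacement, size-matched to IR.

Cross-validation holds out whole half-sib families: sires are split into
four folds of seven, by a greedy agglomerative rule on a sire-relatedness
matrix when one is supplied (most-related pair seeds a fold, highest mean
relatedness joins) or at random otherwise. Inside each fold, everything
that could leak — allele frequencies, OTU standardization statistics, IR
scans, RR draws — is recomputed from training animals only; kernels span
train+test animals but use training statistics. M0 depends on neither
stage nor features, so it is fitted once per fold × trait and its score
replicated across the grid. Scoring uses raw phenotypes (Pearson r and
MSE); cells whose IR selection is empty are recorded as not estimable and
the run continues. A zero-variance prediction vector yields r = NaN with
a warning while MSE is still reported.

## Post-analysis

The pooled grid is fitted with sum-to-zero coding (required for the
type-III hypotheses to be the marginal-means ones) and the exact term list
T + S + M + C + F + S:M + S:C + M:C + T:S + T:M + T:C; some further
estimable interactions (e.g. with fold) are deliberately not fitted, to
match that design. Terms rendered inestimable by empty cells are flagged,
never silently dropped; a constant response yields NaN F ratios
explicitly. Least-squares means average model predictions over all other
factors with equal weights; pairwise contrasts use the fit's coefficient
covariance with Tukey (studentized-range), Bonferroni, or no adjustment.

## Numerical details

* Kernels: symmetry enforced to 1e−10, PSD to min eigenvalue ≥ −1e−8,
  eigenvalues ≤ 1e−10 truncated in the sampler.
* Zero-variance OTU columns are dropped (and reported) before kernel
  construction; a fully monomorphic panel or an all-zero-variance OTU set
  is an error.
* Collinear scan features (zero residual sum of squares after projection)
  get missing p-values and are logged.
* Fold counts must divide the sire count exactly; the error names the
  remainder.
* Determinism: every stochastic operation takes an explicit seed; chain
  seeds for cross-validation cells are derived from the base seed and the
  cell labels via CRC32, keeping all seeds below 2³¹.
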