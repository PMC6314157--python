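# Methods

`pedimpute` is a simulation laboratory for one study-design question:
*given a collection of extended pedigrees, whom should you sequence, how
should you impute everyone else, and how should you measure whether the
imputation was good enough for association testing?*  Everything below is
implemented in the package and exercised by the test suite; no number in
this note comes from anywhere else.

## Simulation model

### Founder haplotype pool

Founder chromosomes are drawn from a synthetic pool of `H` haplotypes over
`S` biallelic sites in a region of ~5.6 Mb (default geometry: `H = 20,000`,
`S = 8954` EUR-like or `11,891` AFR-like, matching a dense sequencing panel
of a single chromosome-22 region).  The pool is produced by a neutral
coalescent simulation (msprime; effective population size 10,000, binary
mutation model, discrete genome) rather than by resampling real reference
haplotypes: the point of the pool is not haplotype identity but two summary
statistics —

* **MAF spectrum.** A target density over (0, 0.5] is configurable; the
  default is `f(p) ∝ 1/p` on `[min_maf, 0.5]` (neutral-like, rare-heavy).
  Simulated mutations are laid on the ancestry at increasing rates until
  every frequency bin of the target spectrum has enough candidate sites,
  then a bin-matched random subset of exactly `S` sites is kept.  This
  pins the realized spectrum while preserving the coalescent's LD.  All
  sites are polarized so allele 1 is the minor allele.
* **Linkage disequilibrium.** The single knob `ld_strength ∈ [0, 1]` maps
  monotonically to the historical crossover rate:
  `r_eff = base_recomb_per_bp · (1 − ld_strength)/ld_strength`
  (default base 1e-8/bp).  `ld_strength = 0` is the exact independent-sites
  limit, for which the mean within-window pairwise r² equals the
  finite-sample null `1/(H − 1)`.

The two ancestry presets were calibrated once against the target LD
summary — the mean pairwise r² inside non-overlapping 100-SNP windows —
giving `ld_strength = 0.370` (EUR-like, window LD ≈ 0.032) and `0.208`
(AFR-like, ≈ 0.02).  The AFR-like preset carries ~33% more sites in the
same region and a heavier rare tail (`min_maf` 0.0015 vs 0.003).

What the generator does **not** emulate: recombination hotspots,
demographic history (bottlenecks/expansions), gene conversion, genotyping
error, and the exact haplotype sharing of any real panel.  Tests passing on
this pool therefore validate the machinery and the qualitative rankings
(e.g. family imputation beating LD imputation for rare variants when close
relatives are sequenced), not tool-specific accuracies on real data.

### Pedigrees

Random pedigrees are built top-down: a founding couple, sibship sizes drawn
from a shifted Poisson (mean 2.5) truncated to the configured range, a
fraction of children marrying in new founders, and mid-pedigree sibships
widened until the size target is met.  Construction guarantees the
structural invariants (both parents present or neither; acyclic; unique
ids).  The full-scale reference design uses 20 pedigrees with sizes 10–174,
generations 3–9 and sibships 1–11.

### Gene dropping

Founders draw distinct pool haplotypes without replacement across *all*
pedigrees of a replicate.  Each meiosis starts from a random parental
strand and switches strand between adjacent sites independently with
probability `θ = min(0.5, 0.01 · d_cM)` under a uniform map of 1 cM per
1000 kb.  This linear-in-distance rule is exactly "1% per cM" at short
range; no mapping function (Haldane/Kosambi) and no interference are
applied, and the convention is part of the model definition.  A GWAS panel
of 500 sites (~5%) is masked at random per replicate; 100 replicates per
scenario is the reference design, with seeds fanned out deterministically
as base seed → replicate → stage so any replicate regenerates in isolation.

## Reference-subject selection

All four strategies spend identical per-pedigree quotas — round-half-up of
`fraction · size` with a largest-remainder global correction so the total
is exactly `round(fraction · N)` (20% of 1200 subjects = 240) — making
downstream comparisons like-for-like.

* **random** — uniform within pedigree.
* **max_unrelated** — greedy scan in order of increasing total relatedness
  accepting subjects pairwise-unrelated at the threshold (default twice-
  kinship 0), exact enumeration fallback on pedigrees ≤ 20 members, quota
  filled with least-related leftovers.  This emulates designs that force a
  maximally unrelated panel.
* **generation_units** — whole parent couples, oldest generation first,
  larger sibships first; a married-in founder spouse inherits the lineage
  member's generation.
* **founder_coverage** — maximizes the expected fraction of the `2f`
  founder allele copies observed in at least one selected subject,
  estimated by Monte-Carlo single-locus label drops (default 500).  Small
  pedigrees are solved exactly by enumeration (greedy marginal gains tie
  between a parent and a child of a nuclear family, and the tie matters);
  large ones greedily, with the (1 − 1/e) guarantee of monotone submodular
  maximization.  This is a deliberately transparent surrogate for
  inheritance-vector-based pickers; published claims about those tools do
  not transfer verbatim to it.

## Imputation

Dosages live on the minor-allele-count scale `[0, 2]`; the "fraction of
minor alleles" convention is count/2, and squared-correlation accuracy is
invariant to the rescaling.  When only a dosage `d` exists, genotype-class
posteriors use the Hardy-Weinberg moment match
`((1−d/2)², 2(d/2)(1−d/2), (d/2)²)` — needed because the agreement metric
requires class probabilities.

Three built-in baselines isolate information sources: allele-frequency
(Hardy-Weinberg prior only), population-LD (per-site OLS on the `k` nearest
panel dosages, fit on reference subjects, clipped to `[0, 2]`), and
family-kinship (per-site Gaussian conditioning of the dosage vector, mean
`2p`, covariance `2p(1−p)A`, on observed reference dosages; with `A = I`
this collapses exactly to the allele-frequency baseline).  The hybrid
combiner takes the family call where its maximum posterior reaches a
threshold `τ` (default 0.8), else the population call; `τ = 0` and `τ > 1`
reproduce the pure results.  The threshold rule is this package's own
combination criterion.  For real studies the intended path is
`export_for_external_tools` → external phasing/imputation →
`import_external_result` (VCF with GP or DS; allele orientation harmonized
against the truth, flipping `d → 2 − d` when REF/ALT are swapped).

## Accuracy metrics

Per SNP, over imputation-target subjects only:

* **dosage R²** — squared Pearson correlation of true vs imputed dosage;
  undefined (NaN, never 0) if either vector is constant.
* **IQS** — chance-corrected agreement from the probability-weighted 3×3
  table `n_jk = Σ_i P_i(j)·1[true_i = k]`:
  `IQS = (Po − Pc)/(1 − Pc)` with `Po = Σ n_jj / N`,
  `Pc = Σ row_j col_j / N²`; ≤ 1, possibly negative, undefined at
  `Pc = 1`.  A best-guess (classic Cohen's kappa) mode exists as a flag;
  the probability-weighted table is the default because imputers emit
  probabilities.  Note one consequence of chance correction: any *constant*
  prediction has `Po = Pc` and scores exactly 0.
* **concordance rate** — best-guess agreement, ties to the smaller
  genotype; reported for completeness but excluded from headline summaries
  (it is dominated by easy major-homozygote calls at low MAF).

Accuracy excludes the observed panel sites and, by default, a 500-site
buffer at each region end (edge sites lack flanking panel information;
8954 → 7954 and 11,891 → 10,891 testable sites).  Both exclusion flags are
carried in the per-SNP table so either convention can be re-derived.  Bin
means use the partition (0,0.01), [0.01,0.05), [0.05,0.1), [0.1,0.2),
[0.2,0.3), [0.3,0.4), [0.4,0.5]; undefined values are counted, never
averaged in.

## Traits and association

Traits follow `Y = ε` (null) or `Y = β_j X_j + ε` (alternative) with
`ε ~ N(0, σ_g²A + σ_e²I)`; defaults `σ_g² = σ_e² = 1` give total variance
2 and heritability 0.5.  (The equivalent unit-variance form
`Σ = h²Φ + (1−h²)I` is the same model up to scale; the package is
parameterized by the two components and reports `h²`.)  Under the
alternative, `β_j = sqrt(v_a / (2·MAF_j·(1−MAF_j)))` so the SNP contributes
additive variance `v_a` (default 0.01); `X_j` is the 0/1/2 minor-allele
count, and the true pool MAF is used for calibration by default (a switch
allows the reference-panel estimate).  Ten traits per model per SNP per
dataset is the reference design.

The association test fits the two-variance-component model by maximum
likelihood per test: `A` is eigendecomposed once per subject set, the
rotated likelihood is profiled over `δ = σ_e²/σ_g²` by bounded 1-D search
on `log δ ∈ [−10, 10]`, and the SNP coefficient gets a Wald test against
the normal reference.  The residual variance behind the standard error uses
residual degrees of freedom (`n − 2`), so with `A = I` the estimate,
standard error, and p-value reduce exactly to ordinary least squares —
the identity the test suite checks against a closed-form OLS oracle.
Dosages enter the design untouched (no hard calls, no quality filtering),
an intercept is always included, and constant genotype vectors return
`p = 1` with a warning.  Rates aggregate per SNP (proportion of trait
replicates with `p < α`, α ∈ {0.05, 0.01, 0.001}) and then average
unweighted within MAF bins; null-model rows are type-I error, alternative
rows are power.

## Numerical choices and degenerate inputs

* Relationship matrices come from the tabular recursion in generation
  order; founders are unrelated and non-inbred by assumption (they draw
  independent pool haplotypes, so the assumption matches the simulation).
  Covariance factorization uses Cholesky with an eigenvalue-clipped
  fallback (warned) for semidefinite edge cases.
* Gaussian conditioning solves the observed block directly (submatrices of
  the positive-definite `A` are positive definite); a ridge of 1e-8 is
  applied only if the solve fails, and logged.
* Monomorphic reference sites in the LD imputer fall back to the
  allele-frequency baseline (logged); monomorphic sites in window-LD are
  skipped (logged).
* Tie-breaks everywhere are lexicographic in subject id, for bit-for-bit
  reproducibility; pipeline outputs embed the config hash, and re-running a
  config reproduces outputs byte-identically.

## Scaled-down defaults

The reference design (100 replicates × 10 traits × all SNPs, 20,000
haplotypes) is hours of compute; the package's own test and acceptance runs
use deliberately smaller problem sizes chosen to keep every check
statistically meaningful at desk scale: fixture pedigree sets of ~300
subjects, pools of a few hundred haplotypes over 100–300 sites, 1000
association tests per calibration check (99% binomial CI half-width ±1.8
percentage points at α = 0.05), 10⁵ meioses for the recombination-rate
check, and 10 paired replicates for directional baseline comparisons.  The
full-scale pool presets are still exercised once per test run to verify the
calibrated LD targets.

## Known limitations

* The built-in imputers are single-site (LD regression) or
  single-site-given-relatives (Gaussian dosage conditioning); they do not
  model multi-site inheritance vectors or haplotype HMMs, and their
  absolute accuracies are below those of dedicated tools.  They exist to
  rank information sources and to exercise the evaluation machinery;
  external tools plug in through VCF.
* Autosomal, sex-agnostic transmission; uniform genetic map; no
  interference, mutation, or genotyping error during gene dropping.
* Quantitative traits only — no ascertainment, covariates, dominance, or
  epistasis.
* Pedigree bit complexity (`2n − f`) is computed, but automated splitting
  of large pedigrees into sub-pedigrees is out of scope.
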