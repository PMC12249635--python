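# Methods

This note documents the models, parameter choices and numerical
decisions behind `mprsnet`, and what the synthetic-data tests do and do
not establish about behaviour on real data.

## 1. Trait network and diffusion

The trait-specific network is the subgraph of a base protein–protein
interaction network induced by genes that carry a gene-level association
p-value; node weights are `w = −log10 max(p, 1e-300)` (the floor keeps
weights finite if a gene-based test underflows to zero). Diffusion
requires every degree ≥ 1, so analysis is restricted to the largest
connected component (ties broken toward the component containing the
lexicographically smallest gene id, for determinism).

Two operator conventions are implemented for the random walk with
restart on the column-stochastic walk matrix `W = A D⁻¹`:

* **hotnet2** (default): `S = β (I − (1−β) W)⁻¹ diag(w)`. Because `W` is
  column-stochastic, each column of `β (I − (1−β) W)⁻¹` sums to one, so
  column `j` of `S` sums exactly to `w_j` — the walk conserves weight.
  This is the insulated-diffusion operator of the HotNet family.
* **literal**: `S = (βI − (1−β) W)⁻¹ diag(w)`. This resolvent form is
  singular whenever `β/(1−β)` is an eigenvalue of `W`; since `W` always
  has eigenvalue 1, it is singular at `β = 0.5` on every connected graph
  and near-singular close by. It exists behind a flag with a
  condition-number guard (error above 1e12) for fidelity comparisons
  only.

Linear systems are solved directly (`numpy.linalg.solve`), not via an
explicit inverse; the result matches the inverse to 1e-10 on the test
networks. `β` defaults to 0.4 (HotNet-family convention); there is no
evidence-based reason in this package to prefer another value, and it is
configurable.

## 2. Hierarchical SCC clustering

For each distinct off-diagonal value `δ` of `S` (descending), the
directed graph with an edge wherever an entry is ≥ `δ` is condensed into
strongly connected components. Growing the edge set can only merge SCCs,
so the partitions are nested and the partition sequence changes at most
`n − 1` times; the implementation exploits this monotonicity to compute
the full hierarchy (and the largest-SCC profile of any permuted matrix)
with `O(breakpoints × log #thresholds)` SCC evaluations instead of one
per threshold. SCC membership is invariant under edge reversal, so the
orientation convention for `S_ij` does not affect the partitions.

### Cut selection and significance

The null model permutes node weights while keeping topology fixed.
Permutations respect degree bins (nodes sorted by degree, near-equal
bins) so that any score–degree relationship in real data is preserved
under the null; the bin count is capped so each bin holds at least ~150
nodes. Two failure modes motivate the cap, both observed during
development at desk scale: a singleton (or thin) bin barely mixes, and on
a few-hundred-node network a dense planted module *is* the top degree
bin, so degree-binned shuffling hands the hot weights straight back to
the module and the null collapses onto the observed data. At genome
scale (10⁴⁺ genes) the cap still yields ~70–100 genuinely degree-matched
bins; at desk scale it degrades gracefully to the uniform permutation,
which is the correct null when scores are degree-independent (as in the
synthetic generator).

For each threshold the observed largest-SCC size is standardized against
the permutation null as `(obs − mean) / max(sd, 1.5)`. The floor matters
twice over. Without any floor, thresholds whose null is exactly constant
(sd = 0, ubiquitous high in the hierarchy) dominate the argmax on any
positive deviation, however tiny. And the floor's magnitude steers a
bias trade-off: at one node of size variation the statistic still favors
high, tight cuts that capture only a module's strongest members, while
floors near two nodes tip the argmax into the giant-merge regime where
everything coalesces. The default of 1.5 was calibrated on synthetic
planted-module studies as the balance point between those two failure
modes (fresh-seed recovery ≈ 0.93 vs ≈ 0.79 at floor 1.0), and the
global-null family-wise error was re-verified afterwards (0.055 at
nominal 0.05 over 200 replicates). The selected cut `δ*` maximizes the
standardized deviation, ties going to the larger threshold (smaller,
tighter modules).

Each SCC at `δ*` with ≥ 3 genes receives a **max-statistic permutation
p-value**: its standardized size deviation at `δ*` is compared with the
distribution, over permutations, of the *maximal* standardized deviation
across all thresholds, `p = (1 + #exceedances)/(1 + n_perm)`. Comparing
against the permutation maximum charges the analysis for selecting `δ*`
where the data look most surprising; the naive alternative (size
exceedance at the observed `δ*` only) was measured at a family-wise
error of 0.45 under a global null at nominal 0.05, while the
max-statistic construction yields ≈ 0.035 with no loss of planted-module
recovery. Defaults: 800 permutations, minimum module size 3, modules
reported at p < 0.05, labelled `side.Mk` in decreasing size order.

## 3. Module-level polygenic risk score

`MPRS(M) = Σ β_k g_k` over the meta-GWAS SNPs lying within ±20 kb
(inclusive at both boundaries; positions 1-based) of any module gene.
Decisions:

* **Harmonization.** SNPs are matched by id; matching allele coding is
  used as-is, swapped coding flips the dosage (`g → 2 − g`),
  strand-ambiguous A/T and C/G SNPs are dropped by default, and any
  other pairing is dropped with a tallied reason. Scores are invariant
  to allele-swap re-encoding of the genotype file (tested to 1e-12).
* **Deduplication.** A SNP inside the windows of two genes of the same
  module contributes once; double-weighting by annotation overlap is
  biologically arbitrary. A flag restores literal per-gene counting.
* **Missing dosages** default to per-SNP mean imputation (standard PRS
  practice; preserves the population mean score); `zero` and
  `drop_individual` are available.
* No LD clumping and no p-value thresholding of the weight SNPs: all
  harmonized SNPs in windows enter the sum.
* Scores are reported raw and z-standardized across the analysis sample;
  survival models use the standardized score so hazard ratios are per
  SD (raw MPRS units are arbitrary).

Gene-level p-values for network construction are an input; when only
SNP-level statistics are available, a Bonferroni-adjusted minimum-p
aggregation (`gene p = min(1, k · min p)`) is provided as a deliberately
simple stand-in for a dedicated gene-based test — it is conservative
under LD and should be replaced by proper gene-based results when they
exist.

## 4. Disease-relevant module selection

Per module and meta-GWAS weighting, an independent two-sample t-test
(Welch by default — group variances are not assumed equal; Student's
available) compares case and control scores, and Cohen's d with the
normal-approximation CI (`SE² = (n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))`)
quantifies the effect. The Bonferroni denominator is the number of
candidate modules pooled across trait sides — not modules × weight
sources — and a module qualifies when it clears the corrected threshold
under at least one source (union rule; intersection behind a flag).

## 5. Clinical validation

* **Staging:** pairwise Welch t-tests of the score across the five
  diagnostic groups, raw p-values (presentation-level, no adjustment).
* **Conversion:** the cohort is baseline EMCI/LMCI with a recorded
  (possibly censored) monthly conversion time. Median split assigns
  individuals exactly at the median to the low-risk group
  (deterministic). Kaplan–Meier curves and the two-group log-rank test
  come from lifelines; so does the Cox model, with Efron tie handling
  (monthly times guarantee ties) and a tightened stopping rule
  (precision 1e-11) so coefficients are resolved past reporting
  precision. Constant covariates, zero events, and suspected separation
  (|coef| > 20) raise errors.
* **Mediation:** mediator model `m = α₀ + α₁x + α₂ᵀz + ε` (OLS) and
  outcome model `logit P(y=1) = γ₀ + γ₁x + γ₂m + γ₃ᵀz`; `y` codes
  CN/SMC = 0 vs MCI/AD = 1. Effects are computed on the probability
  scale by counterfactual simulation at treatment levels mean ± 1 SD of
  `x`, averaging over both treatment arms, the empirical covariate
  distribution, and Monte-Carlo mediator draws (common random numbers
  across arms). With the two-arm average, ACME + ADE equals the total
  effect identically, not just asymptotically. Percentile CIs and
  sign-crossing p-values come from a nonparametric bootstrap (resample
  individuals, refit both models; non-convergent draws are re-sampled up
  to a 10 % budget). Defaults: 5000 bootstrap draws, 100 mediator draws.

## 6. Co-expression and enrichment

Module modularity is the mean pairwise Pearson correlation over module
genes in one tissue (zero-variance genes skipped pairwise), tested
against size-matched random gene sets drawn from the background network
(default 1000, add-one permutation p). Tissue specificity is a paired
t-test of per-module correlations between the target tissue and each
other tissue over the same module list. Enrichment is the one-sided
hypergeometric upper tail against user-supplied GMT sets, intersected
with a user-specified background (default: all network genes), with
Benjamini–Hochberg correction across the collection.

## 7. Synthetic data: what it emulates and what it does not

The generator plants known structure at every stage so each analysis has
a parameter-recovery test:

* **Network** (default 150 genes, background edge probability 0.03, one
  planted 10-gene module with internal probability 0.8, plus a random
  spanning path for connectivity). The scale was chosen so that the
  diffusion far-field — which decays like `(1−β)^distance` — sits well
  below within-module similarity; on much denser desk-scale graphs the
  heavy upper tail of the planted score distribution (Beta(0.01, 1)
  p-values, i.e. exponential `−log10 p` with mean ≈ 43) lets scattered
  hot genes form spurious mutual-reachability clusters and no cut of the
  hierarchy isolates the module.
* **Gene scores**: background p ~ Uniform(0, 1], planted p ~ Beta(α, 1)
  with α = 0.01 (α = 1 is the null).
* **Genotypes**: independent SNPs, 3 per gene (one exactly at the lower
  window boundary), dosages Binomial(2, MAF), MAF ~ U(0.1, 0.4). The
  case-group MAFs of planted-module SNPs are shifted along `sign(β)` by
  a common factor solved (with a few fixed-point iterations, because the
  shift perturbs the binomial variances) so the module score separates
  cases from controls by a target Cohen's d (default 0.5; measured
  calibration bias < 0.01 at n = 2000/group). The second meta-GWAS is a
  noisy replicate of the first. No LD, no population structure.
* **Phenotypes**: with `x` the standardized true module score,
  `m = a·x + ε`, `y ~ Bernoulli(σ(c₀ + c·x + b·m + γᵀz))`; defaults
  a = 0.5, b = 0.5, c = 0.82 put the true mediated proportion at ≈ 0.22
  (computed by a 10⁶-draw Monte-Carlo oracle from the same generative
  equations and stored with each dataset). Diagnosis: y = 0 →
  CN/SMC (80/20); y = 1 → EMCI/LMCI/AD by ascending terciles of the
  latent score. Amygdala grey-matter densities are affine images of the
  latent mediator (mediation effects are invariant to affine maps of
  `m`). Conversion times for EMCI/LMCI are exponential with log-hazard
  θ·x (default θ = log 1.3), administratively censored at the empirical
  quantile matching the configured censoring rate (default 0.4), rounded
  up to whole months (which also exercises Efron tie handling).
* **Expression**: module genes load √ρ on a shared factor in the target
  tissue only (default ρ = 0.6, 80 samples/tissue); everything else is
  independent standard normal.

Passing recovery tests on these data shows the estimators are correct
under the stated models. It does *not* establish robustness to LD
between weight SNPs, score–degree confounding in real interaction
networks, non-exponential conversion hazards, informative censoring,
unmeasured mediator–outcome confounding (sequential ignorability is
assumed, and no sensitivity analysis is implemented), or expression
correlation structure beyond a single shared factor.

## 8. Reproducibility

Every stochastic routine takes an explicit seed; the pipeline derives
per-stage seeds from one global seed by hashing the stage name
(blake2s, reduced below 2³¹), so stages are independently reproducible
and a full rerun with the same config is identical. The synthetic
generator is byte-identical under a fixed seed and config.

Default problem sizes in the test and acceptance suites (150-gene
networks, 99 propagation permutations, 100-replicate recovery studies,
a few hundred bootstrap draws) were chosen as the smallest studies at
which the targeted effects are resolved cleanly; all scale up through
configuration.
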