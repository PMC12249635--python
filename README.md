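# mprsnet

Module-level polygenic risk scores (MPRS) on node-weighted molecular
interaction networks — a network-based GWAS (NetWAS) toolkit for finding
gene modules that link an imaging quantitative trait (iQT) to a disease
outcome, with the brain measurement as the mediating variable.

## Who this is for

Imaging-genetics studies routinely produce gene-level association scores
for a brain phenotype (say, amygdala grey-matter density) and have access
to large disease meta-GWAS (say, Alzheimer's disease). Single hits
explain little and are hard to interpret. `mprsnet` is for analysts who
want to move one level up: find *modules* of interacting genes that are
jointly hot for the imaging trait, score individuals on each module
against disease effect sizes, keep the modules whose scores separate
patients from controls, and then ask the causal question — how much of a
module's disease signal is transmitted through the brain measurement?

## The method

1. **Trait network.** A base protein–protein interaction network is
   restricted to scored genes; each node carries `w(v) = −log10 p` from
   the gene-level trait GWAS.
2. **Propagation.** A random walk with restart gives the asymmetric
   similarity matrix

   `S = β (I − (1−β) A D⁻¹)⁻¹ · diag(w(v₁), …, w(vₙ))`,

   with adjacency `A`, degree matrix `D` and restart probability `β`
   (default 0.4). Column `j` of `S` describes where node `j`'s weight
   diffuses; columns sum to `w(vⱼ)` exactly.
3. **Hierarchical SCC modules.** Thresholding the off-diagonal entries of
   `S` at every distinct value yields directed graphs whose strongly
   connected components form a nested dendrogram. The cut `δ*` maximizes
   the standardized deviation of the largest-SCC size from a permutation
   null (node weights shuffled within degree bins, topology fixed); each
   module at `δ*` gets a max-statistic permutation p-value.
4. **Module scores.** For module `M`,
   `MPRS(M) = Σ_j Σ_k β_{j,k} · SNP_{j,k}` over all meta-GWAS SNPs within
   ±20 kb of any module gene (dosages harmonized to the effect allele,
   strand-ambiguous SNPs dropped, shared SNPs counted once).
5. **Disease-relevant modules (ADMs).** Per-module Welch t-tests of MPRS
   between case and control groups, Bonferroni-corrected over all
   candidate modules from both trait sides (e.g. `0.05/(196+195) =
   1.28e-4` for a study with 196 and 195 candidates per side), with Cohen's d ± 95%
   CI; a module qualifies under either of two meta-GWAS weightings.
6. **Validation.** Co-expression modularity vs 1000 random same-size
   modules, tissue specificity (paired t-test), diagnostic staging,
   Kaplan–Meier / log-rank / Cox conversion analysis (HR per SD of MPRS),
   and x–m–y causal mediation (ACME/ADE, nonparametric bootstrap).

Everything runs end-to-end on synthetic data with planted ground truth —
no downloads required.

## Worked example

```bash
mprsnet demo --out demo/ --seed 1
```

simulates a 150-gene network with one planted 10-gene module (two trait
sides, 400 individuals, target case/control Cohen's d 0.5, ~22 % of the
module effect mediated through the imaging trait, conversion hazard ratio
1.3 per SD) and runs the full pipeline. Key numbers from that exact run:

```
adm.tsv         L.M1  15 genes  perm_p 0.01   cohens_d 1.53 [1.21, 1.85]
                R.M1   8 genes  perm_p 0.02   cohens_d 1.47 [1.15, 1.78]
modularity.tsv  L.M1  observed PCC 0.231  null 0.001 ± 0.012  perm_p 0.001
                R.M1  observed PCC 0.576  null 0.001 ± 0.022  perm_p 0.001
mediation.tsv   L.M1  ACME 0.103  ADE 0.210  prop_mediated 0.33
survival.tsv    L.M1  HR per SD 1.23 [0.91, 1.66]  (n_mci = 141)
```

The left-side module captures all 10 planted genes (plus 5 background
neighbours); the right-side module captures 8/10 cleanly. Both clear the
permutation test, show amygdala co-expression far above the
random-module null, and carry a significant case/control score
difference. (The diagnosis-based Cohen's d exceeds the generator's 0.5
target because diagnoses are assigned from the severity tercile of the
latent disease score, which sharpens the contrast; the 0.5 calibration
is tested against the generator's own case/control labels.) At the
demo's 141-person conversion cohort the Cox CI is wide and covers the
generative HR of 1.3; the acceptance suite checks HR recovery at
n ≈ 1000 where the estimate is sharp.

Per-stage commands (`simulate`, `score-genes`, `build-network`,
`propagate`, `mprs`, `select-adm`, `annotate`, `validate`, `run-all`) are
thin wrappers over the importable API; `examples/` holds one short
narrative script per capability.

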