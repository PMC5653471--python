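# Methods

This note documents the models, the synthetic study population, the
numerical choices, and the known limitations of `crossblup`.

## Models

All three models are four-population animal models over the purebred
lines S, LR, LW and the three-way crossbreds (CB). Each population has
its own fixed effects (a farm×sex interaction within purebred
populations — the analogue of a farm_breed_sex factor — and
trial + farm×sex for crossbreds, plus a centered covariate), a random
common-litter effect with population-specific variance, and a residual
with population-specific variance. Litter and residual covariances
between populations are zero.

**BOA model.** Crossbred genetic merit is split by breed-of-origin:
three independent structures, one per breed b, with

Var[a_b; g_CB^(b)] = K_b ⊗ G^(b),    K_b = [[σ²_a(b), σ_ag(b)], [σ_ag(b), σ²_g(b)]]

where a_b are purebred effects for purebred performance, g_CB^(b) the
crossbred effects carried by breed-b gametes, and G^(b) the partial
relationship matrix below. Purebred animals also hold a CB-performance
effect in each structure; its prediction is the EBV of a purebred for
crossbred performance. Covariances between breeds are not modelled
(structurally zero).

**G models.** A single structure with a 4×4 genetic covariance over
(S, LR, LW, CB) effects ⊗ one genomic matrix (G_A or G_B). The
purebred–purebred covariances are set to zero by default; an option
allows supplying them (estimated from additional purebred-pair bivariate
fits) — with distantly related breeds this barely moves predictions.

## Relationship matrices

All genomic matrices use the VanRaden method-2 locus scaling
D_jj = 1/(2 p_j (1 − p_j)) and divide by the total locus count N. This
single convention is what makes the observable expectations hold: mean
diagonal ≈ 1 for G_A/G_B, and crossbred partial diagonals ≈ the genome
fraction contributed by the breed (0.5 / 0.25 / 0.25).

- **G_A**: across-population observed frequencies.
- **G_B**: purebred rows centered by twice their own breed's frequency;
  crossbred rows by twice the weighted frequency
  p_B = 0.5 p^S + 0.25 p^LR + 0.25 p^LW, which is also the single
  scaling frequency. Between-breed blocks then average zero by
  construction.
- **Partial G^(b)**: purebred rows are diploid dosages centered by 2p^b;
  crossbred rows are single-gamete dosages (0/1) centered by p^b, where
  p^b is counted across the breed's purebreds *and* the crossbred
  alleles assigned to that origin. Crossbred alleles that are unassigned
  or of the other maternal origin are missing and contribute exactly
  zero while N stays at the full locus count — this, and only this,
  makes the crossbred diagonal estimate the genome fraction.
- Loci monomorphic among a matrix's informative alleles are dropped from
  that matrix's N; remaining frequencies are clipped to [0.01, 0.99]
  before forming D.
- **A**: numerator relationship matrix by the tabular method.

A practical caveat verified in simulation: when the crossbreds descend
from few sires/grandsires, the frequency sample is dominated by those
families and the crossbred partial diagonals fall a few percent below
the genome fractions (maternal ≈ 0.20–0.23 instead of 0.25). This
mirrors what is seen with real data. Checks of the 0.5/0.25 expectation
therefore use a diffuse-family design (many parents, small litters).

## Breed-of-origin assignment

Purebred haplotypes are catalogued in overlapping windows (default 50
loci, stride 10; the trailing window is snapped to the chromosome end).
Each crossbred gamete is matched per window by exact string lookup:
the paternal gamete votes S where its window haplotype occurs in the S
library; the maternal gamete votes LR (LW) where its haplotype occurs in
only that maternal library. Overlapping-window votes are reconciled per
allele; the default is strict (any conflict → unassigned), favouring
precision over rate. Phasing is an input contract: simulated data are
truth-phased, real data must arrive phased. On simulated crosses at
F_ST ≈ 0.15 this assigns ≳ 93% of alleles with ≳ 99.8% agreement with
the recorded truth; the unassigned share shrinks as divergence grows,
while mislabelling stays near zero at every divergence.

## REML

Variance components come from bivariate fits (purebred records of one
breed = trait 1, all crossbred records = trait 2) on the dense
record-level covariance V(θ) = K ⊗ G |records + litter + residual, with
θ = (K_11, K_12, K_22, σ²_u,PB, σ²_u,CB, σ²_e,PB, σ²_e,CB). The
optimizer is average-information REML: Newton steps with the AI matrix,
step-halving line search against the exact restricted log-likelihood,
feasibility projection (variances floored, |K_12| < √(K_11 K_22)), and
an exact EM fallback step (for the genetic block,
K ← K + K(S − T)K / q on the P-scale) whenever the AI step fails to
improve — so accepted iterations never decrease the likelihood.
Convergence: relative parameter change < 1e−8 or log-likelihood change
< 1e−6 relative to its magnitude (boundary estimates otherwise crawl
indefinitely at O(1e−5) per iteration). Standard errors come from the
inverse AI matrix; SEs of h² and r_pc by the delta method.

The three bivariate fits are combined into the 4-population set by
averaging the three crossbred genetic/litter/residual estimates (G
models) or keeping them breed-specific (BOA); purebred–purebred
covariances are zero unless supplied. Combined matrices are bent to
positive definite by flooring eigenvalues at 1e−4 of the largest; the
mean absolute percent element change is reported.

At the package's desk scale the r_pc estimates are weakly identified
(SEs of ±0.4 and occasional boundary estimates at |r| = 1); this is a
data-size effect, not an optimizer failure, and is why directional model
comparisons are replicated over seeds rather than read off one run.

## Prediction

Henderson's MME with R⁻¹-weighted incidence blocks; genetic priors
K⁻¹ ⊗ G*⁻¹ with G* = 0.99 G + 0.01 I (the partial matrices are singular
by construction — zero rows for crossbreds with no assigned alleles —
and blending plus this ridge guarantees invertibility). All genotyped
animals get equations whether phenotyped or not; one record per animal
is enforced. Dense Cholesky with a relative-residual check at 1e−8;
reliabilities r² = 1 − PEV/(K_tt G*_ii) from the inverse diagonal when
requested. Solutions match an independent dense GLS oracle to < 1e−6.

## Cross-validation and deregression

Purebreds of the validated breed are split into k = 4 folds by K-means
on d_ij = max(G_A) − G_A,ij, embedded by classical MDS to 10 dimensions,
10 seeded restarts. Each genotyped crossbred joins the fold whose
purebreds it is most related to on average (ties → lowest fold); if one
fold collects > 50% of the crossbreds it is split uniformly at random
across folds. Training excludes the fold's purebreds (of that breed) and
crossbreds. Validation purebreds get EBVs from a pedigree-based (A
matrix) animal model fitted to the fold's crossbred records plus the
phenotyped-but-ungenotyped extra crossbreds, which enter only this step.
Deregression uses the two-information-source decomposition:
r²_PA = (r²_sire + r²_dam)/4, w = λ[r²/(1−r²) − r²_PA/(1−r²_PA)] with
λ = (1−h²)/h², DRP = PA + (EBV − PA)/r²* with r²* = (r²−r²_PA)/(1−r²_PA);
animals with no own-equivalent information get w = 0 and are dropped.
Folds whose usable animals average DRP reliability < 0.05 are excluded
with a logged reason (the analogue of dropping a breed-trait whose
validation reliabilities are too low). Accuracy is the w-weighted
Pearson correlation between DRP and model EBV; SE = (1 − r²)/√N with N
the fold's usable validation count, reported per fold.

## Synthetic study population

The generator is first-class code and defines the study conditions:

- **Divergence** by pure drift from a common ancestral pool (ancestral
  frequencies ~ U(0.1, 0.9), linkage equilibrium), no mutation or
  selection. The number of drift generations is derived from the target
  Weir–Cockerham F_ST via E[F_ST] ≈ 1 − (1 − 1/(2Ne))^T; defaults
  (Ne = 60, target 0.15) realize pairwise F_ST ≈ 0.15, the
  distantly-related-breeds regime.
- **Genetic map**: uniform marker spacing, Poisson crossover counts per
  Morgan, no interference; default 3 chromosomes × 1 Morgan.
- **Cross**: F1 dams from LR×LW matings in both directions, with
  maternal-line grandparents drawn from small reused pools (as in
  practice, where boars sire many litters — and necessary for validation
  animals to have informative crossbred grand-offspring groups); CB
  litters from S sires × F1 dams. Breed-of-origin of every crossbred
  allele is recorded through gamete transmission.
- **Traits**: per breed, per-QTL (purebred effect, crossbred effect)
  pairs from a standard bivariate normal with correlation r_pc(breed) —
  defaults 0.5 (S), 0.3 (LR), 0.6 (LW), putting one maternal line in the
  low-r_pc regime. A purebred's genetic value sums its dosages times its
  breed's purebred effects; a crossbred's sums, per allele, the
  crossbred effect of the allele's true origin. Litter and residual
  variances are scaled to the targets h²_PB = 0.30, h²_CB = 0.35,
  litter fraction 0.10. Fixed-effect levels are i.i.d. normal with SD
  0.5 phenotypic SD; the covariate slope is 0.3 phenotypic SD per unit.
  The generator returns the realized generating components (including
  the realized per-breed 2×2 genetic blocks) for recovery tests; note
  the *realized* genome-level r_pc varies around the QTL-effect target
  because of LD among QTL in drifted populations.
- A block of crossbreds is phenotyped but not genotyped; they feed only
  the pedigree-based validation step.

What the generator does **not** emulate: real LD decay and chip marker
maps, mutation, selection, genotyping or phasing error, imputation
error, and the real data's scale (thousands of animals, 52k SNPs).
Passing tests therefore demonstrate internal correctness and the
method's statistical behaviour under known truth — not real-data
accuracy levels.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen as the
smallest sizes at which each check is statistically meaningful:
relationship-matrix expectations on ≈ 250 crossbreds × 1200 loci; REML
recovery on 550 + 450 records over a 1000-animal genomic matrix
(20 replicates); the directional BOA-vs-G_A comparison on ten replicates
of a 360-purebred / 800-crossbred population with variance components
fixed at their generating values (REML-in-the-loop is available via
`run_crossvalidation(..., varcomps="reml")` and used in the analysis
scripts).

## Known limitations

- Exact-match window voting only; no mismatch-tolerant or probabilistic
  (HMM) origin inference, no phasing or imputation.
- No single-step (pedigree+genomic) evaluation, no metafounders, no
  marker-effect back-solving, no dominance/epistasis.
- The 4-trait covariance is assembled from bivariate fits, never fitted
  jointly.
- Deregression approximates the full removal of within-validation-set
  relative information by the parent-average decomposition.
- One trait is simulated per run by default; multiple traits are
  supported but analysed independently (no genetic correlations between
  traits).
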