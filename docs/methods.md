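# Methods

This note documents the statistical models, estimators, numerical
choices and known limitations of msatpop. Formulas are stated in the
field's standard notation; all were implemented here from the
underlying definitions except where a mature library is noted.

## Data model

A dataset is a rectangular individuals × loci array of diploid
genotypes, each an unordered pair of integer allele sizes (base pairs),
with population and species labels per individual. A genotype is either
fully typed or fully missing; half-missing calls are rejected at parse
time because every estimator here counts gene copies in pairs
(typed_n-based corrections assume 2n copies from n individuals).
GENEPOP files (2- or 3-digit codes, `pop`-delimited blocks, `00…0`
missing) and a long CSV are read and written; since GENEPOP carries no
population names, the writer emits individual names as
`<pop>_<individual>` and the reader recovers the code from the final
individual of each block (a sidecar `pop_names` list overrides this).

## Diversity statistics

- **A**: mean over typed loci of the number of distinct alleles.
- **A_R**: rarefaction to 2g gene copies by the hypergeometric form
  A_R = Σᵢ [1 − C(N−nᵢ, 2g)/C(N, 2g)], evaluated with exact binomials.
  Default g = 10 diploids; a population is reported NA whenever any
  locus is typed below g, which reproduces the convention of standard
  allelic-richness software (NA exactly for samples under the
  standardized size). A_R = A when N = g by construction.
- **A_E** = 1/Σp² per locus, averaged over typed loci.
- **H_O**: fraction of typed individuals heterozygous. **H_E**: both
  the plain gene diversity 1 − Σp² and Nei's unbiased
  (2n/(2n−1))(1 − Σp²) are computed; tabulated output defaults to the
  unbiased form because the commonly used spreadsheet tools report it,
  and the plain form is retained since the two are not distinguishable
  in published tables. SE columns are standard errors across loci.
- **F_IS**: default is the Weir–Cockerham variance-components f
  (components summed over alleles and loci; for a single population
  b = n/(n−1)[p(1−p) − (2n−1)/(4n)h], c = h/2, f = 1 − Σc/Σ(b+c)).
  A Nei-style estimator 1 − mean(H_O)/mean(unbiased H_E) (ratio of
  multilocus means) is exposed as `"nei"`, because published
  per-population F_IS columns may come from either family of tools;
  both are labeled in output.
- **t** = (1 − F_IS)/(1 + F_IS), the outcrossing rate at inbreeding
  equilibrium; it exceeds 1 when F_IS < 0 and is undefined at
  F_IS ≤ −1. The identity t(1+F_IS) = 1−F_IS holds to machine
  precision for every emitted record.

Species-level summaries pool conspecific populations: A and A_E on the
pooled sample; H_S = mean over populations of per-population gene
diversity and H_T = gene diversity of the unweighted mean allele
frequencies. The Nei decomposition deliberately uses the *uncorrected*
gene diversities on both levels: with small-sample corrections applied
asymmetrically (per-population n vs species n), identical populations
would give a spurious negative (H_T − H_S)/H_T, whereas the
uncorrected form guarantees F_ST(nei) = 0 for identical populations
and H_T ≥ H_S always (Jensen's inequality per allele). The multilocus
Weir–Cockerham θ and f are reported alongside.

## Exact Hardy–Weinberg tests

Tests are conditional on the observed allele counts; under Levene's
model a genotype table T with heterozygote total h has probability
P(T) = n! Πⱼ mⱼ! 2^h / ((2n)! Π c_ij!).

- **Enumeration**: the table space conditional on the margins is
  enumerated recursively; complete enumeration is used while the space
  is within 10⁵ tables (exact p, zero Monte Carlo error).
- **Markov chain**: otherwise a chain over tables is run. A move picks
  two distinct individuals and one of the three re-pairings of their
  four labeled gene copies uniformly and always accepts. Uniform random
  pairing of 2n labeled copies is precisely Levene's model, and listing
  the two cross re-pairings separately supplies the 2^h weight, so the
  chain's stationary table law is Levene's without any Metropolis
  correction (this was verified against complete enumeration across 2-
  and 3-allele tables; an earlier variant with an explicit 2^Δh factor
  double-counts the heterozygote weight). Defaults follow the common
  practice for these tests: 10,000 dememorization steps, 1,000 batches
  of 10,000 iterations; p is the mean batch indicator and se_p the
  standard error of batch means. The running log-statistic is
  re-anchored from the counts at every batch boundary to cancel
  floating-point drift.
- **Orderings**: the two-sided "probability test" orders tables by
  conditional probability (ties included via a 1e−9 log tolerance).
  The deficiency test orders by total heterozygote count (fewer
  heterozygotes = more extreme) — a standard one-sided exact ordering;
  the multilocus global deficiency test couples independent per-locus
  chains and compares the summed heterozygote counts with the observed
  sum, reducing exactly to the single-locus test when only one locus is
  polymorphic. Exact tests are discrete and therefore conservative:
  their type-I error is at most, not equal to, the nominal level.
- **Holm correction** delegates to statsmodels' step-down
  implementation behind a thin wrapper.

## Null alleles

The one-null-allele model: visible alleles with frequencies pᵢ plus a
null at frequency r under random mating; visible/null heterozygotes
score as visible homozygotes and null/null as blanks. The EM estimator
(E-step: allocate apparent homozygotes between true homozygotes and
null heterozygotes with weight 2pr/(p²+2pr), blanks to null/null;
M-step: re-estimate gene-copy frequencies) maximizes the multinomial
likelihood; the likelihood is non-decreasing across iterations and
convergence is declared on parameter *or* likelihood change below
tolerance — the latter matters at the r = 0 boundary, where iterates
decay geometrically and a pure parameter-change criterion stalls. All
blanks are attributed to nulls by default (no technical-failure
mixture); callers simulating technical dropout should expect r̂ to
absorb it.

**ENA-corrected θ** carries the null as an explicit extra allele state:
per population and locus the EM visible frequencies (summing to 1−r̂)
replace the raw apparent frequencies — removing the artifactual
among-population variance that population-specific null frequencies
add — each visible allele's heterozygote-carrier frequency adds the
EM-expected visible/null heterozygotes hidden among apparent
homozygotes, and the null's own per-allele components are excluded
from the sums. Denominators are all sampled individuals (blanks
included), matching the EM, so with r̂ ≡ 0 and no blanks the corrected
θ equals the uncorrected one exactly. In simulations with a null
lineage segregating at drift-divergent frequencies this removes nearly
all of the upward bias of the uncorrected θ; under spatially uniform
null pressure both estimators are nearly unbiased and the correction is
a no-op in expectation.

**Diagnostics.** The F_IS-vs-r̂ regression (OLS, Pearson r, two-sided
p via scipy) uses the per-locus Nei-style F_IS = 1 − H_O/H_E, which is
stabler than locus-level variance-components f at small n. The
heterogeneity screen encodes the qualitative rule that a mating system
shifts every locus while nulls act locus by locus: with at least three
null-free loci (r̂ < 0.05) forming at least half the usable loci, a
positive mean F_IS (> 0.05) there is "inbreeding-like" and a near-zero
mean with elevated F_IS confined to null-affected loci is
"null-artifact-like". When most loci carry elevated r̂ the contrast is
not trusted — genuine inbreeding inflates r̂ at every locus because
homozygote excess mimics nulls, so conditioning on low r̂ would
cherry-pick low-F_IS loci — and uniformly positive F_IS across all
loci (median > 0.05, ≥70% positive) decides instead. The 0.05
thresholds are configurable; they concretize a qualitative rule and
were fixed before use.

## Differentiation, R_ST, distances, trees

- **θ** (Weir–Cockerham 1984): per-allele components a, b, c with the
  standard n̄, n_c, p̄, s², h̄ algebra, summed over alleles and loci
  ("ratio of sums"); pairwise significance by permuting multilocus
  genotypes between the two populations with the add-one rule,
  Bonferroni-adjustable across pairs within a species.
- **R_ST**: one-way ANOVA on allele size over gene copies per locus;
  σ²_among = (MS_among − MS_within)/n₀ with the unequal-n n₀, summed
  across loci. Invariant to adding a constant to all sizes at a locus.
- **Allele-size permutation test**: size labels are permuted among the
  distinct allelic states at each locus (genotype identity structure
  kept), pR_ST recomputed per permutation,
  p = (1 + #{pR_ST ≥ R_ST})/(1 + n_perm). A significant p means the
  sizes themselves (stepwise-mutation memory) carry differentiation
  beyond the allelic identities.
- **Nei distances**: D_A = 1 − (1/L)ΣₗΣₐ√(xₐyₐ) (default — bounded,
  robust to non-shared alleles, and the usual choice for
  microsatellite NJ trees) and standard D = −ln(J_xy/√(J_x J_y)) behind
  a flag. Loci untyped in either population are dropped.
- **Neighbor joining**: Saitou–Nei agglomeration on the Q criterion;
  deterministic tie-breaking by the lexicographically smallest pair of
  cluster representative names; negative branch lengths clamped to zero
  with the deficit moved to the sister edge (sum preserved; raw values
  kept on the edges). Exact on additive matrices (verified against
  4–8-taxon random additive trees and cross-checked against
  scikit-bio's NJ).
- **Bootstrap**: loci resampled with replacement B times; supports are
  the percentage of replicate NJ trees containing each internal
  bipartition of the full-data tree. Newick output carries supports as
  internal node labels.

## Synthetic data

The generator is a forward Wright–Fisher simulation whose defaults
mirror the target study design: 13 loci, 6–32 sampled diploids per
population, allele sizes in 80–400 bp stepping by one 2-bp repeat.
Each offspring selfs with probability s (equilibrium F_IS = s/(2−s))
or draws two parents; with probability m the parental deme is a
migrant source (island model, or ring neighbors under stepping-stone —
generation only, no migration estimation); gametes mutate ±1 repeat
with probability mu, reflecting at the size bounds. All demes descend
from a single ancestral pool (5 founder alleles, Dirichlet
frequencies), so differentiation is accrued drift; founder bottlenecks
resample a deme through a small founder set at scheduled generations.
Identical seeds reproduce dataset and truth byte-for-byte.

Null alleles are overlaid in two modes: `"lineage"` (default in
configs) hides the existing allele whose overall frequency is closest
to the target r — the hidden lineage has drifted to different
frequencies per deme, matching both the EM model and how real nulls
distort differentiation — while `"mass"` hides each gene copy
independently with probability r, hitting the target frequency exactly
and identically everywhere (used for exact parameter-recovery checks).
The i.i.d. mass mode matches the EM model only under random mating;
under selfing it breaks the genotype correlation a segregating lineage
would have.

Presets: `core_panmictic` (m = 0.2 among 4 demes; θ ≈ 0),
`fragmented_drift` (K = 8, N = 30, m = 0.008, 300 generations; the
island-model equilibrium 1/(1 + 4N(m+mu)(K/(K−1))²) puts θ near
0.45–0.5, the strongly drift-structured regime), `peripheral_founder`
(serial two-founder bottlenecks in two demes, depressing A_R and H_E
there), `selfing_mixed` (s = 0.2 ⇒ t = 0.8), and `null_artifact`
(random mating, nulls at 4 of 13 loci at r = 0.2).

What the simulator does *not* emulate: linkage and genotyping error
beyond nulls/dropout, mutation-rate heterogeneity among loci, range
expansion geometry, overlapping generations, and seed/pollen dispersal
asymmetries beyond the stepping-stone bias. Passing recovery tests
therefore demonstrate estimator correctness under the stated model,
not robustness to everything field data can contain.

## Problem sizes and numerical conventions

The test suite runs the stochastic checks at reduced but statistically
meaningful sizes chosen as a deliberate compromise between resolution
and runtime: chains of 40–50 batches × 2,000 iterations against
enumeration (3-SE agreement), 50 replicates for EM and F_IS recovery
(3-SE bands), 6–10 replicates for regime-band and classification
checks, and permutation/bootstrap counts of 100–200. Production
defaults remain at the conventional 10,000/1,000/10,000 chain
schedule, 10,000 permutations and 10,000 bootstrap replicates, and are
plain flags on the CLI. Seeds thread from a single root generator;
permutation p-values use the add-one rule throughout; undefined
quantities are returned as None/NA rather than silently coerced.

## Known limitations

- The EM null model assumes random mating within populations; under
  strong selfing r̂ is inflated (the screen is designed around this).
- The global heterozygote-deficiency statistic (summed heterozygote
  counts) weights loci by sample size rather than by information; a
  score-based weighting would differ in edge cases.
- Bootstrap supports are reported for the full-data topology only;
  alternative topologies' frequencies are not tabulated.
- The species-level H_T/H_S decomposition uses uncorrected gene
  diversities (see above); published tables from other tools may apply
  small-sample corrections and differ in the third decimal.
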