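# Methods

This note documents the statistical procedures implemented in `fsspipe`,
their assumptions, the parameters that matter, and the design decisions
taken where the study design left the choice open.

## Data model

Genotypes are unphased biallelic dosages of the *designated* minor allele
(0/1/2, NaN = missing) in a samples × SNPs matrix with case/control labels.
"Minor" follows the external reference-panel designation, not the in-cohort
frequency: a designated allele may exceed 50% in this cohort (rs1046934's C
allele is at 51.8% in controls) and the category order of grouped count
tables — (major-homozygote, heterozygote, minor-homozygote) — is fixed by
that designation.  This is the only ordering that reconciles the published
per-SNP allele frequencies with the published association table.
Coordinates are 1-based; allele labels are taken at face value (no strand
flipping — the inputs carry no strand information).  Missing genotypes are
excluded per marker (complete case per SNP), so per-SNP call rates govern
each analysis' effective n.

One packaged inconsistency: for rs3771381 the published risk-allele letter
(A) contradicts the published counts and OR; the count-consistent
orientation (risk = designated T allele) is stored, with a note on the
fixture row.  For four SNPs whose second allele is never printed, a
placeholder major-allele letter is used; it labels a category and never
enters any statistic.

## Quality control

Per SNP: case/control/combined call rates; designated-allele frequency in
controls; HWE by the 1-df Pearson goodness-of-fit χ² with expected counts
from the observed allele frequency, no continuity correction (this
reproduces the published control p = 0.35 for rs1046934).  Monomorphic
markers return χ² = 0, p = 1 — monomorphism is not an HWE departure.

Inclusion filters (defaults = study thresholds): control MAF ≥ 0.05 —
applied to min(f, 1−f), since "minor" frequency means the rarer allele even
under external designation; combined call rate ≥ 0.95 (whether the study's
printed call rate is combined or per-group is not stated; combined is
filtered on, all three are reported); control-HWE p ≥ 0.05.  HWE in cases
is reported but never filters.  When a marker fails several criteria, every
reason is recorded rather than the first hit.  Relaxing any threshold can
only grow the passed set (monotonicity, property-tested).

## Additive association

The additive model regresses disease on risk-allele dosage.  Grouped
counts are fitted by Newton IRLS on the grouped binomial log-likelihood,
relative tolerance 1e-10 with step-halving; this is exactly the
individual-level ML fit (verified against an independent GLM implementation
in the tests).  Reported: β = ln OR per risk allele, 95% Wald CI using the
exact 97.5% normal quantile (1.959964), and a two-sided Wald p — the
default of the mainstream statistical packages this mirrors; a
likelihood-ratio p against the intercept-only model is carried alongside as
a cross-check (whether the published p-values are Wald or LR is unstated;
at these sample sizes they agree to well within printed precision).

Degenerate designs: a monomorphic marker is an error; complete separation
is detected (diverging coefficients or a collapsing information matrix) and
returned as a flagged result with an infinite-β sentinel, never silently.
A marker with no risk-allele designation is oriented to the designated
allele first and the risk allele is then defined as the allele with fitted
OR > 1 — this resolves the rs3771381 labelling inconsistency
deterministically.

DOMDEV adds a heterozygote indicator to the additive model and tests its
coefficient (Wald).  It requires all three genotype categories non-empty in
the pooled sample.  Family-wise control is Bonferroni: α/1,033 for the
additive screen over the GWAS height-SNP catalogue, α/34 for DOMDEV over
the screened markers.

## Pairwise LD

Haplotype frequencies for a SNP pair are estimated from the 3×3 unphased
genotype cross-table by EM: only double heterozygotes are phase-ambiguous,
and their two resolutions are reweighted by the current frequency estimates
each iteration.  Convergence: max frequency change < 1e-10, cap 10,000
iterations.  The linkage-equilibrium start is an EM fixed point for some
symmetric tables (e.g. a sample of pure double heterozygotes sits exactly
on the saddle), so EM also runs from one coupling- and one
repulsion-perturbed start and returns the highest-likelihood solution; the
tests verify it attains the brute-force grid-search maximum on small
samples.  Allele-frequency marginals are invariant under the EM update, so
the search is effectively one-dimensional and boundary optima are reached
cleanly.

From fitted frequencies (allele 1 = major at each locus): D = p11 − p1·p2;
D′ = |D| / Dmax with Dmax = min(p1·q2, q1·p2) for D > 0 and
min(p1·p2, q1·q2) otherwise; r² = D² / (p1 q1 p2 q2).  The sign of D is
reported separately from D′.  0 ≤ r² ≤ D′ ≤ 1 always (property-tested);
r² ≤ D′² is *not* generally true and is not asserted.  A monomorphic locus
makes LD undefined and raises.

Bootstrap CIs for D′ resample complete-case individuals with replacement
(implemented as a multinomial resample of the genotype table, which is
equivalent and vectorizes); percentile interval, default 1,000 resamples;
degenerate (monomorphic) resamples are redrawn and counted.  Haplotype
blocks use the CI-classification rule standard in the field: a pair is
"strong LD" when its CI is [≥ 0.70, ≥ 0.98], "strong recombination" when
the upper bound is < 0.90; maximal intervals whose outermost pair is strong
and in which ≥ 95% of informative pairs are strong become blocks,
longest-first and non-overlapping.  All four thresholds are exposed as
parameters.

Pruning is greedy: markers are visited in priority order and retained iff
D′ with every already-retained marker is ≤ the threshold (default 0.8).
The priority default is ascending additive-model p — keep the most
significant marker of each LD cluster — because the study does not state
its re-selection rule; the rule in force is echoed in every run log.  Pairs
on different chromosomes are defined as D′ = 0 for pruning (physical
linkage only).  LD is computed on pooled genotypes by default; case-only
and control-only variants are available (the study does not say which it
used).

## Weighted genetic risk score

Raw score: Σᵢ wᵢ·xᵢ with wᵢ = ln ORᵢ and xᵢ the risk-allele dosage, range
[0, 2Σw].  Rescaled convention (default): raw · K/Σw for K markers, range
[0, 2K].  The rescaled convention is the default because the published
quartile cut-points (11.88 / 13.50 / 15.05) are impossible on the raw
natural-log scale — with the 13 published ORs, 2Σw ≈ 8.48 — but sit near
the central quartiles of the 0–26 allele-count scale; this inference is a
package choice, documented, not an assertion about the original procedure
(the log base of the original weights is likewise unstated).  Weights are
taken from the association stage or supplied externally.

Missing dosages default to the control-cohort expectation (2 × control
risk-allele frequency); a complete-case policy is available, and any sample
missing more than half of the weighted markers is flagged unreliable.

Quartile cut-points default to the empirical quartiles of the *pooled*
case+control score distribution — the only choice consistent with quartiles
holding unequal case fractions — with left-open, right-closed membership
(a score exactly on a cut-point falls in the lower quartile).  Quartile-vs-
Q1 ORs come from logistic regression on quartile indicators; for this
saturated design the MLE equals the 2×2 cross-product ratio (asserted to
1e-9 in tests), with Wald CIs.  The Cochran–Armitage trend statistic uses
integer category scores 1..k and a two-sided normal p; it matches a
conditional (both-margins-fixed) permutation null within Monte-Carlo error
on small tables.

## Synthetic cohorts

The generator draws control genotypes from HWE proportions at a specified
control risk-allele frequency and case genotypes from the exponential tilt
P_case(g) ∝ P_control(g)·OR^g, which makes the additive logistic OR on the
grouped data equal the specified OR by construction — an analytic recovery
target for every estimator downstream.  Explicit genotype-probability
triples are accepted as an alternative.  LD blocks are specified at the
haplotype level (block SNPs are drawn as two shared haplotypes per
individual, with the case tilt applied at a designated causal SNP); D′ is a
derived property of the haplotype pool, avoiding an ill-posed inversion
from a target D′.  Missingness is independent per cell.  Randomness is
single-seed with per-column substreams, so extending a panel never perturbs
earlier columns, and identical specifications are bit-reproducible.

Default magnitudes in the tests mirror the study conditions: cohort sizes
978/1,129, ORs 1.31–1.55, risk-allele frequencies 0.14–0.75, missingness
≤ 5%.  What the generator does *not* emulate: population stratification,
relatedness, genotyping batch effects, covariates, or any ascertainment
model beyond the tilt (the original cases' ascertainment is described only
by diagnosis; the tilt is one admissible choice).  Passing recovery tests
therefore demonstrates estimator correctness under a clean sampling model,
not robustness to confounding.

## Problem sizes used in the test-suite

Parameter-recovery runs use 50,000 per group (single SNP); the DOMDEV
type-I simulation uses 1,000 null tables of 1,000 per group; bootstrap-CI
coverage uses 500 simulated pairs of n = 400 with 200 resamples; the
GRS-monotonicity check uses 200 replicates at the study's 978/1,129; the
EM-vs-grid oracle uses samples of n = 30 at grid resolution 1e-4.  The
34-marker pruning demonstration uses 13 perfect-coupling clusters
(sizes 4,4,3,3,3,3,2,2,2,2,2,2,2) at 2,000 per group with per-cluster
OR 1.6 — effects large enough that every cluster clears the 5×10⁻⁵ screen
with margin, so the 34 → 34 → 13 flow is guaranteed by construction.

## Known limitations

- Two-locus EM only; no multi-locus phasing or recombination-rate
  estimation.
- No covariate adjustment anywhere (the single-SNP fits mirror the
  unadjusted study models); no per-sample QC.
- The original 34 → 13 pruning cannot be reproduced exactly: it depends on
  individual-level genotypes that were never published.  Likewise the
  published wGRS cut-points cannot be verified without per-individual
  scores; they are used as explicit cut-points where given.
- Binary PLINK (.bed), BGEN, imputed dosages, multi-allelic sites and
  X-chromosome handling are out of scope; VCF reading is GT-field,
  biallelic-SNV only.
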