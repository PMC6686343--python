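# Methods

This note documents the statistical procedures, the simulator and the design
choices behind `selfmeth`, in the order the pipeline applies them.

## Data model and scoring conventions

Genotypes are diploid codominant calls (unordered allele pairs, stored
canonically as (min, max)); the 0/0 pair is the missing-call sentinel, for
interoperability with the GenAlEx-style tool ecosystem these tables usually
come from. MS-AFLP data are two presence/absence matrices per individual —
one per isoschizomer digest (EcoRI/HpaII "HPA", EcoRI/MspI "MSP") — with the
invariant that a cell is missing in both digests or neither: a methylation
state needs both bands, so a half-missing cell is promoted to fully missing
with a logged warning.

Fragment-analyzer peak tables binarize under the standard reproducibility
settings: analysis window 100–500 bp, minimum peak height 100 RFU. Locus
bins are user-supplied half-open intervals (default 1 bp grid); the binning
width is deliberately configurable because co-migrating fragments cannot be
resolved from a sizing window alone. An individual with no recorded peaks in
a digest is missing at every locus of that digest; a recorded-but-filtered
peak scores 0, not missing.

### Methylation states

| HPA | MSP | state | meaning |
|-----|-----|-------|---------|
| 1 | 1 | UNMETHYLATED | target unmethylated |
| 1 | 0 | HEMI | hemimethylated external cytosine |
| 0 | 1 | INTERNAL | internal cytosine methylation |
| 0 | 0 | AMBIGUOUS | hypermethylation *or* absence of target |

A locus is **methylation-susceptible (MSL)** iff its frequency of
HEMI/INTERNAL patterns across all scored cells (AMBIGUOUS included in the
denominator) **strictly exceeds** the error threshold (default 5%,
matching the replicate-reproducibility error rate customary for AFLP);
otherwise it is **NML** and is re-expressed as a dominant AFLP marker via
its HPA presence profile (for NML loci the two digests agree by definition,
up to error). An MSL locus is polymorphic when at least two distinct
non-missing states occur; only polymorphic MSL enter the variability and
modeling steps.

Two conventions differ deliberately and are both flag-switchable:

- the **per-individual methylation proportion** excludes AMBIGUOUS cells
  from the denominator (the pattern confounds hypermethylation with
  fragment absence, so treating it as either methylated or unmethylated
  would bias the proportion in an unknown direction);
- the **group methylation percentage** follows the band-pattern ratio
  formula as printed in the MS-AFLP literature,
  100 × (#HEMI + #INTERNAL) / (#UNMETHYLATED + #AMBIGUOUS), with the
  proportion-of-total reading 100 × methylated/scored available as an
  alternative — the two coincide only when the denominator classes happen
  to exhaust the scored cells, and published "average methylation"
  percentages do not always state which was used.

The replicate error rate divides mismatching (HPA, MSP) cell pairs by
(shared loci × replicated individuals), both digests compared jointly.

## Population-genetic statistics

Expected heterozygosity is the uncorrected gene diversity 1 − Σp² (the
GenAlEx convention; the unbiased 2n/(2n−1) correction is behind a flag).
The multilocus inbreeding coefficient is Nei's F_IS = 1 − H̄_o/H̄_e on
unweighted locus means, not the Weir–Cockerham estimator — at these sample
sizes the two can differ, and the package reports which it computes.
Homozygosity by locus weights each locus by its expected heterozygosity:
HL = Σ_hom E_ℓ / (Σ_hom E_ℓ + Σ_het E_ℓ), with E_ℓ computed from the full
sample including the focal individual, and missing loci excluded from both
sums. The selfing rate is the inbreeding-equilibrium moment estimator
ŝ = 2F/(1+F) (fixed point of F' = s(1+F)/2); negative F clamps to ŝ = 0
with a warning. Published selfing rates from Bayesian-clustering software
use different internal estimators, so ŝ is labeled with its method and no
attempt is made to match any particular published value.

Individuals are classified selfed iff max q ≥ 0.9 (inclusive boundary);
argmax ties break to the first cluster in file order, deterministically and
logged.

## Differentiation

All distances and tests are implemented from first principles.

- **Binary mismatch distance** (MSL, NML): proportion of mismatching
  entries over jointly scored columns; MSL states first collapse to binary
  methylated/unmethylated, since downstream statistics treat methylation as
  binary.
- **Allelic mismatch distance** (microsatellites): per locus 2 − (shared
  allele count) ∈ {0, 1, 2}, averaged over jointly scored loci.
- **AMOVA** (one level, among/within groups): on squared distances,
  SS_total = Σ_{i<j} d²/N, SS_within = Σ_g Σ_{i<j∈g} d²/n_g;
  σ²_within = SS_within/(N−k), σ²_among = (MS_among − σ²_within)/n̄ with
  n̄ = (N − Σn_g²/N)/(k−1); Φ_ST = σ²_a/(σ²_a+σ²_b). Negative variance
  components are retained (Φ may be slightly negative) — truncation would
  bias the small Φ values typical of epigenetic data. Significance permutes
  individuals across groups with sizes fixed; p = (1 + #{Φ_perm ≥
  Φ_obs})/(1 + n_perm), so p ∈ [1/(n_perm+1), 1] and never 0. All-identical
  inputs give an undefined (NaN) Φ. Permutations are evaluated in
  vectorized blocks of 500.
- **Pairwise Φ_ST** restricts the AMOVA to each group pair; raw permutation
  p-values, no multiple-testing correction.
- **PCoA**: Gower double-centering of −d²/2, symmetric eigendecomposition,
  positive-eigenvalue axes in descending order; negative eigenvalues are
  reported, not corrected; percent variance is over positive eigenvalues.
- **Mantel**: Pearson r of vectorized upper triangles; one-tailed
  (positive association) permutation test permuting rows/columns of the
  second matrix jointly.

Only one-level AMOVA is provided: the study design this pipeline serves
analyzes each grouping factor (site, lineage, inbreeding status)
separately; a nested two-level AMOVA is out of scope.

## Parasite statistics

The scaled parasite load is Σᵢ Nᵢ/Nᵢ,max per individual, with each
morphotype's maximum taken over the whole table (all sites pooled) so that
one very abundant morphotype cannot dominate the composite; all-zero
morphotypes are dropped with a warning. Single-taxon analyses (bacterial
cysts) reuse raw counts, not scaled values. Kruskal–Wallis (tie-corrected
H, chi-square p) and Mann–Whitney (U, z from the normal approximation with
tie and continuity corrections, two-sided p) are the group comparisons; the
z/continuity convention is stated because rank-test software differs here.

## Methylation GLM and model selection

The response is the per-individual (methylated, scored) binomial count pair
— individuals differ in scored-locus counts, so the count pair, not the raw
proportion, carries the right weights. Fitting is maximum likelihood by
IRLS with logit link (statsmodels GLM, Binomial family; the log-likelihood
includes the combinatorial constant, which cancels in AICc differences).
Lineage, site and inbreeding enter as unordered factors with first-level
reference coding (lineages ordered by numeric label); because a single
printed coefficient cannot disambiguate a multi-level factor's contrast,
reports always print per-level coefficients. Outcrossed individuals keep
their argmax lineage for the lineage factor; inbreeding status is a
separate binary factor.

Candidate models are every subset of the main effects {lineage,
scaled_load *or* bacterial_cysts, inbreeding, site (all-sites scope only)}
crossed with every two-way interaction subset under marginality. With
lineages nested almost completely within sites, many site-containing models
are rank-deficient; these are skipped with a warning naming the aliased
columns rather than silently dropping coefficients. Ranking uses
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1); Akaike weights and evidence ratios use
the standard exp(−Δ/2) normalization. Overdispersion (Pearson χ²/df) is
reported but not corrected; quasi-likelihood is out of scope. The site1-only
scope drops the site term and restricts to site1 individuals, removing the
site–lineage confounding.

## Simulator

`synthetic_data.simulate` is a forward-in-time, discrete-generation
simulator of K selfing lineages distributed over sites by an occupancy
table. Each generation, every deme slot draws a parent uniformly from its
(site, lineage) deme; with probability s the offspring selfs (two
independent gametes from the same parent, halving heterozygosity in
expectation), otherwise a second parent comes uniformly from the same site
(any lineage) — sites are treated as isolated, mirroring isolated mangrove
systems with strong between-site structure. Founder allele frequencies are
lineage-specific Dirichlet draws (small concentration pushes lineages
toward fixing different alleles); mutation is omitted because generation
counts are small and the analysis never estimates mutation parameters.
Ancestry fractions propagate as q' = (q_p1 + q_p2)/2 and are emitted as the
q-matrix; the truth record marks an individual selfed iff its
final-generation reproduction event was selfing, so threshold-based
classification can — deliberately — disagree with truth for selfed
offspring of mixed-ancestry parents.

Parasite counts are negative binomial per site × lineage × morphotype
(gamma–Poisson mixture; variance μ + μ²/θ). Methylation: each individual's
Bernoulli probability for MSL loci is
logistic(α_lineage + (β_p + β_{l×p})·load + (β_i + β_{l×i})·outcrossed +
β_{p×i}·load·outcrossed); a methylated cell is HEMI or INTERNAL with equal
probability (the split is inert downstream, where both count as
methylated); unmethylated cells are HPA+/MSP+. With small configured
probabilities a cell becomes AMBIGUOUS (0,0) or missing. Non-MSL loci carry
lineage-determined constant bands identical in both digests.

### Default study configuration

`default_study_config()` encodes the emulated design: 128 individuals in
3 sites — site1: lineages 1/2/4/6 with 14/25/22/7 individuals, site2:
lineage 3 with 41 plus one lineage-6 individual, site3: lineage 5 with
18 — 27 microsatellite loci (8 founder alleles, Dirichlet concentration
0.4), selfing probability 0.95 over 15 generations, and 381 MS-AFLP loci
with 70% MSL. Site-level parasite means (bacterial cysts 3.16/2.66/1.27,
protozoan cysts 0/1.52/0.33, nematodes 0.16/0.02/0; NB dispersion 1.5)
follow the observed site abundances of the emulated study. Methylation
baselines per lineage span logits −0.48…−0.10 (population methylation in
the high-30s to high-40s percent range); main effects β_p = 0.2,
β_i = 0.3 and lineage interactions of magnitude ≤ 0.5 are sized to be
detectable but not overwhelming at N = 128 — no published effect-size
scale exists for these interactions, so detectability at the study's
sample size is the design criterion. Ambiguous-cell and missing-cell
probabilities are 0.05 and 0.02.

### What the simulator does and does not emulate

It reproduces the statistical structure the pipeline assumes: lineage
near-homozygosity, rare within-site outcrossing, site/lineage-structured
parasites, and methylation driven by lineage × environment interactions.
It does **not** emulate microsatellite mutation, linkage, chromosomal
structure, environmental methylation inheritance across generations, or
locus-specific methylation effects (all MSL loci of an individual share one
methylation probability, so there is no between-locus overdispersion).
Passing tests therefore demonstrate correctness of the estimators and
calibration of the tests under this generative model, not robustness to
real-data pathologies such as null alleles, scoring drift between plates,
or locus-specific epigenetic signals.

## Numerical choices and problem sizes

- GLM convergence: IRLS, relative deviance change < 1e-8, ≤ 100
  iterations; complete separation is flagged (|coef| > 15 or SE > 1e3),
  not raised.
- Permutation p-values always use the inclusive (+1) estimator; permutation
  RNG is seeded from the pipeline configuration, and every simulation or
  test records its seed.
- The pure-selfing heterozygosity-decay check runs 2,000 individuals for
  10 generations at 500 loci: at that locus count the Monte-Carlo relative
  standard deviation of mean heterozygosity is ≈ 4–5%, comfortably inside
  the 10% comparison band, whereas a 27-locus panel would leave ≈ 20%
  noise on an expectation of ~26 heterozygous calls.
- Calibration suites use 500 permutations × 500 replicates with small
  instances (Mantel: 12×12 matrices; AMOVA: 16 individuals in two groups;
  Kruskal–Wallis: 3 groups of 10), which keeps each suite in fractions of
  a second while the discrete permutation p-grid (1/501 spacing) stays far
  below the Kolmogorov–Smirnov resolution at 500 replicates.
- Parameter-recovery suites: selfing-rate recovery uses single-deme
  populations (N=100, 27 loci, 15 generations, 20 seeds per rate) so the
  equilibrium estimator is not confounded by Wahlund effects; the
  coverage simulation (200 seeds) fits the correctly specified model with
  true covariates, since it measures Wald-interval calibration rather than
  classifier accuracy.

## Known limitations

- F_IS is Nei's multilocus ratio; Weir–Cockerham would differ at small n.
- The equilibrium ŝ assumes inbreeding equilibrium and no population
  structure; in structured samples the pooled F_IS includes a Wahlund
  component and ŝ is biased upward.
- AMOVA distance metrics are documented choices (simple mismatch, allelic
  mismatch); other software uses different internal metrics, so Φ values
  are comparable only within a metric.
- The GLM screen reports ranking, weights and evidence ratios only;
  model-averaged coefficient inference is not provided.
- Overdispersion of methylation counts is reported but not corrected.
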