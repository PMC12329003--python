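# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `popsplit`. Units throughout: effective sizes N are
diploid individuals; times are generations before present; migration rates
are per-generation fractions; likelihoods are log₁₀.

## Genotypes and filtering

Genotypes are alt-allele dosages in {0, 1, 2, missing}. The filter chain is
applied in the fixed order MAF → missingness → depth → per-locus thinning,
with the conventions of VCFtools-style filtering: *minor allele frequency
strictly greater than* `maf_min` (default 0.05, computed over non-missing
calls), a site called in at least 80% of individuals
(`max_missing_fraction = 0.20`), mean depth across genotyped individuals of
at least 3, and one SNP kept per locus to remove within-locus LD. Per-locus
choice is seeded-uniform-random by default with a deterministic first-SNP
mode for reproducibility; the filter order itself is a documented choice —
the counts per criterion depend on it, the surviving set barely does.

## Diversity and differentiation

Per-group heterozygosity is the mean over sites variant *in the whole
filtered matrix* of (heterozygotes / genotyped group members); a group fixed
at a site contributes zero there. Computing over globally-variant (rather
than within-group-variant) sites is a documented reading of the ambiguous
convention; it matches per-locality values being comparable on one site set.
Groups of one individual are reported but flagged and excluded from means.

Pairwise F_ST uses Weir & Cockerham's θ, combined across loci as a ratio of
sums Σa / Σ(a+b+c); a plug-in Wright-style 1 − H_w/H_t alternative is
selectable. Significance gating follows the survey tradition: loci are
resampled with replacement (default 1000 bootstraps), p is the fraction of
resamples with θ* ≤ 0, and entries with p ≥ 0.05 are flagged; flagged
entries are reported as missing rather than zeroed (both retrievable).
Negative multi-locus estimates are reported as computed. Wright bins use
edges {0.05, 0.15, 0.25}; fractions are emitted with two denominators
(unique pairs, and pairs plus the zero diagonal) because published summary
percentages are not always explicit about which they use.

## PCA and the number of clusters

Genotypes are centered by 2p̂ and scaled by √(2p̂(1−p̂)) (the standard
allele-frequency normalization for genotype PCA; unscaled centering is a
flag), missing calls mean-imputed, and components computed by SVD. Three
components are kept by default for visualisation.

For cluster-number selection, Gaussian mixtures (diagonal covariance,
k-means initialization, seeded restarts) are fitted on the PCs whose
eigenvalues exceed the Marchenko–Pastur noise edge (1 + √(n/L))² — retaining
fixed 3 components lets pure-noise axes swamp weak splits. K from 1 to
(number of regions + 2) is scored. The default criterion is BIC. Evanno's
ΔK = |L(K+1) − 2L(K) + L(K−1)| / sd(L(K)) is implemented on the replicate
log-likelihoods, but on *converged* mixture likelihoods it inherits its
well-known bias toward the uppermost hierarchical level (here, the deep
Yalu split), so it is not the default; when every replicate converges
identically (zero spread) it falls back to BIC with a warning. Only the
argmax behaviour of the selection — four clusters on four-population data —
is claimed, not numerical comparability with admixture-MCMC likelihoods.

## Structured-coalescent simulator

The engine is the continuous-time structured coalescent: within deme i with
k_i lineages, coalescence at rate k_i(k_i−1)/(4N_i) per generation;
backward migration at per-lineage rates M[i][j] (probability a lineage in i
has its parent in j); demographic events (joins with optional ancestral
resize, resizes, migration-matrix replacement) at fixed times. Lineages
trapped in disconnected demes trigger a guard error after a configurable
event/time budget rather than spinning forever.

Mutations are dropped on realized genealogies either as infinite-sites
Poisson(μ L × tree length) or in `one_snp` mode — exactly one mutation on a
branch chosen proportional to length — which is the
conditioned-on-polymorphism model matching ascertained SNP panels. `one_snp`
is the default for emulating the study data; infinite-sites serves the
theory oracles (Watterson's E[S], etc.). An optional minor-allele-frequency
condition on the chosen branch emulates a MAF-filtered panel.

One seeded generator drives each run; per-locus substreams are drawn
sequentially so earlier loci are unchanged when the locus count grows.

An important consequence of polymorphism conditioning: the normalized SFS of
a single panmictic deme is independent of N, so absolute sizes are
identified only through *relative* rates across demes and epochs — see the
identifiability remarks below.

## Joint site-frequency spectra

Observed pairwise JSFS are built by hypergeometric expectation-projection:
per site, each group's alt count is projected to fixed haploid sizes by
adding the full hypergeometric mass across cells (deterministic, unbiased,
and tolerant of partial missingness); sites with fewer called haplotypes
than the projection are dropped and counted. Spectra are folded
(minor-allele) by default — no outgroup exists for this species — with the
two monomorphic corners and the fold-redundant half masked.

Expected spectra are Monte-Carlo estimates over independent genealogies of
the full four-population model: every branch adds its length to the cell
given by its subtended leaf counts in each population pair
(Rao-Blackwellized relative to sampling single mutations, so hundreds of
genealogies suffice where tens of thousands of sampled SNPs would be
needed). All six pairs share one set of genealogies. Zero cells are floored
at 1/(10 n_sims) and renormalized so observed mass never meets a zero
expectation.

Four-population fits use the six pairwise spectra jointly (a composite
likelihood) rather than a 4-D spectrum: ~1400 SNPs cannot populate a 4-D
grid.

## Demographic models and fitting

The candidate set holds the three strict-isolation topologies for the order
of the southern/northern/Japanese divergences after the initial Yalu split,
the best topology (Japanese subdivides from northern) plus three gene-flow
scenarios between the adjacent southern and northern populations —
continuous (IM), ancient-only (AM, flow before a stop time T3) and
secondary contact (SC, flow after a start time T3) — each with steady
bidirectional northern↔Japanese and northern↔Yalu flow, and an SC variant
with founding-size change along each terminal branch. Migration parameters
are stated forward in time; the model builder performs the
forward→backward index swap and restricts each epoch's matrix to extant
demes.

Free parameters are searched on log₁₀ scale: sizes in [10², 10⁷], time
*increments* in [10, 10⁵] (which enforces T0 > T1 > T2 by construction),
migration in [10⁻⁸, 10⁻¹]; the contact fraction T3/T1 is linear in
[0.02, 0.98]. The optimizer is a multi-start cyclic per-parameter
golden-section search with common random numbers within a run (the
coordinate search sees a deterministic surface), an optional narrow-width
refinement stage at a higher simulation count, and a per-batch coalescent
event budget so pathological high-migration corners score −∞ fast instead
of stalling. `staged_fit` adds nested warm starts (SI → IM → AM/SC, the
windowed scenarios entering at the boundary contact fraction that
reproduces the IM fit, then profiling only their distinguishing
parameters) and re-scores every candidate with one common simulation seed
so the AIC comparison shares rather than compounds its Monte-Carlo error.

Reported quantities follow the SFS-fitting conventions: MaxObsLhood is the
saturated bound Σ m log₁₀(m/Σm); MaxEstLhood ≤ MaxObsLhood always (Gibbs);
ΔL = MaxObsLhood − MaxEstLhood; AIC = 2k − 2 ln(10) MaxEstLhood.
Parametric-bootstrap CIs refit spectra simulated at the point estimate and
take 2.5/97.5 percentiles; percentile intervals need not bracket the point
estimate. Times convert to years at 2.5 years/generation; the mutation rate
convention is 2.5×10⁻⁸ /site/generation (it cancels in `one_snp` fits).

### Identifiability at the packaged best-fit history

Two structural limits of these data are worth stating because the test
suite documents them honestly:

* **N1 (and other low-drift sizes) are near-unidentified.** At the best-fit
  values T1/2N1 ≈ 0.02: almost no coalescence happens on pop 1's branch, so
  the likelihood profile in N1 is flat within Monte-Carlo error across two
  orders of magnitude. When the staged fit reports N1 near its generating
  value, that mostly reflects where the search was anchored, not
  information in the data — the recovery test says so explicitly. T1, T0,
  N0 and N3 are well identified.
* **SC vs AM/IM margins are a few log₁₀ units.** The fitted contact phase
  has M01 × T3 ≈ 2 — the northern population is nearly swamped during
  contact — so secondary contact, ancient migration with a small recent
  gap, and IM produce almost identical folded spectra. With near-exhaustive
  optimization the SC truth beats the best AM point by ≈ 2 log-units and
  the best IM point by ≈ 1 (ΔAIC ≈ 9 and 2.6); these margins flip sign
  across data replicates at 1500 SNPs. The model-ranking experiment is run
  faithfully and its strict "SC first in ≥ 7/10" assertion is expected to
  fail at desk scale; the strict-isolation model is reliably rejected.

## Outlier scan

Per SNP, the global multi-population Weir–Cockerham F_ST and total expected
heterozygosity 2p̂(1−p̂) are compared against a neutral (het, F_ST) cloud
from a hierarchical island model (groups of demes with within- and
between-group migration at a fixed 10:1 ratio), calibrated by bisection —
seeded at the analytic island-model guess — until the realized multi-locus
F_ST matches the observed genome-wide value within 0.005. Null and observed
statistics use the same estimator on diploids formed by pairing haplotypes.

p-values are two-tailed empirical proportions within heterozygosity strata
(bins of width 0.05, merged until each holds enough null points). No
add-one smoothing is applied — in the FDIST tradition an observation outside
the simulated cloud scores p = 0 — because with finitely many simulations
the smoothed floor 2/(n+1) would make any single extreme locus
un-flaggable after FDR correction. The cost is mild anticonservatism at the
extreme tail, controlled in practice by the type-I calibration test (the
flagged fraction under the neutral null stays ≤ 7% at q < 0.05).
Benjamini–Hochberg step-up gives q-values; flagged loci above the null
median of their stratum are classified as candidates for positive
selection, below it for balancing selection.

The exact heterozygosity-conditioning and tail construction of legacy FDIST
implementations are version-dependent; this empirical-bin scheme is a
documented stand-in and is not expected to reproduce any particular
historical flag count on identical data.

## Synthetic data generator

The default design mirrors the survey: 18 localities (sizes summing to
144) in 7 regions, mapping to four genetic populations; the three mixed
Taiwan-Strait/East-China-Sea localities draw each individual from the
southern population with probability 0.3 (matching the ~5/17 split of the
survey's assignment) and the northern otherwise. 1392 loci carry one
ascertained SNP each (branch choice conditioned on sample minor-allele
frequency > 0.05, emulating a post-filter panel); a few percent of loci
carry a second SNP, have sub-threshold depth, or elevated missingness, so
every filter rule is exercised while > 90% of sites survive — a design
guarantee asserted in tests. Per-call depths are Poisson around a per-site
Gamma mean (~20×). Haplotypes are paired into diploids within populations;
admixed localities are handled by population reassignment at sampling time,
not by simulating admixture LD (sites are unlinked post-thinning).

Default parameters are the packaged best-fit secondary-contact history with
sizes and times ÷10 and migration ×10, preserving the drift (T/N) and
gene-flow (N·M) scales so summary statistics are approximately invariant
while 1392-locus simulation runs in seconds; `scale=1` restores the
published values. Northern↔Yalu migration, part of the model space but with
no published point values, is zero in the packaged parameter set.

What the generator does *not* emulate: sequencing error, capture bias,
within-locus LD, missingness that correlates with genotype, and real
ascertainment cascades. Tests passing on these data show the pipeline's
statistical machinery is correct and calibrated under the stated model;
they do not validate robustness to those real-data artifacts.

## Scaled experiment sizes

Desk-scale defaults used by the test suite and the acceptance script (the
production-scale values remain one settings object away): cluster-number
recovery at 30 individuals/population × 1392 loci across 10 seeds;
model-comparison and parameter-recovery experiments at 1500 SNPs, 8
haploids/population projections, 1–2 optimizer starts with 2–3 coarse
cycles plus one refinement cycle, and 4000-genealogy common-seed
rescoring; outlier calibration with a 3-group × 5-deme null, ~900 null
loci and 250-locus panels across 10 seeds; oracle checks at 800–4000
replicates. Production-style settings (20+ starts, 10⁴–10⁵ simulations per
evaluation, survey-size nulls of 20 groups × 100 demes × 20000
simulations) are exposed through `FitSettings` and `NullConfig`.
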