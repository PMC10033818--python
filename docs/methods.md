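# Methods

This note documents the models behind `selfscan`, the defaults and their
rationale, what the synthetic-data generator does and does not emulate, and
the numerical choices that matter for reproducing or extending the analyses.

## Setting and assumptions

The package analyses two genotype samples of *one* population taken τ
generations apart (default τ = 31, one generation per cropping year over about
three decades). The organism is assumed predominantly self-fertilising
(default selfing rate 0.95; rice outcrossing rarely exceeds a few percent), so
observed heterozygosity is on the order of 1–2% and allele copies within an
individual are strongly correlated. Both outlier tests treat loci as
independent; linkage enters only downstream, when significant SNPs are
aggregated into candidate regions.

## Population-genetic statistics

Genotypes are dosage-coded (0/1/2 alternate-allele copies, −1 missing); all
coordinates 1-based. Missing data are handled by locus-wise/pairwise deletion,
never imputation.

* **QC filters** (defaults MAF > 0.01, missing < 0.20, heterozygote fraction
  < 0.05) match GBS SNP-panel practice for selfing material. For a temporal
  pair the thresholds are applied on the two collects *pooled*: filtering each
  collect separately would censor precisely the loci that drifted or swept far
  between the samplings and bias the temporal F<sub>ST</sub> down (we verified
  this empirically; the bias halves the apparent genome-wide differentiation).
  The heterozygosity filter is a selfing-panel rule: for outcrossing material
  it must be relaxed (`het_max=1.0`), otherwise it discards most intermediate-
  frequency loci.
* **Gene-identity summaries.** Within-sample identity f̂₀ uses the unbiased
  (without-replacement) estimator on allele counts; between-sample identity
  f̂₁ is the cross-product of allele frequencies. The identity-based locus
  F̂<sub>STi</sub> = (f̂₀ − f̂₁)/(1 − f̂₁) is undefined when both samples are
  fixed for the same allele (reported missing).
* **Weir–Cockerham components** are computed at the individual level (a, b, c
  with the heterozygosity terms), which keeps the estimator valid under
  inbreeding. Negative per-locus estimates are retained; the global estimate
  is the ratio of summed components. The multilocus F̂<sub>IS</sub> is
  1 − Σc/Σ(b+c) with the two collects as the two populations.
* **LD** is the squared Pearson correlation of dosage vectors (composite LD).
  In material that is >98% homozygous, dosages are essentially haplotypes, so
  no EM haplotype phasing is attempted. Decay profiles use a separate sub-25 kb
  "initial LD" class and 50 kb classes beyond it (class widths are a package
  choice; only the sub-25 kb convention is inherited from practice).

## Drift-null outlier test

N̂<sub>e</sub> = τ(1 − F̂<sub>ST</sub>)/(4 F̂<sub>ST</sub>) inverts the
expectation E[F<sub>ST</sub>] ≈ τ/(τ + 4N<sub>e</sub>) for two samples τ
generations apart. This estimator targets the *variance* effective size; under
selfing at rate s the variance N<sub>e</sub> of a census-N population is
roughly N/(1 + F<sub>IS</sub>), and the recovered value should be compared
against that, not against census N.

Per-locus null (one draw):

1. γ₀ ~ Dir(K₀ + 1), K₀ the observed genotype counts at t = 0 — a flat-prior
   posterior that propagates the sampling uncertainty of the first collect;
2. K*₀ ~ Mult(n₀, γ₀) — the simulated first sample; re-sampling *both* ends is
   what puts the t = 0 sampling noise inside the null (omitting it makes the
   test anticonservative);
3. π₀ = γ₀(AA) + γ₀(Aa)/2, then τ binomial generations at 2N̂<sub>e</sub>
   gene copies (rounded to the nearest even integer ≥ 2); fixation is
   absorbing;
4. γ<sub>τ</sub> from (π<sub>τ</sub>, F̂<sub>IS</sub>) with F clipped to
   [0, 1] (the inbreeding parameterisation needs F ≥ 0 to give valid genotype
   frequencies at every π); K*<sub>τ</sub> ~ Mult(n<sub>τ</sub>, γ<sub>τ</sub>);
5. F*<sub>ST</sub> = Weir–Cockerham theta between K*₀ and K*<sub>τ</sub>.
   Draws where both simulated samples are monomorphic carry no differentiation
   and enter the tail count as 0.

p̂ = (1 + #{F* ≥ F<sub>obs</sub>})/(1 + n_sim) avoids zero p-values. Loci
monomorphic in both observed samples are skipped and excluded from FDR.
q-values are Benjamini–Hochberg by default (Storey's estimator with π₀ at
λ = 0.5 is available); outliers are q < 0.05.

**Choosing n_sim.** The desk default is 1,000 draws/locus (50,000 is the
full-scale setting). Note the FDR floor: the smallest attainable q is
approximately m/(k·(n_sim+1)) for m tests and k true outliers, so detecting
~10 outliers among ~1,000 loci at q < 0.05 needs n_sim ≳ 3,000. Power runs in
the test-suite use 5,000 for this reason.

On neutral simulations at the study conditions (N<sub>e</sub> = 500, selfing
0.95, τ = 31, n = 100/100, L = 1,000) the p-value distribution is uniform
(the acceptance suite checks the sub-0.05 mass and a Kolmogorov–Smirnov test).

## Heterozygosity-based (FDist-style) test

The global F̂<sub>ST</sub> is the h₁-weighted average of the identity-based
locus values (w<sub>i</sub> = 1 − f̂₁<sub>i</sub>); the between-population
heterozygosity is Ĥ₁ = ĥ₀/(1 − F̂<sub>ST</sub>).

The neutral null is simulated under a hierarchical island model: k = 50 groups
of d = 10 demes (many villages, each holding few varieties, with preferential
within-village exchange); the two samples sit in two demes of one group.
Migration is parameterised as per-lineage scaled rates (time unit = 2N
generations per deme, within-deme pair-coalescence rate 1); the between:within
ratio is fixed at 1:10 by default and the within rate is calibrated so the
h₁-weighted mean of a ≥ 2,000-locus pilot cloud matches the observed global
F̂<sub>ST</sub> within 10% (the same weighted statistic on both sides, so the
calibration is self-consistent). The closed-form island guess
m<sub>w</sub> ≈ (1/F<sub>ST</sub> − 1)/(2(d/(d−1))²) usually lands inside the
tolerance immediately; otherwise geometric bracketing plus log-bisection.
Undifferentiated inputs (weighted F̂<sub>ST</sub> ≤ 0) are calibrated to a
floor of 10⁻³ — an exactly-zero target is unreachable by any finite island
model, and observed loci with F<sub>ST</sub> ≤ 0 cannot exceed an upper
envelope anyway.

Each simulated locus is an event-driven structured-coalescent genealogy of the
sampled lineages carrying exactly one mutation on a branch drawn in proportion
to branch length (single-SNP model; monomorphic outcomes are impossible
because the root branch is excluded). (h₁, F<sub>ST</sub>) are computed from
the resulting biallelic partition with the same identity estimators as the
data. The simulator is JIT-compiled with numba and handles migration events in
O(1), which is what makes the 500-deme, high-migration regime affordable
(~8 ms/locus at F<sub>ST</sub> ≈ 0.03); a general-purpose coalescent engine
with a 500 × 500 migration matrix is orders of magnitude slower here. The
engine is cross-checked in the test-suite against the classic island-model
F<sub>ST</sub> expectation and against msprime on a small 4-deme
configuration.

Observed loci receive one-sided upper-tail p-values by Gaussian-kernel
weighting on the heterozygosity axis (Silverman bandwidth on the cloud's h₁;
floor 1/(n+1)); a locus whose h₁ lies outside the simulated support gets a
missing p with a warning. Empirical 1% and 5% envelopes (per-h₁-bin upper
quantiles, 25 bins, ≥ 50 points per bin, linear interpolation between bin
centres) provide the graphical classification; a locus is labelled `sig1`/`sig5`
only if it is both beyond the envelope and has p ≤ 0.01 / ≤ 0.05, which makes
the class labels consistent with both decision routes.

Sample sizes for the null are haploid gene counts, by default twice the
observed median genotype counts. Under near-complete selfing the two genes of
an individual are highly correlated, so 2n haploids overstate the effective
gene sample; the null is correspondingly conservative for strongly inbred
data. This mirrors how the outcrossing-based method is conventionally applied
to selfing material and is the main reason the drift-based test is the more
principled of the two for such data.

## Candidate regions and enrichment

Significant SNPs are chained into independent loci by single linkage on
adjacent pairs: joined when the distance is < 250 kb AND adjacent-pair
r² > 0.2 (an OR variant is a config switch). Loci from different genetic
groups on one chromosome merge when any component SNPs are within 250 kb
(transitive closure). Loci are typed M2 if ≥ 1 member SNP is significant under
both detection methods, else M1; single-SNP loci supported by one method only
are dropped by default. Retained intervals are extended ±250 kb, clipped to
[1, chromosome end] (IRGSP-1.0 lengths bundled, overridable).

Overlap with gene/QTL annotations uses closed 1-based intervals (touching
endpoints count); totals deduplicate records by id so adjacent intervals do
not double-count. Term enrichment is exp = input·term_ref/ref_total,
fold = obs/exp (optional hypergeometric tail p); density enrichment is the
observed per-Mb feature density relative to a genome-wide Mb-per-feature
expectation supplied by the caller (the genome-wide QTL density, e.g. one per
0.62 Mb, is an input, not derived).

## Climate and phenotype contrasts

Monthly series are aggregated to the June–October growth season (rainfall
summed, temperatures averaged; a year with any requested month missing is
missing). The standardised anomaly (Lamb index) is I = (X<sub>i</sub> − X̄)/σ
against the 1961–1990 reference with the sample (n−1) sd convention
(switchable); reference years then have mean 0 and sd 1 exactly. A perfectly
constant series has zero reference sd and the index is reported as undefined.
Period contrasts are plain differences of period means. The days-to-heading
contrast reports collect means, the advance (collect 1 minus collect 2),
Welch's unequal-variance t (normality violations are common in such data, so
the classical ANOVA is not the default) and per-collect Shapiro–Wilk flags as
a caveat only.

## Synthetic-data generator

`simulate_temporal_population` is an individual-based Wright–Fisher model:
diploid census N<sub>e</sub>, each offspring from a selfing event with
probability `selfing_rate` else random outcrossing, fertility selection
multiplying a parent's sampling weight by (1+s) per favoured-allele copy at
selected loci, loci unlinked, samples of n₀/n<sub>τ</sub> drawn without
replacement at generations 0 and τ. Initial frequencies are U-shaped
Beta(0.5, 0.5) truncated at MAF 0.01 (a MAF-filtered GBS panel); initial
genotypes start at the selfing-equilibrium inbreeding
F = s/(2−s). Selected loci start as *common* standing variants (favoured
allele at Uniform(0.5, 0.8), configurable): selection then drives them toward
fixation and their heterozygosity falls, as observed at real selection
footprints — a sweep from a rare allele instead ends with the two samples
near-fixed for opposite alleles, at heterozygosities no neutral null reaches.
The truth block records the selected set and full allele-frequency
trajectories. A separate Markov-copying generator (`linked_dosage_matrix`)
produces matrices with exponentially decaying LD of known scale for
LD-profile tests. Climate and phenotype generators add a seasonal profile +
trend + noise grid and Gaussian group × collect days-to-heading records (group
means default to the studied landrace groups, including the 10.3-day advance
of the African-rice group at n = 59/85).

What the generator deliberately does **not** emulate: village-metapopulation
structure and seed exchange (the population is panmictic between selfing
events), linkage and hitchhiking along chromosomes (loci are unlinked except
in the LD helper), genotyping error and missingness patterns, and soft or
asynchronous sweeps. Passing tests therefore demonstrate the estimators'
correctness under their own assumptions, not robustness to every property of
real GBS data.

**A genuine limitation worth knowing.** Under ~95% selfing, several strong
simultaneous sweeps collapse the *genome-wide* background: with effective
recombination suppressed, lineages are quasi-clonal and the whole genome
hitchhikes, inflating neutral temporal F<sub>ST</sub> to ~0.2–0.4 regardless
of census size (we verified this at census 500 and 2,000). No per-locus
outlier test can then separate the planted loci from the background — the null
is estimated from that same inflated genome-wide drift. The power checks
therefore run under outcrossing, where the per-locus-independence assumption
of the drift null holds; for real selfing data the corresponding caveat is
that power is low when many loci respond at once, and detected outliers are
better read as markers of selected multilocus genotypes than as point targets
of selection.

## Numerical choices and degenerate inputs

* τ default 31, configurable; 2N̂<sub>e</sub> rounded to the nearest even
  integer ≥ 2 for the drift chain.
* Monte-Carlo p-values never reach 0 ((1+count)/(1+n) estimator); kernel
  p-values floored at 1/(n+1).
* Temporal F̂<sub>ST</sub> ≤ 0 → N<sub>e</sub> non-estimable → the drift scan
  aborts with an explicit error (no silent ceiling).
* Negative F̂<sub>IS</sub> is clipped to 0 only inside the null's genotype
  reconstruction; the reported estimate is unclipped.
* Identity-based F<sub>ST</sub> missing when both samples are fixed for the
  same allele; Weir–Cockerham missing when a sample has < 2 callable
  genotypes or total variance is zero.
* HapMap heterozygote codes are IUPAC or two-letter; codes not matching the
  declared alleles become missing and are counted in the parse report.
  Multi-allelic and indel records are dropped and counted. Strand is ignored
  (allele-frequency-based analyses only).
* Envelope bins with < 50 points are left missing rather than extrapolated.

## Problem sizes

Desk-scale defaults (1,000 loci, samples of 100, 1,000 drift draws, 5,000
coalescent loci) run each scan in seconds to ~1 minute on one CPU; the
full-scale settings (50,000 draws/simulations) are config flags. The
acceptance script completes in a few minutes.
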