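# selfscan

Temporal F<sub>ST</sub> genome scans for partially selfing populations.

When the same population is sampled twice, a generation gap apart, genetic
drift sets the scale of the allele-frequency differences one should expect at
neutral loci. Loci whose differentiation exceeds that scale are candidates for
directional selection. `selfscan` implements this temporal genome-scan logic
for the setting where it is hardest to get right — highly autogamous crops
such as rice landraces, where >90% selfing means allele copies within an
individual are not independent draws from the population — together with the
statistics, clustering and enrichment arithmetic that turn per-SNP outliers
into interpretable candidate regions. It is aimed at population geneticists
analysing temporal (resurrection-style) collections of selfing species.

## The two outlier tests

**Drift-null test** (genotype-based, selfing-aware). The genome-wide temporal
Weir–Cockerham F<sub>ST</sub> between the two samples gives an effective size

&nbsp;&nbsp;&nbsp;&nbsp;N̂<sub>e</sub> = τ(1 − F̂<sub>ST</sub>) / (4 F̂<sub>ST</sub>),

where τ is the number of generations between samples. Each locus is then
tested against its own simulated null: genotype frequencies γ₀ are drawn from
the Dirichlet posterior Dir(K₀ + 1) given the observed genotype counts K₀ at
the first sampling; the allele frequency π drifts for τ generations as
π<sub>t</sub> ~ B(2N̂<sub>e</sub>, π<sub>t−1</sub>)/2N̂<sub>e</sub>; genotype
frequencies at τ are rebuilt from π<sub>τ</sub> and the multilocus F̂<sub>IS</sub>;
and both samples are re-drawn multinomially. The upper-tail proportion of
simulated Weir–Cockerham F*<sub>ST</sub> values at or above the observed one is
the p-value; Benjamini–Hochberg q-values flag outliers at q < 0.05.

**Heterozygosity-based (FDist-style) test.** Per-locus F̂<sub>STi</sub> =
(f̂₀ − f̂₁)/(1 − f̂₁) from within/between gene-identity probabilities, a global
heterozygosity-weighted F̂<sub>ST</sub>, and a neutral joint (heterozygosity,
F<sub>ST</sub>) cloud simulated under a hierarchical island model (k = 50
groups × d = 10 demes, mimicking villages holding a few varieties each) with
migration calibrated to the observed global F̂<sub>ST</sub>. Each simulated
locus is a structured-coalescent genealogy carrying exactly one mutation.
Observed loci get one-sided kernel-density p-values conditional on their
heterozygosity and are classified against the empirical 1%/5% envelopes.
The event-driven coalescent is JIT-compiled (numba), which keeps the 500-deme,
high-migration model tractable: a 5,000-locus null cloud takes ~40 s.

Around the scans: SNP filtering (MAF > 1%, missing < 20%, heterozygosity < 5%),
multilocus F<sub>IS</sub>, LD decay profiles (r² by distance class),
single-linkage clustering of significant SNPs into independent loci
(< 250 kb and r² > 0.2), cross-group merging, M1/M2 classification, ±250 kb
extension, annotation overlap and fold-enrichment/QTL-density arithmetic, and
a climate module (growth-season aggregation, standardised Lamb anomalies
against a 1961–1990 reference, period contrasts) plus a days-to-heading
contrast. A forward individual-based simulator of a partially selfing
population (with optional planted sweeps, plus climate and phenotype
generators) makes every stage testable without any external data.

## Worked example

```python
import numpy as np
import selfscan as ss

rng = np.random.default_rng(0)
sel = tuple(int(x) for x in rng.choice(1000, size=10, replace=False))
cfg = ss.SimConfig(n_loci=1000, ne=500, selfing_rate=0.0, tau=31,
                   n0=100, n_tau=100, selected=sel, sel_coef=0.3, seed=0)
pair = ss.simulate_temporal_population(cfg)          # two samples, 31 generations apart
fpair, rep = ss.filter_pair(pair, het_max=1.0)       # QC filters, pooled across collects

dres = ss.TemporalDriftScan(fpair, ss.DriftScanConfig(n_sim=5000, seed=1)).fit()
print(dres.summary())
fres = ss.FdistScan(fpair, ss.IslandModelConfig(n_sim=5000, seed=2)).fit()
print(fres.summary())
```

prints

```
Temporal drift-null outlier scan
================================
loci tested            962
generations (tau)      31
null draws per locus   5000
global temporal FST    0.021746
Ne (temporal)          348.6
multilocus FIS         0.0003
outliers (q < 0.05)     8

Heterozygosity-based (FDist) outlier scan
=========================================
loci tested             962
island model            k=50 groups x d=10 demes
null cloud size         5000
global FST (weighted)   0.021747
H1 (between pops)       0.2914
migration (w, b)        18.2, 1.82
outliers beyond 1%      14
outliers in 1-5%        19
```

Reading this: 962 of 1,000 simulated loci pass QC; the genome-wide temporal
F<sub>ST</sub> of ~0.022 corresponds to an effective size of ~349 (the
simulation ran at census 500 with ten planted sweeps, which drag the estimate
below census); the drift test flags 8 loci at q < 0.05 and the
heterozygosity-based test puts 14 beyond its 1% envelope — the planted sweeps
dominate both lists. `ss.cluster_snps` / `ss.classify_and_extend` then
assemble the flagged SNPs into extended candidate intervals, and
`ss.overlap_annotations` / `ss.fold_enrichment` / `ss.density_fold` compute
the annotation statistics.

A command-line interface mirrors the library
(`selfscan simulate | scan-drift | scan-fdist | cluster | annotate | climate |
pheno | run`); `selfscan run --config cfg.yaml` executes the whole pipeline
and writes TSVs, a BED of candidate loci and a run log.

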