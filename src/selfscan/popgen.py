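"""Genotype containers, locus filtering and the population-genetic statistics
shared by both genome scans.

Genotypes are dosage-coded: 0/1/2 copies of the alternate allele, -1 missing.
All positions are 1-based. Two temporal samples of the same population are
treated throughout as two "populations" in the Weir-Cockerham sense.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1


class EmptyOutputError(ValueError):
    """Raised when an operation would return zero loci."""


class NotEstimableError(ValueError):
    """Raised when a statistic cannot be estimated from the data given."""


@dataclass
class ParseReport:
    """What a reader or filter kept, dropped, and complained about."""

    n_samples: int = 0
    n_loci_read: int = 0
    n_loci_dropped: int = 0
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        if self.n_loci_dropped > self.n_loci_read:
            raise ValueError("n_loci_dropped cannot exceed n_loci_read")
        if min(self.n_samples, self.n_loci_read, self.n_loci_dropped) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class GenotypeMatrix:
    """Samples x loci dosage matrix with genomic coordinates.

    Parameters
    ----------
    genotypes : ndarray of int8, shape (n_samples, n_loci)
        Count of the alternate allele, ``MISSING`` (-1) for no-calls.
    chrom : ndarray of str, per locus
    pos : ndarray of int, 1-based positions
    sample_ids : list of str
    population_labels : optional per-sample labels
    """

    genotypes: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    sample_ids: list
    population_labels: np.ndarray | None = None

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x loci)")
        if self.genotypes.shape[1] != len(self.pos) or len(self.chrom) != len(self.pos):
            raise ValueError("locus annotation length mismatch")
        if len(self.sample_ids) != self.genotypes.shape[0]:
            raise ValueError("sample_ids length mismatch")
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosages must be in {0,1,2,missing}")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def sorted_by_position(self) -> "GenotypeMatrix":
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        return self.take_loci(order)

    def take_loci(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.genotypes[:, idx],
            self.chrom[idx],
            self.pos[idx],
            list(self.sample_ids),
            self.population_labels,
        )

    def genotype_counts(self) -> np.ndarray:
        """Per-locus (nAA, nAa, naa) counts; index 0 = hom-ref. Shape (n_loci, 3)."""
        g = self.genotypes
        return np.stack(
            [(g == 0).sum(axis=0), (g == 1).sum(axis=0), (g == 2).sum(axis=0)], axis=1
        ).astype(np.int64)

    def missing_fraction(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Per-locus alternate-allele frequency among callable genotypes (nan if none)."""
        g = self.genotypes.astype(float)
        g[g == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(g, axis=0) / 2.0


@dataclass
class TemporalSamplePair:
    """Two genotype samples of one population taken tau generations apart."""

    sample_t0: GenotypeMatrix
    sample_tau: GenotypeMatrix
    tau: int = 31
    truth: dict | None = None

    def __post_init__(self):
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.sample_t0.n_loci != self.sample_tau.n_loci:
            raise ValueError("samples must share the locus list")
        if not np.array_equal(self.sample_t0.pos, self.sample_tau.pos) or not np.array_equal(
            self.sample_t0.chrom, self.sample_tau.chrom
        ):
            raise ValueError("samples must share the locus list")

    @property
    def n_loci(self) -> int:
        return self.sample_t0.n_loci

    def take_loci(self, idx) -> "TemporalSamplePair":
        return TemporalSamplePair(
            self.sample_t0.take_loci(idx), self.sample_tau.take_loci(idx), self.tau, self.truth
        )


# ---------------------------------------------------------------------------
# locus filtering


def filter_loci(
    m: GenotypeMatrix,
    maf_min: float = 0.01,
    miss_max: float = 0.20,
    het_max: float = 0.05,
) -> tuple[GenotypeMatrix, ParseReport]:
    """Keep loci with MAF > maf_min, missing fraction < miss_max and
    heterozygote fraction < het_max (defaults are the GBS-panel thresholds).

    Order is preserved. Raises :class:`EmptyOutputError` if nothing survives.
    """
    for t in (maf_min, miss_max, het_max):
        if not 0.0 <= t <= 1.0:
            raise ValueError("thresholds must be in [0, 1]")
    p = m.allele_freq()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
    miss = m.missing_fraction()
    counts = m.genotype_counts()
    callable_ = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(callable_ > 0, counts[:, 1] / np.maximum(callable_, 1), 1.0)
    keep = (
        ~np.isnan(maf)
        & (maf > maf_min)
        & (miss < miss_max)
        & (het < het_max)
    )
    report = ParseReport(
        n_samples=m.n_samples,
        n_loci_read=m.n_loci,
        n_loci_dropped=int((~keep).sum()),
    )
    if not keep.any():
        raise EmptyOutputError("all loci removed by filtering")
    return m.take_loci(np.flatnonzero(keep)), report


def filter_pair(
    pair: TemporalSamplePair,
    maf_min: float = 0.01,
    miss_max: float = 0.20,
    het_max: float = 0.05,
) -> tuple[TemporalSamplePair, ParseReport]:
    """Apply the :func:`filter_loci` thresholds on the two samples pooled (the
    group level, not per collect, so loci that drifted far between the collects
    are not censored). The pair stays on one locus list."""
    pooled = GenotypeMatrix(
        np.vstack([pair.sample_t0.genotypes, pair.sample_tau.genotypes]),
        pair.sample_t0.chrom,
        pair.sample_t0.pos,
        list(pair.sample_t0.sample_ids) + list(pair.sample_tau.sample_ids),
    )
    p = pooled.allele_freq()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
    miss = pooled.missing_fraction()
    counts = pooled.genotype_counts()
    callable_ = counts.sum(axis=1)
    het = np.where(callable_ > 0, counts[:, 1] / np.maximum(callable_, 1), 1.0)
    keep = ~np.isnan(maf) & (maf > maf_min) & (miss < miss_max) & (het < het_max)
    report = ParseReport(
        n_samples=pooled.n_samples, n_loci_read=pair.n_loci, n_loci_dropped=int((~keep).sum())
    )
    if not keep.any():
        raise EmptyOutputError("all loci removed by filtering")
    return pair.take_loci(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# identity probabilities and the heterozygosity-based locus FST


def locus_summaries(pair: TemporalSamplePair) -> pd.DataFrame:
    """Per-locus gene-identity probabilities and the identity-based FST.

    f0 is the average probability that two distinct genes drawn within one
    temporal sample are identical (unbiased, i.e. without-replacement, within
    each sample, averaged over the two samples); f1 the probability that one
    gene from each sample is identical. The locus FST is (f0 - f1)/(1 - f1),
    undefined (NaN) where both samples are fixed for the same allele.

    Returns a DataFrame with columns chrom, pos, genotype counts per sample,
    f0_hat, f1_hat, h0_hat, h1_hat, fst_bn and fst_wc.
    """
    c0 = pair.sample_t0.genotype_counts().astype(float)
    c1 = pair.sample_tau.genotype_counts().astype(float)

    def identity_within(c):
        n_genes = 2.0 * c.sum(axis=1)
        x = 2.0 * c[:, 0] + c[:, 1]  # reference-allele gene count
        y = n_genes - x
        with np.errstate(invalid="ignore", divide="ignore"):
            f = (x * (x - 1) + y * (y - 1)) / (n_genes * (n_genes - 1))
        f[n_genes < 2] = np.nan
        return f

    def freqs(c):
        n_genes = 2.0 * c.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = (2.0 * c[:, 0] + c[:, 1]) / n_genes
        p[n_genes < 1] = np.nan
        return p

    f_within = np.nanmean(np.stack([identity_within(c0), identity_within(c1)]), axis=0)
    p0, p1 = freqs(c0), freqs(c1)
    f1 = p0 * p1 + (1 - p0) * (1 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst_bn = np.where(f1 < 1.0, (f_within - f1) / (1.0 - f1), np.nan)
    fst_wc, _ = fst_weir_cockerham(pair)
    return pd.DataFrame(
        {
            "chrom": pair.sample_t0.chrom,
            "pos": pair.sample_t0.pos,
            "n0_AA": c0[:, 0].astype(int),
            "n0_Aa": c0[:, 1].astype(int),
            "n0_aa": c0[:, 2].astype(int),
            "n1_AA": c1[:, 0].astype(int),
            "n1_Aa": c1[:, 1].astype(int),
            "n1_aa": c1[:, 2].astype(int),
            "f0_hat": f_within,
            "f1_hat": f1,
            "h0_hat": 1.0 - f_within,
            "h1_hat": 1.0 - f1,
            "fst_bn": fst_bn,
            "fst_wc": fst_wc,
        }
    )


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components (individual level, valid under inbreeding)


def wc_components_from_counts(counts1: np.ndarray, counts2: np.ndarray):
    """Weir-Cockerham (1984) variance components a, b, c for two populations
    from genotype counts.

    ``counts1``/``counts2`` are (..., 3) arrays of (hom-ref, het, hom-alt)
    counts. Returns arrays ``(a, b, c)`` with the leading shape; components are
    NaN where either population has fewer than two callable genotypes. ``a`` is
    the between-population component, ``b`` between individuals within
    populations, ``c`` within individuals; theta = a/(a+b+c).
    """
    c1 = np.asarray(counts1, dtype=float)
    c2 = np.asarray(counts2, dtype=float)
    squeeze = c1.ndim == 1
    if squeeze:
        c1 = c1[None, :]
        c2 = c2[None, :]
    n1 = c1.sum(axis=-1)
    n2 = c2.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = (2 * c1[..., 0] + c1[..., 1]) / (2 * n1)
        p2 = (2 * c2[..., 0] + c2[..., 1]) / (2 * n2)
        h1 = c1[..., 1] / n1
        h2 = c2[..., 1] / n2
        nbar = (n1 + n2) / 2.0
        nc = 2 * nbar - (n1**2 + n2**2) / (2 * nbar)
        pbar = (n1 * p1 + n2 * p2) / (2 * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar  # r-1 = 1
        hbar = (n1 * h1 + n2 * h2) / (2 * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 / 2.0 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 / 2.0 - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
    invalid = (n1 < 2) | (n2 < 2) | (nc <= 0)
    for arr in (a, b, c):
        arr[invalid] = np.nan
    if squeeze:
        return a[0], b[0], c[0]
    return a, b, c


def fst_weir_cockerham(pair: TemporalSamplePair) -> tuple[np.ndarray, float]:
    """Per-locus and global Weir-Cockerham FST between the two temporal samples.

    Per-locus theta = a/(a+b+c); negative values are retained. The global
    estimate is the ratio of summed components over all estimable loci (loci
    with zero total variance, i.e. monomorphic in both samples, contribute
    nothing and are NaN per locus).
    """
    a, b, c = wc_components_from_counts(
        pair.sample_t0.genotype_counts(), pair.sample_tau.genotype_counts()
    )
    tot = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = np.where(tot != 0, a / tot, np.nan)
    ok = np.isfinite(tot) & (tot != 0)
    if not ok.any():
        return per_locus, np.nan
    global_fst = float(a[ok].sum() / tot[ok].sum())
    return per_locus, global_fst


def multilocus_fis(pair: TemporalSamplePair) -> float:
    """Multilocus Weir-Cockerham inbreeding coefficient, both temporal samples
    pooled as two populations: FIS = 1 - sum(c)/sum(b + c) over polymorphic
    loci. Raises :class:`NotEstimableError` when no locus is informative."""
    a, b, c = wc_components_from_counts(
        pair.sample_t0.genotype_counts(), pair.sample_tau.genotype_counts()
    )
    bc = b + c
    ok = np.isfinite(bc) & (bc != 0)
    if not ok.any():
        raise NotEstimableError("no polymorphic loci: FIS not estimable")
    return float(1.0 - c[ok].sum() / bc[ok].sum())


# ---------------------------------------------------------------------------
# linkage disequilibrium


def ld_r2(m: GenotypeMatrix, locus_i: int, locus_j: int) -> float:
    """Composite LD: squared Pearson correlation of the two dosage vectors over
    pairwise-callable samples. NaN when either locus is monomorphic among the
    shared callable samples (undefined)."""
    gi = m.genotypes[:, locus_i].astype(float)
    gj = m.genotypes[:, locus_j].astype(float)
    ok = (gi != MISSING) & (gj != MISSING)
    gi, gj = gi[ok], gj[ok]
    if len(gi) < 2 or gi.std() == 0 or gj.std() == 0:
        return np.nan
    r = np.corrcoef(gi, gj)[0, 1]
    return float(r * r)


@dataclass
class LDProfile:
    """Mean/sd of r-squared by physical-distance class (kb)."""

    bin_edges: np.ndarray  # kb, length n_bins + 1
    mean_r2: np.ndarray
    sd_r2: np.ndarray
    n_pairs: np.ndarray

    def decay_distance(self, threshold: float = 0.2) -> float | None:
        """Left edge (kb) of the first occupied bin whose mean r2 drops below
        ``threshold``; None if LD never decays below it."""
        for k in range(len(self.mean_r2)):
            if self.n_pairs[k] > 0 and np.isfinite(self.mean_r2[k]) and self.mean_r2[k] < threshold:
                return float(self.bin_edges[k])
        return None

    @property
    def initial_ld(self) -> float:
        """Mean r2 of the sub-25 kb class (the first bin)."""
        return float(self.mean_r2[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_kb": self.bin_edges[:-1],
                "bin_end_kb": self.bin_edges[1:],
                "mean_r2": self.mean_r2,
                "sd_r2": self.sd_r2,
                "n_pairs": self.n_pairs,
            }
        )


def ld_decay_profile(
    m: GenotypeMatrix, bin_width_kb: float = 50.0, max_dist_kb: float = 3000.0
) -> LDProfile:
    """r-squared against pairwise distance, within chromosomes, averaged by
    distance class. The first class is the sub-25 kb "initial LD" bin; the
    remaining classes are ``bin_width_kb`` wide."""
    edges = np.concatenate([[0.0, 25.0], np.arange(25.0 + bin_width_kb, max_dist_kb + bin_width_kb, bin_width_kb)])
    nb = len(edges) - 1
    sums = np.zeros(nb)
    sqs = np.zeros(nb)
    cnt = np.zeros(nb, dtype=np.int64)
    g = m.genotypes.astype(float)
    g[g == MISSING] = np.nan
    for ch in pd.unique(m.chrom.astype(str)):
        idx = np.flatnonzero(m.chrom.astype(str) == ch)
        if len(idx) < 2:
            continue
        sub = g[:, idx]
        dfm = pd.DataFrame(sub)
        r = dfm.corr(min_periods=2).to_numpy()  # pairwise-complete Pearson
        r2 = r * r
        pos_kb = m.pos[idx] / 1000.0
        iu, ju = np.triu_indices(len(idx), k=1)
        d = np.abs(pos_kb[ju] - pos_kb[iu])
        v = r2[iu, ju]
        ok = np.isfinite(v) & (d < max_dist_kb)
        which = np.digitize(d[ok], edges) - 1
        np.add.at(sums, which, v[ok])
        np.add.at(sqs, which, v[ok] ** 2)
        np.add.at(cnt, which, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, sums / np.maximum(cnt, 1), np.nan)
        var = np.where(cnt > 1, sqs / np.maximum(cnt, 1) - mean**2, np.nan)
        sd = np.sqrt(np.clip(var, 0, None))
    return LDProfile(bin_edges=edges, mean_r2=mean, sd_r2=sd, n_pairs=cnt)
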