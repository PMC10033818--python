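"""Forward simulation of a partially selfing population sampled at two times,
plus matching synthetic climate and phenotype series.

The genotype generator is an individual-based Wright-Fisher model with partial
self-fertilisation and optional fertility selection; it emulates the
statistical structure of a GBS SNP panel from a highly homozygous landrace
population (observed heterozygosity of a percent or two) sampled roughly a
generation apart per year over three decades.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .popgen import GenotypeMatrix, TemporalSamplePair

#: IRGSP-1.0 rice chromosome lengths (bp), used to place synthetic loci and to
#: clip extended intervals.
IRGSP_CHROM_LENGTHS = {
    "chr01": 43_270_923,
    "chr02": 35_937_250,
    "chr03": 36_413_819,
    "chr04": 35_502_694,
    "chr05": 29_958_434,
    "chr06": 31_248_787,
    "chr07": 29_697_621,
    "chr08": 28_443_022,
    "chr09": 23_012_720,
    "chr10": 23_207_287,
    "chr11": 29_021_106,
    "chr12": 27_531_856,
}


@dataclass
class SimConfig:
    """Study conditions for the temporal-population generator.

    Defaults follow the sampled system: a selfing rate of 0.95 (rice
    outcrossing is at most a few percent), tau = 31 generations between
    collects, and a U-shaped initial allele-frequency distribution truncated at
    MAF 0.01 as in a MAF-filtered GBS panel.
    """

    n_loci: int = 1000
    ne: int = 500
    selfing_rate: float = 0.95
    tau: int = 31
    n0: int = 100
    n_tau: int = 100
    selected: tuple = ()
    sel_coef: float = 0.0
    sel_init_freq: tuple | None = (0.5, 0.8)
    maf_init: float = 0.01
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.selfing_rate <= 1.0:
            raise ValueError("selfing_rate must be in [0, 1]")
        if self.sel_coef < 0:
            raise ValueError("sel_coef must be >= 0")
        if self.ne < 2:
            raise ValueError("ne must be >= 2")
        if any(i < 0 or i >= self.n_loci for i in self.selected):
            raise ValueError("selected indices out of range")
        if max(self.n0, self.n_tau) > self.ne:
            raise ValueError("sample sizes cannot exceed the population size")


def _positions(n_loci: int, rng: np.random.Generator):
    """Spread loci over the 12 rice chromosomes proportionally to length, at
    sorted uniform positions."""
    chroms = list(IRGSP_CHROM_LENGTHS)
    lens = np.array([IRGSP_CHROM_LENGTHS[c] for c in chroms], dtype=float)
    n_per = np.maximum(1, np.round(n_loci * lens / lens.sum()).astype(int))
    while n_per.sum() > n_loci:
        n_per[np.argmax(n_per)] -= 1
    while n_per.sum() < n_loci:
        n_per[np.argmax(lens)] += 1
    chrom_out, pos_out = [], []
    for c, n, ln in zip(chroms, n_per, lens):
        p = np.sort(rng.choice(int(ln) - 1, size=n, replace=False) + 1)
        chrom_out.extend([c] * n)
        pos_out.extend(p.tolist())
    return np.array(chrom_out, dtype=object), np.array(pos_out, dtype=np.int64)


def _next_generation(geno, sel_mask, sel_coef, selfing_rate, rng):
    """One generation of reproduction: fertility selection, partial selfing,
    Mendelian gamete segregation. ``geno`` is (N, L) int8 dosages."""
    n = geno.shape[0]
    if sel_coef > 0 and sel_mask.any():
        w = (1.0 + sel_coef) ** geno[:, sel_mask].sum(axis=1).astype(float)
        w /= w.sum()
    else:
        w = None
    p1 = rng.choice(n, size=n, replace=True, p=w)
    p2 = rng.choice(n, size=n, replace=True, p=w)
    self_mask = rng.random(n) < selfing_rate
    p2[self_mask] = p1[self_mask]

    def gamete(parent_idx):
        g = geno[parent_idx]
        out = (g // 2).astype(np.int8)  # 0->0, 2->1
        het = g == 1
        out[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
        return out

    return gamete(p1) + gamete(p2)


def simulate_temporal_population(config: SimConfig) -> TemporalSamplePair:
    """Simulate the population forward and return samples at generations 0 and
    tau, with the ground truth (selected set, allele-frequency trajectories)
    attached for power/calibration testing."""
    rng = np.random.default_rng(config.seed)
    n, L = config.ne, config.n_loci

    # initial frequencies: U-shaped Beta(0.5, 0.5) truncated at the MAF filter
    p = rng.beta(0.5, 0.5, size=L)
    while True:
        bad = np.minimum(p, 1 - p) <= config.maf_init
        if not bad.any():
            break
        p[bad] = rng.beta(0.5, 0.5, size=int(bad.sum()))
    if config.selected and config.sel_init_freq is not None:
        # selected loci start as common standing variants: directional
        # selection then drives them toward fixation and heterozygosity at
        # those loci falls, without leaving the heterozygosity range a
        # neutral null spans (a sweep from a rare allele ends with the two
        # samples near-fixed for opposite alleles, outside any neutral cloud)
        lo, hi = config.sel_init_freq
        p[list(config.selected)] = rng.uniform(lo, hi, size=len(config.selected))

    # genotypes at inbreeding equilibrium for the selfing rate
    s = config.selfing_rate
    f_eq = s / (2.0 - s) if s < 1 else 1.0
    g_aa = p**2 + f_eq * p * (1 - p)
    g_ab = 2 * p * (1 - p) * (1 - f_eq)
    u = rng.random((n, L))
    geno = np.where(u < g_aa, 2, np.where(u < g_aa + g_ab, 1, 0)).astype(np.int8)

    sel_mask = np.zeros(L, dtype=bool)
    sel_mask[list(config.selected)] = True

    sample0_idx = rng.choice(n, size=config.n0, replace=False)
    sample0 = geno[sample0_idx].copy()

    traj = np.empty((config.tau + 1, L), dtype=np.float32)
    traj[0] = geno.mean(axis=0) / 2.0
    for t in range(1, config.tau + 1):
        geno = _next_generation(geno, sel_mask, config.sel_coef, s, rng)
        traj[t] = geno.mean(axis=0) / 2.0

    sample_tau_idx = rng.choice(n, size=config.n_tau, replace=False)
    sample_tau = geno[sample_tau_idx].copy()

    chrom, pos = _positions(L, rng)
    ids0 = [f"t0_{i:04d}" for i in range(config.n0)]
    ids1 = [f"t{config.tau}_{i:04d}" for i in range(config.n_tau)]
    m0 = GenotypeMatrix(sample0, chrom, pos, ids0)
    m1 = GenotypeMatrix(sample_tau, chrom, pos, ids1)
    truth = {
        "selected": tuple(config.selected),
        "sel_coef": config.sel_coef,
        "trajectories": traj,
        "config": config,
    }
    return TemporalSamplePair(m0.sorted_by_position(), m1.sorted_by_position(), config.tau, truth)


def linked_dosage_matrix(
    n_samples: int,
    n_loci: int,
    spacing_bp: int = 10_000,
    decay_bp: float = 100_000.0,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Haploid-like dosage matrix (0/2) with LD decaying exponentially with
    distance, for LD-profile testing.

    Each sample is a pair of identical haplotypes (fully homozygous, as in a
    complete selfer) built by a Markov copying process along one chromosome:
    the allele is redrawn (Bernoulli 0.5) between adjacent loci with
    probability 1 - exp(-spacing/decay), which gives
    r^2(d) ~ exp(-2 d / decay_bp); the half-decay distance of r^2 is
    decay_bp * ln(2) / 2.
    """
    rng = np.random.default_rng(seed)
    switch = 1.0 - np.exp(-spacing_bp / decay_bp)
    hap = np.empty((n_samples, n_loci), dtype=np.int8)
    hap[:, 0] = rng.integers(0, 2, size=n_samples)
    for j in range(1, n_loci):
        redraw = rng.random(n_samples) < switch
        hap[:, j] = np.where(redraw, rng.integers(0, 2, size=n_samples), hap[:, j - 1])
    pos = np.arange(1, n_loci + 1, dtype=np.int64) * spacing_bp
    chrom = np.array(["chr01"] * n_loci, dtype=object)
    ids = [f"s{i:03d}" for i in range(n_samples)]
    return GenotypeMatrix(2 * hap, chrom, pos, ids)


# ---------------------------------------------------------------------------
# climate and phenotype generators

#: Monthly rainfall profile (mm) shaped like a West-African monomodal monsoon:
#: dry Nov-Apr, wet Jun-Oct peak in Aug.
RAIN_PROFILE = np.array([5, 10, 40, 90, 160, 220, 280, 330, 300, 180, 40, 10], dtype=float)

#: Monthly mean temperature profile (deg C), mild seasonal cycle.
TEMP_PROFILE = np.array(
    [24.5, 26.0, 27.5, 27.5, 26.5, 25.5, 24.5, 24.5, 25.0, 25.5, 25.0, 24.0]
)


def simulate_climate_series(
    years=range(1961, 2011),
    variable: str = "rain",
    trend_per_decade: float = 0.0,
    sd: float = 0.0,
    seed: int | None = None,
    station: str = "synthetic",
):
    """Monthly climate grid = seasonal profile + linear trend + Gaussian noise.

    Returns a :class:`~selfscan.climate.ClimateSeries`. The trend is applied
    uniformly to every month, anchored at the first year.
    """
    from .climate import ClimateSeries

    years = list(years)
    if not years:
        raise ValueError("year range must be non-empty")
    rng = np.random.default_rng(seed)
    profile = RAIN_PROFILE if variable == "rain" else TEMP_PROFILE
    rows = []
    for y in years:
        drift = trend_per_decade * (y - years[0]) / 10.0
        vals = profile + drift + rng.normal(0.0, sd, size=12)
        if variable == "rain":
            vals = np.clip(vals, 0.0, None)
        rows.append(vals)
    grid = pd.DataFrame(rows, index=pd.Index(years, name="year"), columns=range(1, 13))
    return ClimateSeries(station=station, variable=variable, values=grid)


#: Group x collect mean days-to-heading (days) emulating the phenotype table:
#: group means ~145/115/106 d for Og/Osi/Osj; Og advances 10.3 d, Osj 3.4 d,
#: Osi lengthens 4.3 d between collects.
DTHD_MEANS = {
    ("Og", 1): 150.15,
    ("Og", 2): 139.85,
    ("Osj", 1): 107.7,
    ("Osj", 2): 104.3,
    ("Osi", 1): 114.67,
    ("Osi", 2): 118.94,
}

#: Accessions phenotyped per group and collect.
DTHD_N = {
    ("Og", 1): 59,
    ("Og", 2): 85,
    ("Osj", 1): 107,
    ("Osj", 2): 147,
    ("Osi", 1): 73,
    ("Osi", 2): 180,
}


def simulate_phenotypes(
    n_per_group: dict | None = None,
    means: dict | None = None,
    sd: float = 12.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Gaussian days-to-heading records with programmed group x collect means.

    Returns a DataFrame with columns accession, group, collect, dthd.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    n_per_group = dict(DTHD_N if n_per_group is None else n_per_group)
    means = dict(DTHD_MEANS if means is None else means)
    rng = np.random.default_rng(seed)
    rows = []
    for (group, collect), n in sorted(n_per_group.items()):
        mu = means[(group, collect)]
        vals = rng.normal(mu, sd, size=n)
        vals = np.clip(vals, 1.0, None)  # dthd > 0 by construction
        for i, v in enumerate(vals):
            rows.append(
                {
                    "accession": f"{group}{collect}_{i:03d}",
                    "group": group,
                    "collect": collect,
                    "dthd": float(v),
                }
            )
    return pd.DataFrame(rows)
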