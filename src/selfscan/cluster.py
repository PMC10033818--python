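"""Aggregation of significant SNPs into independent loci under selection
(ILUS), merging across genetic groups, M1/M2 classification and interval
extension for annotation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import IRGSP_CHROM_LENGTHS


@dataclass
class IndependentLocus:
    """A run of adjacent significant SNPs treated as one selection signal.

    ``member_snps`` is a list of dicts with keys pos, p_drift, p_fdist,
    sig_drift, sig_fdist; ``type`` is M2 when at least one member is
    significant under both detection methods, else M1.
    """

    chrom: str
    start: int
    end: int
    member_snps: list
    groups: set = field(default_factory=set)
    type: str | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("start must be <= end")
        self.member_snps = sorted(self.member_snps, key=lambda s: s["pos"])

    @property
    def n_snp(self) -> int:
        return len(self.member_snps)

    def _any_both_methods(self) -> bool:
        return any(s.get("sig_drift") and s.get("sig_fdist") for s in self.member_snps)

    def _any_single_method(self) -> bool:
        return any(bool(s.get("sig_drift")) != bool(s.get("sig_fdist")) for s in self.member_snps)


def cluster_snps(
    sig_snps: pd.DataFrame,
    r2,
    max_gap_kb: float = 250.0,
    r2_min: float = 0.2,
    group: str | None = None,
    rule: str = "and",
) -> list[IndependentLocus]:
    """Chain significant SNPs into independent loci.

    Adjacent SNPs (sorted by chrom, pos) are joined into the same locus when
    their distance is below ``max_gap_kb`` AND their LD exceeds ``r2_min``
    (single linkage on adjacent pairs; ``rule='or'`` relaxes to either
    condition). ``r2`` is an accessor ``r2(chrom, pos_i, pos_j) -> float``.
    ``sig_snps`` needs columns chrom, pos and (optionally) p_drift, p_fdist,
    sig_drift, sig_fdist.
    """
    if rule not in ("and", "or"):
        raise ValueError("rule must be 'and' or 'or'")
    df = sig_snps.sort_values(["chrom", "pos"]).reset_index(drop=True)
    loci: list[IndependentLocus] = []
    members: list[dict] = []

    def flush():
        if members:
            loci.append(
                IndependentLocus(
                    chrom=members[0]["chrom"],
                    start=members[0]["pos"],
                    end=members[-1]["pos"],
                    member_snps=[{k: v for k, v in m.items() if k != "chrom"} for m in members],
                    groups={group} if group else set(),
                )
            )

    prev = None
    for _, row in df.iterrows():
        snp = {
            "chrom": row["chrom"],
            "pos": int(row["pos"]),
            "p_drift": row.get("p_drift", np.nan),
            "p_fdist": row.get("p_fdist", np.nan),
            "sig_drift": bool(row.get("sig_drift", False)),
            "sig_fdist": bool(row.get("sig_fdist", False)),
        }
        if prev is not None and snp["chrom"] == prev["chrom"]:
            near = (snp["pos"] - prev["pos"]) / 1000.0 < max_gap_kb
            linked = False
            if near or rule == "or":
                v = r2(snp["chrom"], prev["pos"], snp["pos"])
                linked = np.isfinite(v) and v > r2_min
            joined = (near and linked) if rule == "and" else (near or linked)
        else:
            joined = False
        if not joined:
            flush()
            members = []
        members.append(snp)
        prev = snp
    flush()
    return loci


def merge_loci_groups(
    loci_a: list[IndependentLocus],
    loci_b: list[IndependentLocus],
    max_gap_kb: float = 250.0,
) -> list[IndependentLocus]:
    """Merge loci from two genetic groups whose component SNPs lie within
    ``max_gap_kb`` of each other on the same chromosome (transitive closure, so
    chains of nearby loci collapse into one)."""
    all_loci = list(loci_a) + list(loci_b)
    n = len(all_loci)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        for j in range(i + 1, n):
            a, b = all_loci[i], all_loci[j]
            if a.chrom != b.chrom:
                continue
            dmin = min(
                abs(sa["pos"] - sb["pos"]) for sa in a.member_snps for sb in b.member_snps
            )
            if dmin / 1000.0 < max_gap_kb:
                union(i, j)

    clusters: dict[int, list[IndependentLocus]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(all_loci[i])
    merged = []
    for group_members in clusters.values():
        snps = [dict(s) for loc in group_members for s in loc.member_snps]
        groups = set().union(*(loc.groups for loc in group_members))
        merged.append(
            IndependentLocus(
                chrom=group_members[0].chrom,
                start=min(loc.start for loc in group_members),
                end=max(loc.end for loc in group_members),
                member_snps=snps,
                groups=groups,
            )
        )
    merged.sort(key=lambda L: (L.chrom, L.start))
    return merged


def classify_and_extend(
    loci: list[IndependentLocus],
    flank_kb: float = 250.0,
    drop_singletons_single_method: bool = True,
    chrom_lengths: dict | None = None,
) -> list[IndependentLocus]:
    """Classify loci as M2 (at least one member SNP significant under both
    detection methods) or M1, optionally discard single-SNP loci supported by
    one method only, and extend each retained interval by ``flank_kb`` on both
    sides (clipped to [1, chromosome end])."""
    chrom_lengths = IRGSP_CHROM_LENGTHS if chrom_lengths is None else chrom_lengths
    out = []
    flank = int(round(flank_kb * 1000))
    for loc in loci:
        both = loc._any_both_methods()
        if drop_singletons_single_method and loc.n_snp == 1 and not both:
            continue
        if loc.chrom not in chrom_lengths:
            raise KeyError(f"no chromosome length for {loc.chrom}")
        new = IndependentLocus(
            chrom=loc.chrom,
            start=max(1, loc.start - flank),
            end=min(int(chrom_lengths[loc.chrom]), loc.end + flank),
            member_snps=[dict(s) for s in loc.member_snps],
            groups=set(loc.groups),
            type="M2" if both else "M1",
        )
        out.append(new)
    return out


def loci_to_frame(loci: list[IndependentLocus]) -> pd.DataFrame:
    """Tabular view mirroring the candidate-locus table: number, type, n SNP,
    chromosome, start, end, groups."""
    rows = []
    for i, loc in enumerate(sorted(loci, key=lambda L: (L.chrom, L.start)), start=1):
        rows.append(
            {
                "n": i,
                "type": loc.type or "",
                "n_snp": loc.n_snp,
                "chrom": loc.chrom,
                "start": loc.start,
                "end": loc.end,
                "groups": ",".join(sorted(loc.groups)),
            }
        )
    return pd.DataFrame(rows)


def loci_to_bed(loci: list[IndependentLocus], path) -> None:
    """Write loci as BED (0-based half-open)."""
    df = loci_to_frame(loci)
    with open(path, "w") as fh:
        for _, r in df.iterrows():
            name = f"ILUS_{r['n']}_{r['type'] or 'NA'}"
            fh.write(f"{r['chrom']}\t{r['start'] - 1}\t{r['end']}\t{name}\n")
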