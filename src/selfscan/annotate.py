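"""Overlap of candidate intervals with gene/QTL annotations and the
fold-enrichment arithmetic for annotation-term and QTL-density statistics.

All coordinates are 1-based, closed intervals (the RAP-DB convention); BED
inputs are converted on read by :mod:`selfscan.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


@dataclass
class AnnotationRecord:
    chrom: str
    start: int
    end: int
    id: str
    kind: str = "gene"
    tags: tuple = ()

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"record {self.id}: start > end")


@dataclass
class EnrichmentResult:
    """Observed vs expected annotation counts and their ratio."""

    obs: int
    exp: float
    fold: float
    ref_total: int
    input_total: int
    term_ref: int
    p_hypergeom: float | None = None


def overlap_annotations(intervals, annot: list[AnnotationRecord]):
    """Count annotation records overlapping each interval (closed intervals;
    touching endpoints count). Returns (per_interval, total) where
    ``per_interval`` is a list of record-id lists aligned with ``intervals``
    and ``total`` is the number of distinct record ids hit by any interval
    (records shared between overlapping intervals are not double-counted).

    ``intervals`` is any iterable of objects with chrom/start/end attributes
    (e.g. :class:`~selfscan.cluster.IndependentLocus`).
    """
    per_interval = []
    seen: set = set()
    for iv in intervals:
        hits = [
            rec.id
            for rec in annot
            if rec.chrom == iv.chrom and rec.start <= iv.end and rec.end >= iv.start
        ]
        per_interval.append(hits)
        seen.update(hits)
    return per_interval, len(seen)


def fold_enrichment(
    obs: int, term_ref: int, input_total: int, ref_total: int, with_p: bool = False
) -> EnrichmentResult:
    """Annotation-term fold enrichment: exp = input_total * term_ref /
    ref_total, fold = obs / exp. A hypergeometric upper-tail p-value is
    attached when ``with_p`` is set."""
    if min(obs, term_ref, input_total, ref_total) <= 0:
        raise ValueError("all counts must be positive")
    if obs > input_total or term_ref > ref_total:
        raise ValueError("observed counts exceed their totals")
    exp = input_total * term_ref / ref_total
    if exp == 0:
        raise ValueError("expected count is zero")
    p = float(hypergeom.sf(obs - 1, ref_total, term_ref, input_total)) if with_p else None
    return EnrichmentResult(
        obs=obs,
        exp=exp,
        fold=obs / exp,
        ref_total=ref_total,
        input_total=input_total,
        term_ref=term_ref,
        p_hypergeom=p,
    )


def density_fold(
    n_features: int, segment_len_mb: float, expected_density_mb_per_feature: float
) -> tuple[float, float]:
    """Feature-density enrichment of a genomic segment.

    Returns ``(density_mb_per_feature, fold)`` where the fold is the observed
    per-Mb density relative to the genome-wide expectation expressed as Mb per
    feature (e.g. one QTL every 0.62 Mb)."""
    if segment_len_mb <= 0:
        raise ValueError("segment length must be positive")
    if n_features <= 0 or expected_density_mb_per_feature <= 0:
        raise ValueError("inputs must be positive")
    density = segment_len_mb / n_features
    fold = (n_features / segment_len_mb) * expected_density_mb_per_feature
    return density, fold


def enrichment_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble term/obs/exp/fold rows into a table (term, obs, exp, fold,
    p_hypergeom)."""
    out = []
    for r in rows:
        res = fold_enrichment(
            r["obs"], r["term_ref"], r["input_total"], r["ref_total"], with_p=True
        )
        out.append(
            {
                "term": r.get("term", ""),
                "obs": res.obs,
                "exp": round(res.exp, 2),
                "fold": round(res.fold, 2),
                "p_hypergeom": res.p_hypergeom,
            }
        )
    return pd.DataFrame(out)
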