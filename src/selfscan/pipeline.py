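"""End-to-end orchestration: filter -> descriptive statistics -> both outlier
scans -> independent-locus construction -> annotation overlap, with all tables
written as TSV and a run log recording every threshold applied."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .cluster import classify_and_extend, cluster_snps, loci_to_bed, loci_to_frame
from .drift import DriftScanConfig, TemporalDriftScan
from .fdist import FdistScan, IslandModelConfig
from .popgen import GenotypeMatrix, TemporalSamplePair, filter_pair, ld_decay_profile, locus_summaries, multilocus_fis

logger = logging.getLogger("selfscan")


@dataclass
class PipelineConfig:
    """Flat configuration for a full scan run. Any field can be overridden by a
    CLI flag; unspecified paths switch the corresponding stage off."""

    genotypes_t0: str | None = None
    genotypes_tau: str | None = None
    genotype_format: str = "hapmap"
    annotations: str | None = None
    out_dir: str = "selfscan_out"
    seed: int = 0
    tau: int = 31
    maf_min: float = 0.01
    miss_max: float = 0.20
    het_max: float = 0.05
    drift_n_sim: int = 1000
    fdist_n_sim: int = 5000
    k_groups: int = 50
    d_demes: int = 10
    cluster_gap_kb: float = 250.0
    cluster_r2_min: float = 0.2
    flank_kb: float = 250.0
    group_label: str = "sim"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Flat key/value text file (YAML mapping of scalars)."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def pooled_r2_accessor(pair: TemporalSamplePair):
    """LD accessor over both samples pooled: r2(chrom, pos_i, pos_j)."""
    from .popgen import ld_r2

    pooled = GenotypeMatrix(
        np.vstack([pair.sample_t0.genotypes, pair.sample_tau.genotypes]),
        pair.sample_t0.chrom,
        pair.sample_t0.pos,
        list(pair.sample_t0.sample_ids) + list(pair.sample_tau.sample_ids),
    )
    index = {(str(c), int(p)): i for i, (c, p) in enumerate(zip(pooled.chrom, pooled.pos))}

    def accessor(chrom, pos_i, pos_j):
        return ld_r2(pooled, index[(str(chrom), int(pos_i))], index[(str(chrom), int(pos_j))])

    return accessor


def significant_snp_table(drift_res, fdist_res) -> pd.DataFrame:
    """Join the two scans on (chrom, pos) and keep SNPs significant under at
    least one method (drift: q below threshold; fdist: beyond the 5% limits)."""
    d = drift_res.table.rename(columns={"p": "p_drift", "q": "q_drift"})
    f = fdist_res.table.rename(columns={"p": "p_fdist", "class": "class_fdist"})
    merged = d.merge(f[["chrom", "pos", "p_fdist", "class_fdist"]], on=["chrom", "pos"])
    merged["sig_drift"] = merged["class"] == "sig"
    merged["sig_fdist"] = merged["class_fdist"].isin(["sig1", "sig5"])
    return merged[merged["sig_drift"] | merged["sig_fdist"]][
        ["chrom", "pos", "p_drift", "p_fdist", "sig_drift", "sig_fdist"]
    ].reset_index(drop=True)


def run_full_scan(pair: TemporalSamplePair, config: PipelineConfig) -> dict:
    """Run the whole analysis on a temporal sample pair and write outputs to
    ``config.out_dir``. Returns a report dict with the fitted results and the
    paths written."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    logger.info(
        "thresholds: maf>%g miss<%g het<%g | tau=%d drift_n_sim=%d fdist_n_sim=%d "
        "k=%d d=%d gap<%gkb r2>%g flank=%gkb seed=%d",
        config.maf_min, config.miss_max, config.het_max, config.tau,
        config.drift_n_sim, config.fdist_n_sim, config.k_groups, config.d_demes,
        config.cluster_gap_kb, config.cluster_r2_min, config.flank_kb, config.seed,
    )

    stage = "filter"
    try:
        fpair, freport = filter_pair(pair, config.maf_min, config.miss_max, config.het_max)
        logger.info("filter: %d loci kept of %d", fpair.n_loci, freport.n_loci_read)

        stage = "descriptive"
        summaries = locus_summaries(fpair)
        fis = multilocus_fis(fpair)
        ld = ld_decay_profile(fpair.sample_t0)

        stage = "drift_scan"
        drift_res = TemporalDriftScan(
            fpair, DriftScanConfig(tau=config.tau, n_sim=config.drift_n_sim, seed=config.seed)
        ).fit()
        logger.info("drift scan: Ne=%.1f, %d outliers", drift_res.ne_hat, len(drift_res.significant))

        stage = "fdist_scan"
        fdist_res = FdistScan(
            fpair,
            IslandModelConfig(
                k_groups=config.k_groups, d_demes=config.d_demes,
                n_sim=config.fdist_n_sim, seed=config.seed + 1,
            ),
        ).fit()
        logger.info("fdist scan: %d outliers", len(fdist_res.significant))

        stage = "cluster"
        sig = significant_snp_table(drift_res, fdist_res)
        loci = cluster_snps(
            sig, pooled_r2_accessor(fpair),
            max_gap_kb=config.cluster_gap_kb, r2_min=config.cluster_r2_min,
            group=config.group_label,
        )
        ilus = classify_and_extend(loci, flank_kb=config.flank_kb)

        stage = "annotate"
        annot_table = None
        if config.annotations:
            records, _ = io_formats.read_annotation_table(config.annotations)
            per_interval, total = io_formats_overlap(ilus, records)
            annot_table = pd.DataFrame(
                {
                    "locus": range(1, len(ilus) + 1),
                    "n_hits": [len(h) for h in per_interval],
                    "hits": [",".join(h) for h in per_interval],
                }
            )
            annot_table.attrs["total_distinct"] = total

        stage = "write"
        io_formats.write_scan_results(drift_res.table, out / "drift_scan.tsv")
        io_formats.write_scan_results(
            fdist_res.table.assign(q=np.nan), out / "fdist_scan.tsv"
        )
        summaries.to_csv(out / "locus_summaries.tsv", sep="\t", index=False, float_format="%.6g")
        ld.to_frame().to_csv(out / "ld_profile.tsv", sep="\t", index=False, float_format="%.6g")
        fdist_res.cloud.to_frame().to_csv(out / "null_cloud.tsv", sep="\t", index=False, float_format="%.6g")
        env_rows = []
        for env in (fdist_res.envelope_99, fdist_res.envelope_95):
            for c, q in zip(env.bin_centers, env.quantile):
                env_rows.append({"alpha": env.alpha, "h1_bin_center": c, "fst_quantile": q})
        pd.DataFrame(env_rows).to_csv(out / "envelopes.tsv", sep="\t", index=False, float_format="%.6g")
        try:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            ax = fdist_res.plot()
            ax.figure.savefig(out / "fdist_joint.png", dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
        except Exception as exc:  # plotting must never sink a finished scan
            logger.warning("joint plot skipped: %s", exc)
        loci_frame = loci_to_frame(ilus)
        loci_frame.to_csv(out / "independent_loci.tsv", sep="\t", index=False)
        loci_to_bed(ilus, out / "independent_loci.bed")
        if annot_table is not None:
            annot_table.to_csv(out / "annotation_overlap.tsv", sep="\t", index=False)
        with open(out / "run_log.txt", "w") as fh:
            fh.write(drift_res.summary() + "\n\n" + fdist_res.summary() + "\n")
            fh.write(f"\nmultilocus FIS: {fis:.4f}\n")
            fh.write(f"independent loci: {len(ilus)}\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    return {
        "pair": fpair,
        "filter_report": freport,
        "fis": fis,
        "ld_profile": ld,
        "drift": drift_res,
        "fdist": fdist_res,
        "ilus": ilus,
        "annotation": annot_table,
        "out_dir": str(out),
    }


def io_formats_overlap(ilus, records):
    from .annotate import overlap_annotations

    return overlap_annotations(ilus, records)
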