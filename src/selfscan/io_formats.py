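"""Readers and writers for the file formats the pipeline touches: HapMap
tabular genotypes, VCF, BED / 1-based annotation tables and TSV result files.

Everything internal is 1-based, closed intervals; dosages count the alternate
allele with -1 for missing. Multi-allelic and indel records are dropped and
counted in the accompanying :class:`~selfscan.popgen.ParseReport`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotate import AnnotationRecord
from .popgen import MISSING, EmptyOutputError, GenotypeMatrix, ParseReport

HAPMAP_COLUMNS = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]

_IUPAC_HET = {"R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
              "K": {"G", "T"}, "M": {"A", "C"}}
_MISSING_CODES = {"N", "NN", "--", "-", "./.", ""}


class FormatError(ValueError):
    """Malformed input file."""


def _decode_hapmap_genotype(code: str, ref: str, alt: str) -> int:
    """IUPAC or two-letter genotype -> alt-allele dosage (missing on anything
    not matching the declared alleles)."""
    code = code.strip().upper()
    if code in _MISSING_CODES:
        return MISSING
    if len(code) == 1:
        if code == ref:
            return 0
        if code == alt:
            return 2
        if code in _IUPAC_HET and _IUPAC_HET[code] == {ref, alt}:
            return 1
        return MISSING
    if len(code) == 2:
        a, b = code[0], code[1]
        if {a, b} - {ref, alt}:
            return MISSING
        return int(a == alt) + int(b == alt)
    return MISSING


def read_genotypes(path, format: str = "hapmap") -> tuple[GenotypeMatrix, ParseReport]:
    """Read a genotype matrix from HapMap or VCF.

    Returns the matrix (loci sorted by chrom, pos; dosage-coded) and a parse
    report counting multi-allelic/indel records dropped. Raises
    :class:`FormatError` on a malformed header and
    :class:`~selfscan.popgen.EmptyOutputError` when no locus parses.
    """
    if format == "hapmap":
        return _read_hapmap(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError("format must be 'hapmap' or 'vcf'")


def _read_hapmap(path):
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:11]) != HAPMAP_COLUMNS:
        raise FormatError(
            f"{path}: not a HapMap table (expected leading columns {HAPMAP_COLUMNS})"
        )
    samples = list(df.columns[11:])
    if not samples:
        raise FormatError(f"{path}: no sample columns")
    warnings: list[str] = []
    keep_rows, chroms, poss = [], [], []
    dosages = []
    n_unmatched = 0
    for i, row in df.iterrows():
        alleles = str(row["alleles"]).split("/")
        if len(alleles) != 2 or any(len(a) != 1 or a not in "ACGT" for a in alleles):
            continue  # multi-allelic or indel
        ref, alt = alleles
        calls = [ _decode_hapmap_genotype(str(row[s]), ref, alt) for s in samples ]
        raw = [str(row[s]).strip().upper() for s in samples]
        n_unmatched += sum(
            1 for c, r in zip(calls, raw) if c == MISSING and r not in _MISSING_CODES
        )
        keep_rows.append(i)
        chroms.append(str(row["chrom"]))
        poss.append(int(row["pos"]))
        dosages.append(calls)
    n_read = len(df)
    n_dropped = n_read - len(keep_rows)
    if n_unmatched:
        warnings.append(f"{n_unmatched} genotype codes did not match the declared alleles; set missing")
    if not keep_rows:
        raise EmptyOutputError(f"{path}: zero parsable loci")
    m = GenotypeMatrix(
        np.array(dosages, dtype=np.int8).T,
        np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64),
        samples,
    ).sorted_by_position()
    return m, ParseReport(len(samples), n_read, n_dropped, warnings)


def _read_vcf(path):
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises plain Exceptions on bad headers
        raise FormatError(f"{path}: {exc}") from exc
    samples = list(vcf.samples)
    chroms, poss, dosages = [], [], []
    n_read = n_dropped = 0
    for v in vcf:
        n_read += 1
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_dropped += 1
            continue
        # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.asarray(v.gt_types)
        dos = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        chroms.append(v.CHROM)
        poss.append(v.POS)
        dosages.append(dos.astype(np.int8))
    if not dosages:
        raise EmptyOutputError(f"{path}: zero parsable loci")
    m = GenotypeMatrix(
        np.array(dosages, dtype=np.int8).T,
        np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64),
        samples,
    ).sorted_by_position()
    return m, ParseReport(len(samples), n_read, n_dropped, [])


def write_genotypes_hapmap(m: GenotypeMatrix, path, ref: str = "A", alt: str = "G") -> None:
    """Write a genotype matrix as a HapMap table. Allele letters are synthetic
    (the matrix stores dosages only); heterozygotes use the IUPAC code."""
    het = next(c for c, pair in _IUPAC_HET.items() if pair == {ref, alt})
    code = {0: ref, 1: het, 2: alt, MISSING: "N"}
    with open(path, "w") as fh:
        fh.write("\t".join(HAPMAP_COLUMNS + list(m.sample_ids)) + "\n")
        for j in range(m.n_loci):
            meta = [
                f"snp{j:06d}", f"{ref}/{alt}", str(m.chrom[j]), str(m.pos[j]),
                "+", "NA", "NA", "NA", "NA", "NA", "NA",
            ]
            calls = [code[int(g)] for g in m.genotypes[:, j]]
            fh.write("\t".join(meta + calls) + "\n")


def read_annotation_table(path, dialect: str = "one_based_table"):
    """Read a delimited annotation table (chrom, start, end, id, kind).

    ``dialect='bed'`` treats coordinates as 0-based half-open and converts to
    the internal 1-based closed convention. Returns (records, report); records
    whose interval is empty after normalisation are reported, not returned.
    """
    if dialect not in ("bed", "one_based_table"):
        raise ValueError("dialect must be 'bed' or 'one_based_table'")
    df = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#",
        names=["chrom", "start", "end", "id", "kind"], dtype=str,
    )
    records, warnings = [], []
    for i, row in df.iterrows():
        chrom = str(row["chrom"])
        start, end = int(row["start"]), int(row["end"])
        if dialect == "bed":
            start += 1
        rid = row["id"] if pd.notna(row["id"]) else f"rec{i}"
        kind = row["kind"] if pd.notna(row["kind"]) else "gene"
        if start > end:
            warnings.append(f"line {i + 1}: empty interval after normalisation ({chrom}:{start}-{end})")
            continue
        records.append(AnnotationRecord(chrom=chrom, start=start, end=end, id=str(rid), kind=str(kind)))
    report = ParseReport(0, len(df), len(df) - len(records), warnings)
    return records, report


def write_annotation_bed(records, path) -> None:
    """Write annotation records as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.chrom}\t{rec.start - 1}\t{rec.end}\t{rec.id}\t{rec.kind}\n")


SCAN_COLUMNS = ["chrom", "pos", "fst", "p", "q", "class", "method"]


def write_scan_results(results: pd.DataFrame, path) -> None:
    """Write a per-locus scan table as TSV, sorted by (chrom, pos). Requires
    the standard columns; extra columns are kept after them."""
    if results.empty:
        raise ValueError("results must be non-empty")
    cols = [c for c in SCAN_COLUMNS if c in results.columns]
    rest = [c for c in results.columns if c not in cols]
    out = results.sort_values(["chrom", "pos"])[cols + rest]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def read_scan_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")
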