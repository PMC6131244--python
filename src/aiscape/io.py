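"""Readers and writers for the pipeline's tabular formats.

All genomic intervals are 0-based half-open, matching BED conventions.
Tables are plain TSV; SNVs may also come from a minimal VCF 4.2 with a
per-sample ``AD`` (allelic depth) FORMAT field, read through cyvcf2.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("aiscape")

KLASSES = ("gain", "loss", "homozygous_deletion")

PROBE_COLUMNS = ["sample_id", "chrom", "pos", "baf", "lrr"]
SEGMENT_COLUMNS = ["chrom", "start", "end", "sample_id", "klass",
                   "mean_lrr", "mean_mbaf", "n_probes"]
SNV_COLUMNS = ["sample_id", "chrom", "pos", "ref_reads", "alt_reads", "vaf"]
PEAK_COLUMNS = ["rank", "chrom", "klass", "apex_start", "apex_end",
                "height", "prominence", "genes"]


class FormatError(ValueError):
    """Malformed input file; the message names the offending row."""


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


# ---------------------------------------------------------------------------
# probe signals
# ---------------------------------------------------------------------------

def read_probe_signals(path) -> pd.DataFrame:
    """Read per-sample heterozygous-SNP tumor signals (BAF, LRR).

    Returns a DataFrame with columns sample_id, chrom, pos, baf, lrr.
    Positions must be sorted within each (sample, chrom) block.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str},
                     float_precision="round_trip")
    if df.empty:
        logger.warning("%s: empty probe file", path)
        return pd.DataFrame(columns=PROBE_COLUMNS)
    _require_columns(df, PROBE_COLUMNS, path)
    bad = df.index[(df["baf"] < 0) | (df["baf"] > 1) | df["baf"].isna()]
    if len(bad):
        # +2: header line and 1-based counting
        raise FormatError(f"{path}: BAF outside [0,1] at line {bad[0] + 2}")
    for (sample, chrom), grp in df.groupby(["sample_id", "chrom"], sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            row = grp.index[int(np.argmax(np.diff(pos) < 0)) + 1]
            raise FormatError(
                f"{path}: unsorted positions for sample {sample} chrom {chrom} "
                f"at line {row + 2}")
    return df[PROBE_COLUMNS]


def write_probe_signals(df: pd.DataFrame, path) -> None:
    df[PROBE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# AI segments (BED-like)
# ---------------------------------------------------------------------------

def read_segments_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str},
                     float_precision="round_trip")
    if df.empty:
        return pd.DataFrame(columns=SEGMENT_COLUMNS)
    _require_columns(df, SEGMENT_COLUMNS, path)
    df["klass"] = df["klass"].str.lower()
    bad = df.index[~df["klass"].isin(KLASSES)]
    if len(bad):
        raise FormatError(
            f"{path}: unknown klass {df.loc[bad[0], 'klass']!r} at line {bad[0] + 2}")
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise FormatError(f"{path}: start >= end at line {bad[0] + 2}")
    return df[SEGMENT_COLUMNS]


def write_segments_bed(df: pd.DataFrame, path) -> None:
    df[SEGMENT_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# somatic SNVs (TSV or minimal VCF with AD)
# ---------------------------------------------------------------------------

def read_snvs(path) -> pd.DataFrame:
    """Read somatic SNVs from TSV (ref_reads/alt_reads columns) or VCF (AD)."""
    path = str(path)
    if path.endswith(".vcf") or path.endswith(".vcf.gz"):
        df = _read_snvs_vcf(path)
    else:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
        if df.empty:
            return pd.DataFrame(columns=SNV_COLUMNS)
        _require_columns(df, ["sample_id", "chrom", "pos", "ref_reads", "alt_reads"], path)
    depth = df["ref_reads"] + df["alt_reads"]
    rejected = int((depth <= 0).sum())
    if rejected:
        logger.warning("%s: dropped %d SNV rows with zero depth", path, rejected)
        df = df[depth > 0].copy()
    df["vaf"] = df["alt_reads"] / (df["ref_reads"] + df["alt_reads"])
    df = df.sort_values(["sample_id", "chrom", "pos"], kind="stable").reset_index(drop=True)
    return df[SNV_COLUMNS]


def _read_snvs_vcf(path) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows = []
    for var in vcf:
        ad = var.format("AD")
        if ad is None:
            raise FormatError(f"{path}: VCF record {var.CHROM}:{var.POS} lacks AD field")
        for si, sample in enumerate(samples):
            ref, alt = int(ad[si][0]), int(ad[si][1])
            if ref < 0 or alt < 0:  # missing genotype encoded negative
                continue
            rows.append((sample, var.CHROM, var.POS - 1, ref, alt))
    df = pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "ref_reads", "alt_reads"])
    return df


def write_snvs_vcf(df: pd.DataFrame, path, contigs=None) -> None:
    """Write SNVs as a minimal multi-sample VCF 4.2 with AD per sample.

    Records without a call for a sample get ``./.:.``; ref/alt alleles are
    placeholders (N/A) since only depths matter downstream.
    """
    samples = sorted(df["sample_id"].unique())
    keyed = {(r.chrom, r.pos, r.sample_id): (r.ref_reads, r.alt_reads)
             for r in df.itertuples()}
    loci = sorted({(r.chrom, r.pos) for r in df.itertuples()})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for name, length in contigs:
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths (ref,alt)">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for chrom, pos in loci:
            cells = []
            for s in samples:
                if (chrom, pos, s) in keyed:
                    ref, alt = keyed[(chrom, pos, s)]
                    cells.append(f"{ref},{alt}")
                else:
                    cells.append(".")
            fh.write(f"{chrom}\t{pos + 1}\t.\tN\tA\t.\tPASS\t.\tAD\t"
                     + "\t".join(cells) + "\n")


def write_snvs_tsv(df: pd.DataFrame, path) -> None:
    df[SNV_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED (genes with a name column; callable mask as BED3)
# ---------------------------------------------------------------------------

def read_genes_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name"],
                     dtype={"chrom": str, "name": str})
    if (df["start"] >= df["end"]).any():
        raise FormatError(f"{path}: gene interval with start >= end")
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_genes_bed(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "name"]].to_csv(path, sep="\t", index=False, header=False)


def read_mask_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"], dtype={"chrom": str})
    if (df["start"] >= df["end"]).any():
        raise FormatError(f"{path}: mask interval with start >= end")
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_mask_bed(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# sample metadata, peak reports
# ---------------------------------------------------------------------------

def read_sample_meta(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    _require_columns(df, ["sample_id", "msi_status", "purity"], path)
    if ((df["purity"] <= 0) | (df["purity"] > 1)).any():
        raise FormatError(f"{path}: purity outside (0,1]")
    return df


def write_sample_meta(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_peaks_tsv(peaks, path) -> None:
    """Write a ranked peak report; ``peaks`` is a list of Peak objects."""
    rows = [{
        "rank": p.rank, "chrom": p.chrom, "klass": p.klass,
        "apex_start": p.apex_start, "apex_end": p.apex_end,
        "height": p.height, "prominence": p.prominence,
        "genes": ",".join(p.genes),
    } for p in peaks]
    pd.DataFrame(rows, columns=PEAK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_peaks_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["genes"] = df["genes"].fillna("")
    return df
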