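"""Readers and writers for the pipeline's exchange formats.

VCFv4.2 multi-sample files (GT:AD:DP:GQ genotypes; FS/MQ/MQRS/RPRS site
metrics in INFO) are handled with pysam.  Variant annotations, sample
phenotypes, carrier matrices and result tables travel as plain TSV with
fixed, documented column sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .qc import VariantRecord

__all__ = [
    "VcfData",
    "write_vcf",
    "read_vcf",
    "ANNOTATION_COLUMNS",
    "write_annotation_tsv",
    "read_annotation_tsv",
    "PHENOTYPE_COLUMNS",
    "write_phenotype_tsv",
    "read_phenotype_tsv",
    "variant_records_from",
    "write_carrier_matrix",
]

ANNOTATION_COLUMNS = [
    "variant_key",
    "gene",
    "transcript",
    "consequence",
    "gnomad_maf",
    "gnomad_popmax_maf",
    "gnomad_cov10_fraction",
    "exome_z",
    "exome_mq",
    "damaging_flag",
    "in_ccds",
    "observed_in_gnomad",
]

PHENOTYPE_COLUMNS = [
    "sample_id",
    "cohort",
    "stratum",
    "status",
    "aggressive",
    "age",
    "sex",
    "PC1",
    "PC2",
    "PC3",
    "PC4",
]

_SITE_METRICS = ("FS", "MQ", "MQRS", "RPRS")


@dataclass
class VcfData:
    """In-memory view of a multi-sample VCF.

    ``sites`` is indexed by variant_key with QUAL and INFO metrics;
    ``gt``/``dp``/``alt_reads``/``gq`` are DataFrames (samples x variants);
    missing genotypes are NaN in ``gt``.
    """

    sites: pd.DataFrame
    gt: pd.DataFrame
    dp: pd.DataFrame
    alt_reads: pd.DataFrame
    gq: pd.DataFrame

    @property
    def samples(self) -> pd.Index:
        return self.gt.index

    @property
    def variant_keys(self) -> pd.Index:
        return self.gt.columns


def _vcf_header(samples, contigs) -> pysam.VariantHeader:
    hdr = pysam.VariantHeader()
    for contig in contigs:
        hdr.add_line(f"##contig=<ID={contig}>")
    hdr.add_line('##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">')
    hdr.add_line('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">')
    hdr.add_line(
        '##INFO=<ID=MQRS,Number=1,Type=Float,Description="Mapping quality rank sum">'
    )
    hdr.add_line(
        '##INFO=<ID=RPRS,Number=1,Type=Float,Description="Read position rank sum">'
    )
    hdr.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    hdr.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">'
    )
    hdr.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    hdr.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    for s in samples:
        hdr.add_sample(str(s))
    return hdr


def write_vcf(path, sites: pd.DataFrame, gt, dp, alt_reads, gq) -> Path:
    """Write a multi-sample VCFv4.2 file.

    ``sites`` must carry chrom/pos/ref/alt/qual/fs/mq/mqrs/rprs columns
    indexed by variant_key and sorted by (chrom, pos); the genotype frames
    are samples x variant_key.  ``gt`` holds dosages with NaN for missing.
    Output is deterministic for identical inputs.
    """
    path = Path(path)
    samples = list(gt.index.astype(str))
    contigs = list(dict.fromkeys(sites["chrom"].astype(str)))
    hdr = _vcf_header(samples, contigs)
    with pysam.VariantFile(str(path), "w", header=hdr) as vf:
        for key, row in sites.iterrows():
            rec = vf.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                alleles=(str(row["ref"]), str(row["alt"])),
            )
            rec.qual = float(row["qual"])
            for metric in _SITE_METRICS:
                rec.info[metric] = float(row[metric.lower()])
            g = gt[key]
            d = dp[key]
            a = alt_reads[key]
            q = gq[key]
            for s in samples:
                call = rec.samples[s]
                dose = g[s]
                if pd.isna(dose):
                    call["GT"] = (None, None)
                else:
                    dose = int(dose)
                    call["GT"] = (0, 0) if dose == 0 else ((0, 1) if dose == 1 else (1, 1))
                depth = int(d[s])
                alt = int(a[s])
                call["AD"] = (depth - alt, alt)
                call["DP"] = depth
                call["GQ"] = int(q[s])
            vf.write(rec)
    return path


def read_vcf(path) -> VcfData:
    """Read a multi-sample VCF written by :func:`write_vcf` (or any VCF with
    GT:AD:DP:GQ and FS/MQ/MQRS/RPRS INFO metrics)."""
    site_rows = []
    gt_cols: dict[str, np.ndarray] = {}
    dp_cols: dict[str, np.ndarray] = {}
    ad_cols: dict[str, np.ndarray] = {}
    gq_cols: dict[str, np.ndarray] = {}
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            ref, alt = rec.alleles[0], rec.alleles[1]
            key = f"{rec.contig}:{rec.pos}:{ref}:{alt}"
            site_rows.append(
                {
                    "variant_key": key,
                    "chrom": rec.contig,
                    "pos": rec.pos,
                    "ref": ref,
                    "alt": alt,
                    "qual": float(rec.qual) if rec.qual is not None else np.nan,
                    "is_indel": len(ref) != len(alt),
                    **{
                        m.lower(): float(rec.info.get(m, np.nan))
                        for m in _SITE_METRICS
                    },
                }
            )
            gts = np.empty(len(samples))
            dps = np.zeros(len(samples), dtype=np.int64)
            ads = np.zeros(len(samples), dtype=np.int64)
            gqs = np.zeros(len(samples), dtype=np.int64)
            for i, s in enumerate(samples):
                call = rec.samples[s]
                alleles = call.get("GT")
                if alleles is None or any(a is None for a in alleles):
                    gts[i] = np.nan
                else:
                    gts[i] = sum(alleles)
                dps[i] = call.get("DP") or 0
                ad = call.get("AD")
                ads[i] = ad[1] if ad is not None and ad[1] is not None else 0
                gqs[i] = call.get("GQ") or 0
            gt_cols[key] = gts
            dp_cols[key] = dps
            ad_cols[key] = ads
            gq_cols[key] = gqs
    sites = pd.DataFrame(site_rows).set_index("variant_key")
    idx = pd.Index(samples, name="sample_id")
    return VcfData(
        sites=sites,
        gt=pd.DataFrame(gt_cols, index=idx),
        dp=pd.DataFrame(dp_cols, index=idx),
        alt_reads=pd.DataFrame(ad_cols, index=idx),
        gq=pd.DataFrame(gq_cols, index=idx),
    )


def write_annotation_tsv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.loc[:, ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_annotation_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation TSV is missing columns: {sorted(missing)}")
    return df


def write_phenotype_tsv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.loc[:, PHENOTYPE_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")
    return path


def read_phenotype_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype TSV is missing columns: {sorted(missing)}")
    return df.set_index("sample_id")


def variant_records_from(
    annotation: pd.DataFrame, sites: pd.DataFrame
) -> dict[str, VariantRecord]:
    """Join the annotation table with VCF site metrics into VariantRecords."""
    ann = annotation.set_index("variant_key") if "variant_key" in annotation else annotation
    records = {}
    for key, row in ann.iterrows():
        site = sites.loc[key] if key in sites.index else None
        popmax = row.get("gnomad_popmax_maf")
        records[key] = VariantRecord(
            variant_key=key,
            gene=row["gene"],
            transcript=row.get("transcript", ""),
            consequence=row["consequence"],
            gnomad_maf=float(row["gnomad_maf"]),
            gnomad_popmax_maf=None if pd.isna(popmax) else float(popmax),
            gnomad_cov10_fraction=float(row["gnomad_cov10_fraction"]),
            exome_z=None if pd.isna(row.get("exome_z")) else float(row["exome_z"]),
            exome_mq=None if pd.isna(row.get("exome_mq")) else float(row["exome_mq"]),
            qual=None if site is None else float(site["qual"]),
            fs=None if site is None else float(site["fs"]),
            mq=None if site is None else float(site["mq"]),
            mqrs=None if site is None else float(site["mqrs"]),
            rprs=None if site is None else float(site["rprs"]),
            is_indel=bool(site["is_indel"]) if site is not None else False,
            observed_in_gnomad=bool(row.get("observed_in_gnomad", True)),
            in_ccds=bool(row.get("in_ccds", True)),
            damaging_flag=bool(row.get("damaging_flag", False)),
        )
    return records


def write_carrier_matrix(matrix, path, provenance_path=None) -> Path:
    """Persist a carrier matrix as TSV (samples x gene.model) with an
    optional sidecar provenance JSON."""
    import json

    path = Path(path)
    data = getattr(matrix, "data", matrix)
    data.astype(int).to_csv(path, sep="\t", index_label="sample_id")
    prov = getattr(matrix, "provenance", None)
    if provenance_path is not None and prov is not None:
        serialisable = {
            col: {s: list(keys) for s, keys in sorted(samples.items())}
            for col, samples in sorted(prov.items())
        }
        Path(provenance_path).write_text(json.dumps(serialisable, indent=1, sort_keys=True))
    return path
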