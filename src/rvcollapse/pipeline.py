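"""End-to-end orchestration: VCF + annotation + phenotypes in, results out.

Glues the QC stacks, qualifying-variant classification, carrier
collapsing and association testing together behind a few functions the
CLI exposes.  Genotypes that fail genotype-level rules are set to missing;
variants that fail site-level rules are dropped; every decision is
recorded in a filter-audit table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import io as _io
from .association import CollapsingModel, CollapsingResults
from .flags import Thresholds, compute_thresholds
from .qc import (
    GenotypeCall,
    VariantRecord,
    collapsing_site_filter,
    exwas_genotype_filter,
    exwas_site_filter,
)
from .qv import build_carrier_matrix, classify_variant, default_registry, exclude_genes

__all__ = [
    "genotype_calls_for",
    "apply_collapsing_qc",
    "apply_exwas_qc",
    "internal_mafs",
    "assign_qvs",
    "run_collapsing",
]


def genotype_calls_for(vcf: _io.VcfData, key: str) -> list[GenotypeCall]:
    gt = vcf.gt[key]
    dp = vcf.dp[key]
    alt = vcf.alt_reads[key]
    gq = vcf.gq[key]
    calls = []
    for s in vcf.samples:
        g = gt[s]
        calls.append(
            GenotypeCall(
                sample_id=str(s),
                variant_key=key,
                gt=None if pd.isna(g) else int(g),
                dp=int(dp[s]),
                gq=int(gq[s]),
                alt_reads=int(alt[s]),
            )
        )
    return calls


def _audit_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["variant_key", "sample_id", "rule", "verdict"])


def apply_collapsing_qc(
    vcf: _io.VcfData, records: dict[str, VariantRecord]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the collapsing filter stack.

    Returns ``(clean genotype matrix, audit table)``.  A variant whose
    site-level rules fail is dropped; a genotype failing genotype-level
    rules becomes missing (NaN).
    """
    clean = vcf.gt.copy()
    audit_rows = []
    drop: list[str] = []
    for key in vcf.variant_keys:
        if key not in records:
            drop.append(key)
            audit_rows.append((key, None, "unannotated", "fail"))
            continue
        decisions = collapsing_site_filter(records[key], genotype_calls_for(vcf, key))
        site_failed = None
        for dec in decisions:
            site_rules = [r for r in dec.failed_rules if r in _SITE_LEVEL_RULES]
            geno_rules = [r for r in dec.failed_rules if r not in _SITE_LEVEL_RULES]
            if site_failed is None:
                site_failed = site_rules
            if geno_rules:
                clean.loc[dec.sample_id, key] = np.nan
                for r in geno_rules:
                    audit_rows.append((key, dec.sample_id, r, "fail"))
        if site_failed:
            drop.append(key)
            for r in site_failed:
                audit_rows.append((key, None, r, "fail"))
    clean = clean.drop(columns=drop)
    return clean, _audit_frame(audit_rows)


_SITE_LEVEL_RULES = {
    "ccds",
    "rprs",
    "fs",
    "qual",
    "mq",
    "mqrs",
    "gnomad-coverage",
    "gnomad-exome-z",
    "gnomad-exome-mq",
}


def apply_exwas_qc(
    vcf: _io.VcfData, records: dict[str, VariantRecord]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the single-variant (ExWAS) filter stack; same contract as
    :func:`apply_collapsing_qc` with the additional site-level exclusions."""
    clean = vcf.gt.copy()
    audit_rows = []
    drop: list[str] = []
    for key in vcf.variant_keys:
        if key not in records:
            drop.append(key)
            audit_rows.append((key, None, "unannotated", "fail"))
            continue
        calls = genotype_calls_for(vcf, key)
        site = exwas_site_filter(records[key], calls)
        if not site.passed:
            drop.append(key)
            for r in site.failed_rules:
                audit_rows.append((key, None, r, "fail"))
            continue
        for call in calls:
            dec = exwas_genotype_filter(records[key], call)
            if not dec.passed:
                clean.loc[call.sample_id, key] = np.nan
                for r in dec.failed_rules:
                    audit_rows.append((key, call.sample_id, r, "fail"))
    clean = clean.drop(columns=drop)
    return clean, _audit_frame(audit_rows)


def internal_mafs(genotypes: pd.DataFrame, strata: pd.Series) -> pd.Series:
    """Within-stratum alternate-allele frequency on QC-passed genotypes,
    reported per variant as the maximum over strata (the ceiling a
    frequency filter must respect in every analysed stratum)."""
    strata = strata.reindex(genotypes.index)
    out = {}
    for key in genotypes.columns:
        best = 0.0
        for _, idx in genotypes.groupby(strata, sort=True).groups.items():
            col = genotypes.loc[idx, key]
            n = col.notna().sum()
            if n:
                best = max(best, float(col.sum(skipna=True) / (2 * n)))
        out[key] = best
    return pd.Series(out)


def assign_qvs(
    records: dict[str, VariantRecord],
    internal_maf: pd.Series,
    registry=None,
    models=None,
) -> dict[str, dict[str, str]]:
    """Classify every annotated variant under every requested QV model.

    Returns model -> {variant_key: gene} for the qualifying variants.
    """
    registry = registry if registry is not None else default_registry()
    names = list(models) if models is not None else list(registry)
    assignments: dict[str, dict[str, str]] = {name: {} for name in names}
    for key, rec in records.items():
        if key not in internal_maf.index:
            continue
        for name in names:
            if classify_variant(rec, float(internal_maf[key]), registry[name]):
                assignments[name][key] = rec.gene
    return assignments


def run_collapsing(
    vcf_path,
    annotation_path,
    phenotype_path,
    models=None,
    exclusion_list=(),
    contrast: str = "PCa_vs_Ctrl",
    thresholds: Thresholds | None = None,
) -> CollapsingResults:
    """Full gene-level collapsing analysis from files to results."""
    vcf = _io.read_vcf(vcf_path)
    annotation = _io.read_annotation_tsv(annotation_path)
    phenotypes = _io.read_phenotype_tsv(phenotype_path)
    records = _io.variant_records_from(annotation, vcf.sites)
    clean, _ = apply_collapsing_qc(vcf, records)
    maf = internal_mafs(clean, phenotypes["stratum"])
    registry = default_registry()
    if models is not None:
        registry = {m: registry[m] for m in models}
    assignments = assign_qvs(
        {k: r for k, r in records.items() if k in clean.columns}, maf, registry
    )
    matrix = build_carrier_matrix(clean, assignments, registry)
    if exclusion_list:
        matrix = exclude_genes(matrix, exclusion_list)
    model = CollapsingModel(
        matrix,
        phenotypes,
        contrast=contrast,
        thresholds=thresholds or compute_thresholds(),
    )
    return model.fit()
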