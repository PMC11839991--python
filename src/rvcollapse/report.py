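"""Deterministic result writers and the run manifest.

All outputs are plain TSV/JSON so that repeated runs with the same seed
are byte-identical: gene-level results with a significance-tier column,
variant-level meta results, somatic-artifact flags, a genomic-inflation
table, and a run manifest recording seed, config hash and version.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .flags import SomaticFlagResult, Thresholds, significance_tier

__all__ = ["write_report", "GENE_RESULT_COLUMNS"]

#: Fixed column order of the gene-level results TSV.
GENE_RESULT_COLUMNS = [
    "gene",
    "qv_model",
    "contrast",
    "n_group1",
    "n_group2",
    "carriers_group1",
    "carriers_group2",
    "carrier_freq_group1",
    "carrier_freq_group2",
    "p_cmh",
    "or_mh",
    "ci_low",
    "ci_high",
    "n_strata",
    "tier",
    "flags",
]

VARIANT_RESULT_COLUMNS = ["variant_key", "model", "z", "p", "cohorts_used", "tier"]

FLAG_COLUMNS = [
    "gene",
    "qv_model",
    "age_association_p",
    "median_het_alt_fraction",
    "skew_p",
    "flagged",
]

LAMBDA_COLUMNS = ["label", "lambda", "n_permutations", "n_tests"]


def _write_tsv(df: pd.DataFrame, columns, path: Path) -> None:
    out = df.reindex(columns=columns) if len(df) else pd.DataFrame(columns=columns)
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def write_report(
    gene_results: pd.DataFrame | None,
    thresholds: Thresholds,
    out_dir,
    variant_results: pd.DataFrame | None = None,
    somatic_flags=None,
    inflation_results=None,
    seed: int | None = None,
    config: dict | None = None,
) -> dict[str, Path]:
    """Write the analysis report files into ``out_dir``.

    Empty inputs produce headers-only files.  Returns the mapping of report
    name to written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    genes = gene_results if gene_results is not None else pd.DataFrame()
    if len(genes) and "tier" not in genes:
        genes = genes.assign(tier=[significance_tier(p, thresholds) for p in genes["p_cmh"]])
    path = out_dir / "gene_results.tsv"
    _write_tsv(genes, GENE_RESULT_COLUMNS, path)
    written["gene_results"] = path

    variants = variant_results if variant_results is not None else pd.DataFrame()
    if len(variants):
        variants = variants.copy()
        if "tier" not in variants and "p" in variants:
            variants["tier"] = [significance_tier(p, thresholds) for p in variants["p"]]
        if "cohorts_used" in variants:
            variants["cohorts_used"] = variants["cohorts_used"].map(
                lambda c: ",".join(c) if isinstance(c, (tuple, list)) else c
            )
    path = out_dir / "variant_meta_results.tsv"
    _write_tsv(variants, VARIANT_RESULT_COLUMNS, path)
    written["variant_meta_results"] = path

    flag_rows = []
    for f in somatic_flags or []:
        if isinstance(f, SomaticFlagResult):
            flag_rows.append(
                {
                    "gene": f.gene,
                    "qv_model": f.qv_model,
                    "age_association_p": f.age_association_p,
                    "median_het_alt_fraction": f.median_het_alt_fraction,
                    "skew_p": f.skew_p,
                    "flagged": int(f.flagged),
                }
            )
        else:
            flag_rows.append(dict(f))
    path = out_dir / "somatic_flags.tsv"
    _write_tsv(pd.DataFrame(flag_rows), FLAG_COLUMNS, path)
    written["somatic_flags"] = path

    lam_rows = []
    for r in inflation_results or []:
        lam_rows.append(
            {
                "label": r.label,
                "lambda": r.lambda_,
                "n_permutations": r.n_permutations,
                "n_tests": r.n_tests,
            }
        )
    path = out_dir / "lambda.tsv"
    _write_tsv(pd.DataFrame(lam_rows), LAMBDA_COLUMNS, path)
    written["lambda"] = path

    from . import __version__

    config_json = json.dumps(config or {}, sort_keys=True)
    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "version": __version__,
        "thresholds": {
            "suggestive": thresholds.suggestive,
            "study_wide": thresholds.study_wide,
            "n_genes_tested": thresholds.n_genes_tested,
        },
        "files": {k: p.name for k, p in written.items()},
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    written["run_manifest"] = path
    return written
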