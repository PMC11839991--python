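"""Seeded multi-cohort case-control exome simulator.

Generates the same inputs the analysis pipeline consumes — a multi-sample
VCF with per-genotype AD/DP/GQ and per-site QUAL/FS/MQ/MQRS/RPRS, a
variant annotation TSV and a sample phenotype TSV — together with the
ground truth needed to test recovery: realized carrier counts per stratum,
the variants designed to fail each QC rule, and the carriers of a planted
somatic-contamination gene.

Effect structure
----------------
Carrier status for a gene is drawn per sample with probability ``f`` in
controls and with odds scaled exactly by the configured odds ratio in
cases: ``odds = f/(1-f) * OR`` (aggressive cases additionally scale by the
aggressiveness odds ratio), so the target OR is identifiable from the
simulated tables.  Each carrier receives exactly one heterozygous
qualifying genotype; synonymous variants carry a status-independent
(negative-control) signal.  A planted somatic gene draws carriers with a
logistic dependence on age and heterozygous alt-read counts centred below
50%, emulating clonal-haematopoiesis contamination of germline calls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from . import io as _io
from .association import StratumTables, Table2x2

__all__ = [
    "CohortSpec",
    "GeneEffectSpec",
    "SomaticGeneSpec",
    "SimulationConfig",
    "GroundTruth",
    "StudyData",
    "simulate_study",
    "SeverityCall",
    "classify_severity",
    "sample_stratum_tables",
    "sample_carrier_matrix",
    "sample_somatic_cohort",
]

_CONSEQUENCE_BY_CLASS = {
    "ptv": "stop_gained",
    "missense": "missense_variant",
    "synonymous": "synonymous_variant",
}

#: QC rules a decoy variant can be designed to violate, with the metric
#: override that violates them.
_QC_FAIL_DESIGNS: tuple[tuple[str, dict], ...] = (
    ("qual", {"qual": 10.0}),
    ("fs", {"fs": 80.0}),
    ("mq", {"mq": 30.0}),
    ("mqrs", {"mqrs": -9.0}),
    ("rprs", {"rprs": -3.0}),
    ("gnomad-coverage", {"gnomad_cov10_fraction": 0.1}),
    ("gnomad-exome-z", {"exome_z": -3.0}),
)


def _check(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid SimulationConfig field {fieldname!r}: {msg}")


@dataclass(frozen=True)
class CohortSpec:
    name: str
    n_cases: int
    n_controls: int
    aggressive_fraction: float = 0.2

    def __post_init__(self) -> None:
        _check(self.n_cases >= 1, "n_cases", "cohort sizes must be >= 1")
        _check(self.n_controls >= 1, "n_controls", "cohort sizes must be >= 1")
        _check(0.0 <= self.aggressive_fraction <= 1.0, "aggressive_fraction", "must be in [0,1]")


@dataclass(frozen=True)
class GeneEffectSpec:
    gene: str
    control_carrier_freq: float
    odds_ratio_risk: float = 1.0
    odds_ratio_aggressive: float = 1.0
    n_variants: dict = field(
        default_factory=lambda: {"ptv": 4, "missense": 4, "synonymous": 2}
    )

    def __post_init__(self) -> None:
        _check(0.0 <= self.control_carrier_freq <= 1.0, "control_carrier_freq", "must be in [0,1]")
        _check(self.odds_ratio_risk > 0, "odds_ratio_risk", "odds ratios must be > 0")
        _check(self.odds_ratio_aggressive > 0, "odds_ratio_aggressive", "odds ratios must be > 0")
        unknown = set(self.n_variants) - set(_CONSEQUENCE_BY_CLASS)
        _check(not unknown, "n_variants", f"unknown consequence classes {sorted(unknown)}")
        _check(sum(self.n_variants.values()) >= 1, "n_variants", "at least one variant per gene")


@dataclass(frozen=True)
class SomaticGeneSpec:
    gene: str
    age_slope_per_year: float = 0.1
    mean_alt_fraction: float = 0.3
    base_carrier_freq: float = 0.005
    n_variants: int = 3

    def __post_init__(self) -> None:
        _check(0.0 < self.mean_alt_fraction < 0.5, "mean_alt_fraction", "must be in (0, 0.5)")
        _check(0.0 < self.base_carrier_freq < 1.0, "base_carrier_freq", "must be in (0,1)")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    cohorts: tuple[CohortSpec, ...]
    genes: tuple[GeneEffectSpec, ...]
    qc_fail_fraction: float = 0.05
    somatic_gene: SomaticGeneSpec | None = None
    age_range: tuple[int, int] = (45, 75)

    def __post_init__(self) -> None:
        _check(len(self.cohorts) >= 1, "cohorts", "at least one cohort")
        _check(len(self.genes) >= 1, "genes", "at least one gene")
        _check(0.0 <= self.qc_fail_fraction <= 1.0, "qc_fail_fraction", "must be in [0,1]")
        _check(self.age_range[0] < self.age_range[1], "age_range", "low < high required")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        somatic = d.get("somatic_gene")
        return cls(
            seed=int(d["seed"]),
            cohorts=tuple(CohortSpec(**c) for c in d["cohorts"]),
            genes=tuple(
                GeneEffectSpec(**{**g, "n_variants": dict(g.get("n_variants") or
                                                          {"ptv": 4, "missense": 4, "synonymous": 2})})
                for g in d["genes"]
            ),
            qc_fail_fraction=float(d.get("qc_fail_fraction", 0.05)),
            somatic_gene=SomaticGeneSpec(**somatic) if somatic else None,
            age_range=tuple(d.get("age_range", (45, 75))),
        )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class GroundTruth:
    """Realized simulation truth for recovery testing."""

    carrier_counts: dict  # gene -> stratum -> {case,control,aggressive_case,nonaggressive_case}
    qc_fail_variants: dict  # variant_key -> [rule, ...]
    somatic_carriers: dict  # sample_id -> realized mean het alt fraction
    qualifying_variants: dict  # gene -> [variant_key, ...] (nonsynonymous QVs)

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))
        return path


@dataclass
class StudyData:
    """Paths and in-memory objects produced by one simulated study."""

    vcf_path: Path
    annotation_path: Path
    phenotype_path: Path
    ground_truth_path: Path
    ground_truth: GroundTruth
    config: SimulationConfig


@dataclass(frozen=True)
class SeverityCall:
    label: str  # "aggressive" | "non_aggressive"
    flags: tuple[str, ...] = ()


def classify_severity(
    is_case: bool = True,
    stage_t: str | None = None,
    node_n: str | None = None,
    metastasis_m: str | None = None,
    gleason: int | None = None,
    cause_of_death: str | None = None,
    metastatic: bool | None = None,
    chemotherapy: bool | None = None,
    castration_resistant: bool | None = None,
) -> SeverityCall:
    """Classify a prostate-cancer case as aggressive or non-aggressive.

    Aggressive iff ANY of: tumour stage T4, nodal stage N1, metastasis M1,
    Gleason score >= 8, prostate cancer as cause of death, metastatic
    disease, chemotherapy treatment, or castration resistance.  Missing
    fields count as not met; if every field is missing the case is
    classified non-aggressive with a ``severity-unknown`` flag.  Severity
    is defined for cases only.
    """
    if not is_case:
        raise ValueError("severity classification is defined for cases only")
    fields = (
        stage_t, node_n, metastasis_m, gleason, cause_of_death,
        metastatic, chemotherapy, castration_resistant,
    )
    if all(f is None for f in fields):
        return SeverityCall("non_aggressive", flags=("severity-unknown",))
    criteria = (
        stage_t == "T4",
        node_n == "N1",
        metastasis_m == "M1",
        gleason is not None and gleason >= 8,
        cause_of_death == "prostate_cancer",
        bool(metastatic),
        bool(chemotherapy),
        bool(castration_resistant),
    )
    return SeverityCall("aggressive" if any(criteria) else "non_aggressive")


def case_carrier_probability(
    control_freq: float, odds_ratio: float, aggressive_odds_ratio: float = 1.0
) -> float:
    """Exact odds scaling: carrier odds in cases = control odds x OR, so the
    configured OR is identifiable from the simulated 2x2 tables."""
    odds = control_freq / (1.0 - control_freq) * odds_ratio * aggressive_odds_ratio
    return odds / (1.0 + odds)


# ---------------------------------------------------------------------------
# fast paths for large-n statistical checks
# ---------------------------------------------------------------------------


def sample_stratum_tables(
    control_freq: float,
    odds_ratio: float,
    strata_sizes,
    rng: np.random.Generator,
) -> StratumTables:
    """Draw per-stratum carrier 2x2 tables directly (no file output)."""
    p_case = case_carrier_probability(control_freq, odds_ratio)
    items = []
    for i, (n_cases, n_controls) in enumerate(strata_sizes):
        a = int(rng.binomial(n_cases, p_case))
        c = int(rng.binomial(n_controls, control_freq))
        items.append((f"stratum{i}", Table2x2(a, n_cases - a, c, n_controls - c)))
    return StratumTables.from_list(items)


def sample_carrier_matrix(
    n_samples: int, n_genes: int, freq: float, rng: np.random.Generator
) -> np.ndarray:
    """Null (status-independent) boolean carrier matrix, samples x genes."""
    return rng.random((n_samples, n_genes)) < freq


def sample_somatic_cohort(
    n_samples: int,
    spec: SomaticGeneSpec,
    rng: np.random.Generator,
    age_range: tuple[int, int] = (45, 75),
    mean_dp: int = 50,
):
    """Draw one cohort's somatic-gene carriers with logistic age dependence.

    Returns ``(ages, carrier_mask, het_calls)`` where ``het_calls`` is a
    list of (alt_reads, dp) for the carriers' heterozygous calls.
    """
    lo, hi = age_range
    ages = rng.integers(lo, hi + 1, size=n_samples)
    mid = (lo + hi) / 2.0
    p = expit(logit(spec.base_carrier_freq) + spec.age_slope_per_year * (ages - mid))
    carrier = rng.random(n_samples) < p
    dps = np.maximum(12, rng.negative_binomial(10, 10.0 / (10.0 + mean_dp), size=int(carrier.sum())))
    alts = rng.binomial(dps, spec.mean_alt_fraction)
    het_calls = list(zip(alts.tolist(), dps.tolist()))
    return ages, carrier, het_calls


# ---------------------------------------------------------------------------
# full study simulation
# ---------------------------------------------------------------------------


def _draw_depths(rng, n, mean_dp=50, floor=12):
    return np.maximum(floor, rng.negative_binomial(10, 10.0 / (10.0 + mean_dp), size=n))


def _germline_het_alt(rng, dps):
    """Heterozygous alt reads ~ Binomial(DP, 0.5), truncated into the
    retained allele-balance band so planted carriers survive QC."""
    alts = rng.binomial(dps, 0.5)
    lo = np.ceil(0.35 * dps).astype(np.int64)
    hi = np.floor(0.65 * dps).astype(np.int64)
    return np.clip(alts, lo, hi)


def simulate_study(config: SimulationConfig, out_dir) -> StudyData:
    """Simulate a stratified multi-cohort study and write its input files.

    Deterministic given ``config.seed``: the same config produces
    byte-identical VCF/TSV/JSON outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # ---- samples and phenotypes -------------------------------------------
    pheno_rows = []
    lo, hi = config.age_range
    for cohort in config.cohorts:
        for j in range(cohort.n_cases + cohort.n_controls):
            is_case = j < cohort.n_cases
            sid = f"{cohort.name}_{j:06d}"
            age = int(rng.integers(lo, hi + 1))
            clinical: dict = {}
            aggressive: float | None = None
            if is_case:
                want_aggressive = rng.random() < cohort.aggressive_fraction
                clinical = _draw_clinical(rng, want_aggressive)
                aggressive = 1 if classify_severity(True, **clinical).label == "aggressive" else 0
            pheno_rows.append(
                {
                    "sample_id": sid,
                    "cohort": cohort.name,
                    "stratum": cohort.name,
                    "status": "case" if is_case else "control",
                    "aggressive": aggressive,
                    "age": age,
                    "sex": "M",
                    "PC1": round(float(rng.normal(0, 1)), 4),
                    "PC2": round(float(rng.normal(0, 1)), 4),
                    "PC3": round(float(rng.normal(0, 1)), 4),
                    "PC4": round(float(rng.normal(0, 1)), 4),
                }
            )
    pheno = pd.DataFrame(pheno_rows)
    samples = pheno["sample_id"].tolist()
    n_samples = len(samples)
    ages = pheno["age"].to_numpy()
    status = pheno["status"].to_numpy()
    aggressive = pheno["aggressive"].to_numpy(dtype=float)
    stratum = pheno["stratum"].to_numpy()

    # ---- variant catalogue -------------------------------------------------
    ann_rows: list[dict] = []
    site_rows: list[dict] = []
    gene_variant_keys: dict[str, dict[str, list[str]]] = {}

    def add_variant(gene, chrom, pos, consequence, maf, damaging, overrides=None):
        key = f"{chrom}:{pos}:A:C"
        site = {
            "variant_key": key,
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "C",
            "qual": round(200.0 + float(rng.exponential(50.0)), 2),
            "fs": round(float(rng.uniform(0.0, 5.0)), 3),
            "mq": round(float(rng.uniform(55.0, 60.0)), 2),
            "mqrs": round(float(rng.normal(0.0, 0.5)), 3),
            "rprs": round(float(rng.normal(0.0, 0.5)), 3),
        }
        ann = {
            "variant_key": key,
            "gene": gene,
            "transcript": f"ENST_{gene}",
            "consequence": consequence,
            "gnomad_maf": maf,
            "gnomad_popmax_maf": maf,
            "gnomad_cov10_fraction": 0.98,
            "exome_z": round(float(rng.normal(1.0, 0.5)), 3),
            "exome_mq": 60.0,
            "damaging_flag": damaging,
            "in_ccds": True,
            "observed_in_gnomad": True,
        }
        for k, v in (overrides or {}).items():
            (site if k in site else ann)[k] = v
        site_rows.append(site)
        ann_rows.append(ann)
        return key

    gene_specs = list(config.genes)
    all_gene_names = [g.gene for g in gene_specs]
    if config.somatic_gene is not None:
        all_gene_names.append(config.somatic_gene.gene)
    chrom_of = {
        g: f"chr{(i % 22) + 1}" for i, g in enumerate(all_gene_names)
    }
    base_of = {g: 1_000_000 * (i + 1) for i, g in enumerate(all_gene_names)}

    for spec in gene_specs:
        keys: dict[str, list[str]] = {"ptv": [], "missense": [], "synonymous": []}
        pos = base_of[spec.gene]
        for cls in ("ptv", "missense", "synonymous"):
            for _ in range(spec.n_variants.get(cls, 0)):
                keys[cls].append(
                    add_variant(
                        spec.gene,
                        chrom_of[spec.gene],
                        pos,
                        _CONSEQUENCE_BY_CLASS[cls],
                        maf=1e-5,
                        damaging=(cls == "missense"),
                    )
                )
                pos += 10
        # two common (non-qualifying) background variants per gene
        for _ in range(2):
            add_variant(
                spec.gene, chrom_of[spec.gene], pos, "missense_variant",
                maf=0.05, damaging=False,
            )
            pos += 10
        gene_variant_keys[spec.gene] = keys

    somatic_keys: list[str] = []
    if config.somatic_gene is not None:
        sg = config.somatic_gene
        pos = base_of[sg.gene]
        for _ in range(sg.n_variants):
            somatic_keys.append(
                add_variant(sg.gene, chrom_of[sg.gene], pos, "stop_gained",
                            maf=1e-5, damaging=False)
            )
            pos += 10

    # ---- designed QC failures ---------------------------------------------
    n_qc_fail = int(round(config.qc_fail_fraction * len(site_rows)))
    qc_fail_variants: dict[str, list[str]] = {}
    for i in range(n_qc_fail):
        rule, overrides = _QC_FAIL_DESIGNS[i % len(_QC_FAIL_DESIGNS)]
        gene = gene_specs[i % len(gene_specs)].gene
        pos = base_of[gene] + 900_000 + i * 10
        key = add_variant(
            gene, chrom_of[gene], pos, "stop_gained", maf=1e-5, damaging=False,
            overrides=overrides,
        )
        qc_fail_variants[key] = [rule]

    sites = pd.DataFrame(site_rows).set_index("variant_key")
    annotation = pd.DataFrame(ann_rows)
    variant_keys = list(sites.index)

    # ---- genotypes ---------------------------------------------------------
    gt = np.zeros((n_samples, len(variant_keys)))
    col_of = {k: i for i, k in enumerate(variant_keys)}
    is_case_arr = status == "case"

    carrier_counts: dict = {}
    qualifying: dict[str, list[str]] = {}
    for spec in gene_specs:
        keys = gene_variant_keys[spec.gene]
        qv_keys = keys["ptv"] + keys["missense"]
        qualifying[spec.gene] = qv_keys
        f = spec.control_carrier_freq
        p_case = case_carrier_probability(f, spec.odds_ratio_risk)
        p_agg = case_carrier_probability(
            f, spec.odds_ratio_risk, spec.odds_ratio_aggressive
        )
        p = np.where(
            is_case_arr,
            np.where(aggressive == 1, p_agg, p_case),
            f,
        )
        carrier = rng.random(n_samples) < p
        if qv_keys:
            choice = rng.integers(0, len(qv_keys), size=n_samples)
            for idx in np.nonzero(carrier)[0]:
                gt[idx, col_of[qv_keys[choice[idx]]]] = 1
        else:
            carrier[:] = False
        # synonymous variants: status-independent carriers at the control rate
        for key in keys["synonymous"]:
            syn_carrier = rng.random(n_samples) < f
            gt[syn_carrier, col_of[key]] = 1
        counts: dict = {}
        for strat in sorted(set(stratum)):
            m = stratum == strat
            counts[strat] = {
                "case": int(np.sum(carrier & m & is_case_arr)),
                "control": int(np.sum(carrier & m & ~is_case_arr)),
                "aggressive_case": int(np.sum(carrier & m & (aggressive == 1))),
                "nonaggressive_case": int(np.sum(carrier & m & (aggressive == 0))),
            }
        carrier_counts[spec.gene] = counts

    # common background variants: Hardy-Weinberg dosages
    for row in ann_rows:
        if row["gnomad_maf"] >= 0.01:
            j = col_of[row["variant_key"]]
            gt[:, j] = rng.binomial(2, row["gnomad_maf"], size=n_samples)

    somatic_carriers: dict[str, float] = {}
    somatic_carrier_mask = np.zeros(n_samples, dtype=bool)
    if config.somatic_gene is not None:
        sg = config.somatic_gene
        mid = (lo + hi) / 2.0
        p = expit(logit(sg.base_carrier_freq) + sg.age_slope_per_year * (ages - mid))
        somatic_carrier_mask = rng.random(n_samples) < p
        choice = rng.integers(0, len(somatic_keys), size=n_samples)
        for idx in np.nonzero(somatic_carrier_mask)[0]:
            gt[idx, col_of[somatic_keys[choice[idx]]]] = 1

    # ---- per-genotype metrics ---------------------------------------------
    dp = _draw_depths(rng, (n_samples, len(variant_keys)))
    gq = rng.integers(60, 100, size=(n_samples, len(variant_keys)))
    alt = np.zeros_like(dp)
    het = gt == 1
    alt[het] = _germline_het_alt(rng, dp[het])
    hom = gt == 2
    alt[hom] = np.maximum(dp[hom] - rng.binomial(dp[hom], 0.02), np.ceil(0.85 * dp[hom]).astype(np.int64))
    if config.somatic_gene is not None:
        sg = config.somatic_gene
        for key in somatic_keys:
            j = col_of[key]
            rows = np.nonzero(gt[:, j] == 1)[0]
            alt[rows, j] = rng.binomial(dp[rows, j], sg.mean_alt_fraction)
            for idx in rows:
                somatic_carriers[samples[idx]] = float(alt[idx, j] / dp[idx, j])

    idx = pd.Index(samples, name="sample_id")
    gt_df = pd.DataFrame(gt, index=idx, columns=variant_keys)
    dp_df = pd.DataFrame(dp, index=idx, columns=variant_keys)
    alt_df = pd.DataFrame(alt, index=idx, columns=variant_keys)
    gq_df = pd.DataFrame(gq, index=idx, columns=variant_keys)

    # ---- outputs -----------------------------------------------------------
    order = sites.sort_values(["chrom", "pos"], kind="mergesort",
                              key=lambda s: s if s.name == "pos"
                              else s.str.replace("chr", "").astype(int)).index
    vcf_path = _io.write_vcf(
        out_dir / "study.vcf", sites.loc[order],
        gt_df[order], dp_df[order], alt_df[order], gq_df[order],
    )
    ann_path = _io.write_annotation_tsv(
        annotation.set_index("variant_key").loc[order].reset_index(),
        out_dir / "annotation.tsv",
    )
    pheno_path = _io.write_phenotype_tsv(pheno, out_dir / "phenotypes.tsv")
    truth = GroundTruth(
        carrier_counts=carrier_counts,
        qc_fail_variants=qc_fail_variants,
        somatic_carriers=somatic_carriers,
        qualifying_variants=qualifying,
    )
    truth_path = truth.to_json(out_dir / "ground_truth.json")
    return StudyData(
        vcf_path=vcf_path,
        annotation_path=ann_path,
        phenotype_path=pheno_path,
        ground_truth_path=truth_path,
        ground_truth=truth,
        config=config,
    )


def _draw_clinical(rng: np.random.Generator, want_aggressive: bool) -> dict:
    """Clinical fields consistent with the desired severity class."""
    clinical = {
        "stage_t": f"T{int(rng.integers(1, 4))}",
        "node_n": "N0",
        "metastasis_m": "M0",
        "gleason": int(rng.integers(6, 8)),
        "cause_of_death": None,
        "metastatic": False,
        "chemotherapy": False,
        "castration_resistant": False,
    }
    if want_aggressive:
        pick = int(rng.integers(0, 6))
        if pick == 0:
            clinical["stage_t"] = "T4"
        elif pick == 1:
            clinical["node_n"] = "N1"
        elif pick == 2:
            clinical["metastasis_m"] = "M1"
            clinical["metastatic"] = True
        elif pick == 3:
            clinical["gleason"] = int(rng.integers(8, 11))
        elif pick == 4:
            clinical["chemotherapy"] = True
        else:
            clinical["castration_resistant"] = True
    return clinical
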