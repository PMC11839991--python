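"""Site and genotype quality-control filter stacks.

Two filter stacks are provided, mirroring the ones applied to
sequencing-pipeline PASS calls in exome collapsing studies:

* the **collapsing** stack, applied per genotype before qualifying-variant
  classification (depth, genotype quality, heterozygous allele balance,
  strand bias, mapping quality, rank-sum scores, gnomAD site coverage and
  site quality), and
* the **ExWAS** stack, which adds site-level exclusions for single-variant
  testing (cohort coverage fraction, per-site genotype-failure rate,
  stricter gnomAD coverage, and a Hardy-Weinberg exact test).

The allele-balance binomial test and the Hardy-Weinberg exact test are
computed exactly, in log space, so that p-values remain meaningful for
extreme observations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "VariantRecord",
    "GenotypeCall",
    "FilterDecision",
    "allele_balance_test",
    "hwe_exact_test",
    "collapsing_site_filter",
    "exwas_site_filter",
    "exwas_genotype_filter",
    "imputation_info_filter",
    "COLLAPSING_RULES",
    "EXWAS_SITE_RULES",
]

# Relative tolerance when comparing point masses to the observed mass in
# "minimum-likelihood" two-sided exact tests (same convention as R's
# fisher.test / binom.test).
_MINLIKE_RTOL = 1e-7

#: Rule identifiers of the collapsing genotype/site stack, in evaluation order.
COLLAPSING_RULES = (
    "dp",
    "ccds",
    "het-allele-balance-range",
    "het-allele-balance-binomial",
    "rprs",
    "gq",
    "fs",
    "qual",
    "mq",
    "mqrs",
    "gnomad-coverage",
    "gnomad-exome-z",
    "gnomad-exome-mq",
)

#: Site-level rules added by the ExWAS stack.
EXWAS_SITE_RULES = (
    "site-low-coverage",
    "genotype-failure-rate",
    "gnomad-coverage-50",
    "hwe",
)


@dataclass(frozen=True)
class VariantRecord:
    """One annotated alternate allele at a site, with site QC metrics.

    ``pos`` is 1-based.  ``gnomad_cov10_fraction`` is the fraction of gnomAD
    exomes with >=10x coverage at the site.  Site metrics (``qual``, ``fs``,
    ``mq``, ``mqrs``, ``rprs``) may be ``None`` when missing; missing metrics
    conservatively fail the corresponding rule.
    """

    variant_key: str
    gene: str
    transcript: str = ""
    consequence: str = ""
    gnomad_maf: float = 0.0
    gnomad_popmax_maf: float | None = None
    gnomad_cov10_fraction: float = 1.0
    exome_z: float | None = None
    exome_mq: float | None = None
    qual: float | None = None
    fs: float | None = None
    mq: float | None = None
    mqrs: float | None = None
    rprs: float | None = None
    is_indel: bool = False
    observed_in_gnomad: bool = True
    in_ccds: bool = True
    damaging_flag: bool = False

    def __post_init__(self) -> None:
        chrom, pos, ref, alt = self.variant_key.split(":")
        if int(pos) < 1:
            raise ValueError(f"variant_key {self.variant_key!r}: pos must be >= 1")
        if ref == alt:
            raise ValueError(f"variant_key {self.variant_key!r}: ref == alt")
        for name in ("gnomad_maf", "gnomad_cov10_fraction"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def chrom(self) -> str:
        return self.variant_key.split(":")[0]

    @property
    def pos(self) -> int:
        return int(self.variant_key.split(":")[1])


@dataclass(frozen=True)
class GenotypeCall:
    """A single sample genotype at a variant; ``gt`` is the alt-allele dosage
    (0/1/2) or ``None`` when missing."""

    sample_id: str
    variant_key: str
    gt: int | None
    dp: int = 0
    gq: int = 0
    alt_reads: int = 0

    def __post_init__(self) -> None:
        if self.dp < 0 or self.alt_reads < 0:
            raise ValueError("dp and alt_reads must be non-negative")
        if self.alt_reads > self.dp:
            raise ValueError("alt_reads cannot exceed dp")


@dataclass
class FilterDecision:
    """Outcome of a filter stack for one variant (optionally one genotype)."""

    variant_key: str
    sample_id: str | None = None
    failed_rules: list[str] = field(default_factory=list)
    unevaluable_rules: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.failed_rules


def allele_balance_test(alt_reads: int, dp: int) -> float:
    """Two-sided exact binomial test of alt-read fraction against 0.5.

    The two-sided p-value is the sum of binomial(dp, 0.5) point masses not
    exceeding the observed mass (minimum-likelihood convention), evaluated
    in log space.  Heterozygous genotypes are retained when p > 1e-6.
    """
    if dp < 1:
        raise ValueError("allele_balance_test requires dp >= 1")
    if not 0 <= alt_reads <= dp:
        raise ValueError("alt_reads must satisfy 0 <= alt_reads <= dp")
    k = np.arange(dp + 1)
    # log C(n,k) - n log 2
    logpmf = gammaln(dp + 1) - gammaln(k + 1) - gammaln(dp - k + 1) - dp * math.log(2.0)
    obs = logpmf[alt_reads]
    keep = logpmf <= obs + math.log1p(_MINLIKE_RTOL)
    if keep.all():
        return 1.0
    return float(min(1.0, math.exp(logsumexp(logpmf[keep]))))


def hwe_exact_test(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact Hardy-Weinberg equilibrium test on genotype counts.

    Conditions on the observed allele counts and sums, over all feasible
    heterozygote counts of the same parity, the conditional probabilities
    that do not exceed the observed one (two-sided exact test, evaluated in
    log space).  ExWAS excludes variants with p < 1e-10.
    """
    for name, v in (("n_homref", n_homref), ("n_het", n_het), ("n_homalt", n_homalt)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    n = n_homref + n_het + n_homalt
    if n < 1:
        raise ValueError("at least one genotype is required")
    n_alt = 2 * n_homalt + n_het
    n_ref = 2 * n_homref + n_het
    # Feasible het counts share the parity of the minor-allele count.
    m = min(n_alt, n_ref)
    hets = np.arange(m % 2, m + 1, 2)
    homalt = (n_alt - hets) // 2
    homref = (n_ref - hets) // 2
    # log of the unnormalised conditional likelihood:
    #   n! / (homref! het! homalt!) * 2^het   (the (2n)!/(na! nb!) term is constant)
    logl = (
        -gammaln(homref + 1.0)
        - gammaln(hets + 1.0)
        - gammaln(homalt + 1.0)
        + hets * math.log(2.0)
    )
    logl -= logsumexp(logl)  # normalise
    obs = logl[np.searchsorted(hets, n_het)]
    keep = logl <= obs + math.log1p(_MINLIKE_RTOL)
    if keep.all():
        return 1.0
    return float(min(1.0, math.exp(logsumexp(logl[keep]))))


def _site_rule_checks(v: VariantRecord) -> list[tuple[str, float | None, bool]]:
    """Return (rule, metric value, pass?) for the site-level metric rules."""
    fs_max = 200.0 if v.is_indel else 60.0
    checks: list[tuple[str, float | None, bool]] = [
        ("ccds", 1.0 if v.in_ccds else 0.0, v.in_ccds),
        ("rprs", v.rprs, v.rprs is not None and v.rprs >= -2.0),
        ("fs", v.fs, v.fs is not None and v.fs <= fs_max),
        ("qual", v.qual, v.qual is not None and v.qual >= 30.0),
        ("mq", v.mq, v.mq is not None and v.mq >= 40.0),
        ("mqrs", v.mqrs, v.mqrs is not None and v.mqrs >= -8.0),
        (
            "gnomad-coverage",
            v.gnomad_cov10_fraction,
            v.gnomad_cov10_fraction is not None and v.gnomad_cov10_fraction >= 0.25,
        ),
    ]
    if v.observed_in_gnomad:
        checks.append(
            ("gnomad-exome-z", v.exome_z, v.exome_z is not None and v.exome_z >= -2.0)
        )
        checks.append(
            ("gnomad-exome-mq", v.exome_mq, v.exome_mq is not None and v.exome_mq >= 30.0)
        )
    return checks


def _genotype_rule_checks(
    call: GenotypeCall, *, hom_alt_rule: bool
) -> list[tuple[str, bool]]:
    checks = [("dp", call.dp >= 10), ("gq", call.gq >= 30)]
    if call.gt == 1:
        if call.dp >= 1:
            frac = call.alt_reads / call.dp
            checks.append(("het-allele-balance-range", 0.3 <= frac <= 0.8))
            checks.append(
                (
                    "het-allele-balance-binomial",
                    allele_balance_test(call.alt_reads, call.dp) > 1e-6,
                )
            )
        else:
            checks.append(("het-allele-balance-range", False))
            checks.append(("het-allele-balance-binomial", False))
    if hom_alt_rule and call.gt == 2:
        ok = call.dp >= 1 and call.alt_reads / call.dp >= 0.8
        checks.append(("hom-allele-fraction", ok))
    return checks


def collapsing_site_filter(
    v: VariantRecord, calls: list[GenotypeCall]
) -> list[FilterDecision]:
    """Apply the gene-level collapsing filter stack to every genotype at a site.

    Site-level metric failures are recorded on every genotype decision;
    genotype-level rules (depth, genotype quality, heterozygous allele
    balance) are evaluated per call.  A rule whose metric is missing is
    recorded both as failed (conservative) and as unevaluable.
    """
    site_failed: list[str] = []
    site_unevaluable: list[str] = []
    for rule, value, ok in _site_rule_checks(v):
        if value is None:
            site_failed.append(rule)
            site_unevaluable.append(rule)
        elif not ok:
            site_failed.append(rule)
    decisions = []
    for call in calls:
        failed = list(site_failed)
        for rule, ok in _genotype_rule_checks(call, hom_alt_rule=False):
            if not ok:
                failed.append(rule)
        decisions.append(
            FilterDecision(
                variant_key=v.variant_key,
                sample_id=call.sample_id,
                failed_rules=failed,
                unevaluable_rules=list(site_unevaluable),
            )
        )
    return decisions


def exwas_genotype_filter(v: VariantRecord, call: GenotypeCall) -> FilterDecision:
    """Per-genotype rules of the ExWAS stack: the collapsing genotype rules
    plus the requirement that homozygous-alt calls carry >=80% alt reads."""
    failed = [
        rule for rule, ok in _genotype_rule_checks(call, hom_alt_rule=True) if not ok
    ]
    return FilterDecision(
        variant_key=v.variant_key, sample_id=call.sample_id, failed_rules=failed
    )


def exwas_site_filter(
    v: VariantRecord,
    calls: list[GenotypeCall],
    max_low_coverage_fraction: float = 0.01,
    max_genotype_failure_fraction: float = 0.005,
    hwe_alpha: float = 1e-10,
) -> FilterDecision:
    """Apply the single-variant (ExWAS) site filter stack.

    On top of the collapsing site metric rules the variant is excluded when

    * >=1% of samples have DP < 10 at the site,
    * more than 0.5% of genotypes fail any genotype-level rule,
    * the site reached >=10x coverage in <=50% of gnomAD exomes, or
    * the Hardy-Weinberg exact test gives p < 1e-10 (computed on
      non-missing genotypes).
    """
    if not calls or all(c.gt is None for c in calls):
        raise ValueError("exwas_site_filter requires at least one non-missing genotype")
    failed: list[str] = []
    unevaluable: list[str] = []
    for rule, value, ok in _site_rule_checks(v):
        if rule == "gnomad-coverage":
            continue  # the ExWAS stack uses its own, stricter coverage rule
        if value is None:
            failed.append(rule)
            unevaluable.append(rule)
        elif not ok:
            failed.append(rule)

    n = len(calls)
    low_cov = sum(1 for c in calls if c.dp < 10)
    if low_cov / n >= max_low_coverage_fraction:
        failed.append("site-low-coverage")

    n_fail = sum(1 for c in calls if not exwas_genotype_filter(v, c).passed)
    if n_fail / n > max_genotype_failure_fraction:
        failed.append("genotype-failure-rate")

    if not (
        v.gnomad_cov10_fraction is not None and v.gnomad_cov10_fraction > 0.5
    ):
        failed.append("gnomad-coverage-50")

    counts = {0: 0, 1: 0, 2: 0}
    for c in calls:
        if c.gt is not None:
            counts[c.gt] += 1
    if hwe_exact_test(counts[0], counts[1], counts[2]) < hwe_alpha:
        failed.append("hwe")

    return FilterDecision(
        variant_key=v.variant_key, failed_rules=failed, unevaluable_rules=unevaluable
    )


def imputation_info_filter(info: float) -> bool:
    """Imputed-array cohorts only: retain a variant iff imputation INFO >= 0.6."""
    if not 0.0 <= info <= 1.0:
        raise ValueError(f"imputation INFO must be in [0, 1], got {info}")
    return info >= 0.6
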