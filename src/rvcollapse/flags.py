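"""Somatic-artifact detection and significance thresholds.

Blood-derived clonal somatic mutations (clonal haematopoiesis, e.g. in
*TET2*) can masquerade as germline qualifying variants.  Two orthogonal
signatures identify them in cohort data: carrier status correlates with
age, and the heterozygous alternate-read fraction is skewed below the 50%
expected for a germline heterozygote.  A gene is flagged only when both
signatures are significant at their configured alphas.

Also here: exome-wide Bonferroni significance thresholds and tier
annotation for gene-level results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "Thresholds",
    "compute_thresholds",
    "significance_tier",
    "age_carrier_association",
    "alt_fraction_skew",
    "SomaticFlagResult",
    "somatic_artifact_flag",
]

#: Default number of consensus protein-coding genes tested exome-wide.
DEFAULT_N_GENES = 18948


@dataclass(frozen=True)
class Thresholds:
    """Significance thresholds for gene-level testing."""

    suggestive: float
    study_wide: float
    n_genes_tested: int

    def __post_init__(self) -> None:
        if not self.study_wide < self.suggestive:
            raise ValueError("study-wide threshold must be below the suggestive one")


def _round_2_sig_figs(x: float) -> float:
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round(x, -exp + 1)


def compute_thresholds(n_genes: int = DEFAULT_N_GENES) -> Thresholds:
    """Suggestive threshold = 0.05/n_genes rounded to two significant
    figures (exome-wide Bonferroni); study-wide threshold fixed at 1e-8."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return Thresholds(
        suggestive=_round_2_sig_figs(0.05 / n_genes),
        study_wide=1e-8,
        n_genes_tested=n_genes,
    )


def significance_tier(p: float, thresholds: Thresholds) -> str:
    """Tier annotation; thresholds are strict (p equal to a threshold is
    not significant)."""
    if p < thresholds.study_wide:
        return "study-wide"
    if p < thresholds.suggestive:
        return "suggestive"
    return "ns"


def age_carrier_association(
    carrier_ages,
    noncarrier_ages,
    method: str = "ranksum",
) -> float:
    """Two-sided test for an age difference between carriers and non-carriers.

    The default is the rank-based Mann-Whitney U test (assumption-light;
    exact for small groups, normal approximation otherwise).
    ``method="logistic"`` instead fits a Firth logistic regression of
    carrier status on age and reports the age-coefficient p-value.
    Degenerate groups (<2 observations on either side) give p = 1.
    """
    carrier_ages = np.asarray(carrier_ages, dtype=float)
    noncarrier_ages = np.asarray(noncarrier_ages, dtype=float)
    if len(carrier_ages) < 2 or len(noncarrier_ages) < 2:
        return 1.0
    if method == "ranksum":
        res = stats.mannwhitneyu(
            carrier_ages, noncarrier_ages, alternative="two-sided"
        )
        return float(res.pvalue)
    if method == "logistic":
        from .association import firth_logistic  # deferred: avoids cycle

        y = np.concatenate(
            [np.ones(len(carrier_ages)), np.zeros(len(noncarrier_ages))]
        )
        age = np.concatenate([carrier_ages, noncarrier_ages])
        X = np.column_stack([np.ones_like(age), (age - age.mean()) / age.std()])
        fit = firth_logistic(y, X, exog_names=("const", "age"))
        return float(fit.pvalues[1])
    raise ValueError(f"unknown method {method!r}")


def alt_fraction_skew(het_calls) -> tuple[float, float]:
    """Pooled one-sided test for alt-read fractions skewed below 50%.

    ``het_calls`` is a sequence of ``(alt_reads, dp)`` pairs from a gene's
    heterozygous qualifying-variant calls.  Returns ``(median per-call
    fraction, skew p)`` where the p-value is the one-sided binomial
    probability of observing at most the pooled alt-read total at
    fraction 0.5.  Germline heterozygotes centre at 0.5; somatic
    contamination drags the fraction below it.
    """
    calls = list(het_calls)
    if not calls:
        raise ValueError("alt_fraction_skew requires at least one het call")
    alts = np.array([a for a, _ in calls], dtype=np.int64)
    dps = np.array([d for _, d in calls], dtype=np.int64)
    if np.any(dps <= 0):
        raise ValueError("all het calls must have depth > 0")
    if np.any(alts < 0) or np.any(alts > dps):
        raise ValueError("alt_reads must be within [0, dp]")
    median_fraction = float(np.median(alts / dps))
    p = float(stats.binom.cdf(int(alts.sum()), int(dps.sum()), 0.5))
    return median_fraction, p


@dataclass(frozen=True)
class SomaticFlagResult:
    """Somatic-artifact assessment for one (gene, QV model)."""

    gene: str
    qv_model: str
    age_association_p: float
    median_het_alt_fraction: float
    skew_p: float
    flagged: bool


def somatic_artifact_flag(
    gene: str,
    qv_model: str,
    carrier_ages,
    noncarrier_ages,
    het_calls,
    age_alpha: float = 1e-3,
    skew_alpha: float = 1e-3,
    age_method: str = "ranksum",
) -> SomaticFlagResult:
    """Flag a gene as a putative somatic (clonal haematopoiesis) artifact.

    Flagged iff the carrier-age association AND the alt-fraction skew are
    both significant at their alphas (defaults 1e-3 each).
    """
    age_p = age_carrier_association(carrier_ages, noncarrier_ages, method=age_method)
    median_fraction, skew_p = alt_fraction_skew(het_calls)
    return SomaticFlagResult(
        gene=gene,
        qv_model=qv_model,
        age_association_p=age_p,
        median_het_alt_fraction=median_fraction,
        skew_p=skew_p,
        flagged=(age_p < age_alpha) and (skew_p < skew_alpha),
    )
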