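"""Single-variant exome-wide association (ExWAS) and meta-analysis.

Each variant is tested with the two-sided Fisher exact test under three
genetic models built from alt-allele dosages (X = alternate, Y = reference
allele): dominant (XX+XY vs YY), allelic (X vs Y) and recessive (XX vs
XY+YY).  Across cohorts, allelic/additive results combine with the
sample-size-weighted Stouffer z-score method (effective N = 4/(1/n_cases +
1/n_controls)); dominant and recessive results combine with the
Cochran-Mantel-Haenszel test.  Genomic inflation is estimated by
regressing observed test statistics on an empirical null built from
case-control label permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import (
    StratumTables,
    Table2x2,
    cmh_test,
    fisher_exact_two_sided,
    mh_odds_ratio_ci,
)

__all__ = [
    "GENETIC_MODELS",
    "GeneticModelTable",
    "genotype_model_tables",
    "variant_scan",
    "CohortStat",
    "MetaResult",
    "stouffer_meta",
    "cmh_variant_meta",
    "InflationResult",
    "permutation_lambda",
    "collapsing_lambda",
    "ExwasModel",
    "ExwasResults",
]

GENETIC_MODELS = ("dominant", "allelic", "recessive")


@dataclass(frozen=True)
class GeneticModelTable:
    """A 2x2 table for one variant under one genetic model."""

    model: str
    table: Table2x2
    flags: tuple[str, ...] = ()


def genotype_model_tables(
    genotypes, status, allow_hom: bool = True
) -> dict[str, GeneticModelTable]:
    """Build the three genetic-model 2x2 tables for one variant.

    ``genotypes`` are alt-allele dosages (0/1/2, NaN missing) aligned with
    ``status`` (1 = case, 0 = control).  Missing genotypes are dropped.
    ``allow_hom=False`` marks hemizygous-style input: the recessive table is
    emptied and flagged.
    """
    gt = np.asarray(genotypes, dtype=float)
    st_arr = np.asarray(status, dtype=float)
    ok = ~np.isnan(gt)
    if not ok.any():
        raise ValueError("all genotypes missing for variant")
    gt, st_arr = gt[ok], st_arr[ok]
    case = st_arr == 1
    out: dict[str, GeneticModelTable] = {}

    n_case, n_ctrl = int(case.sum()), int((~case).sum())
    carrier = gt >= 1
    out["dominant"] = GeneticModelTable(
        "dominant",
        Table2x2(
            int((carrier & case).sum()),
            int((~carrier & case).sum()),
            int((carrier & ~case).sum()),
            int((~carrier & ~case).sum()),
        ),
    )
    alt_case = int(gt[case].sum())
    alt_ctrl = int(gt[~case].sum())
    out["allelic"] = GeneticModelTable(
        "allelic",
        Table2x2(alt_case, 2 * n_case - alt_case, alt_ctrl, 2 * n_ctrl - alt_ctrl),
    )
    if allow_hom:
        hom = gt == 2
        out["recessive"] = GeneticModelTable(
            "recessive",
            Table2x2(
                int((hom & case).sum()),
                int((~hom & case).sum()),
                int((hom & ~case).sum()),
                int((~hom & ~case).sum()),
            ),
        )
    else:
        out["recessive"] = GeneticModelTable(
            "recessive", Table2x2(0, 0, 0, 0), flags=("hemizygous-no-recessive",)
        )
    return out


def variant_scan(
    genotype_matrix: pd.DataFrame,
    status,
    models=GENETIC_MODELS,
) -> pd.DataFrame:
    """Per-variant Fisher exact association under the requested genetic
    models.  Returns one row per (variant, model) with p, sample OR,
    carrier counts and MAF."""
    status = np.asarray(status, dtype=float)
    rows = []
    for key in genotype_matrix.columns:
        gt = genotype_matrix[key].to_numpy(dtype=float)
        ok = ~np.isnan(gt)
        maf = float(gt[ok].sum() / (2 * ok.sum())) if ok.any() else float("nan")
        tables = genotype_model_tables(gt, status)
        for model in models:
            t = tables[model].table
            p = fisher_exact_two_sided(t)
            direction = _direction_of_effect(t)
            rows.append(
                {
                    "variant_key": key,
                    "model": model,
                    "p": p,
                    "direction": direction,
                    "a": t.a,
                    "b": t.b,
                    "c": t.c,
                    "d": t.d,
                    "maf": maf,
                    "n_cases": t.n_cases,
                    "n_controls": t.n_controls,
                }
            )
    return pd.DataFrame(rows)


def _direction_of_effect(t: Table2x2) -> int:
    """Sign of the sample log OR; zero cells get a 0.5 correction (for
    direction determination only)."""
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return 1 if a * d >= b * c else -1


@dataclass(frozen=True)
class CohortStat:
    """One cohort's summary statistic for a variant."""

    p: float
    direction: int  # +1 risk, -1 protective
    n_cases: int
    n_controls: int
    cohort: str = ""


@dataclass(frozen=True)
class MetaResult:
    variant_key: str
    z: float
    p: float
    cohorts_used: tuple[str, ...]
    flags: tuple[str, ...] = ()


def stouffer_meta(cohort_stats, variant_key: str = "") -> MetaResult:
    """Sample-size-weighted Stouffer meta-analysis (METAL convention).

    Per cohort ``z_i = sign(direction) * Phi^-1(1 - p_i/2)`` and weight
    ``w_i = sqrt(Neff_i)`` with ``Neff = 4/(1/n_cases + 1/n_controls)``;
    the combined ``Z = sum(w z)/sqrt(sum w^2)`` and ``p = 2 Phi(-|Z|)``.
    A p of exactly 0 is clipped to the smallest positive float with a
    warning.
    """
    cohort_stats = list(cohort_stats)
    if not cohort_stats:
        raise ValueError("stouffer_meta requires at least one cohort")
    flags: list[str] = []
    zs, ws, used = [], [], []
    for cs in cohort_stats:
        p = cs.p
        if p < 1e-300:
            # smallest input that still maps to a finite normal quantile
            p = 1e-300
            flags.append("p-clipped")
            warnings.warn("stouffer_meta: p=0 clipped", stacklevel=2)
        p = min(p, 1.0)
        z = float(np.sign(cs.direction) * stats.norm.isf(p / 2.0))
        neff = 4.0 / (1.0 / cs.n_cases + 1.0 / cs.n_controls)
        zs.append(z)
        ws.append(np.sqrt(neff))
        used.append(cs.cohort)
    zs_arr, ws_arr = np.asarray(zs), np.asarray(ws)
    Z = float(np.sum(ws_arr * zs_arr) / np.sqrt(np.sum(ws_arr**2)))
    p_comb = float(min(1.0, 2.0 * stats.norm.sf(abs(Z))))
    return MetaResult(
        variant_key=variant_key,
        z=Z,
        p=p_comb,
        cohorts_used=tuple(used),
        flags=tuple(dict.fromkeys(flags)),
    )


def cmh_variant_meta(stratified_tables, model: str = "dominant"):
    """CMH meta-analysis of one genetic model's 2x2 tables across sequenced
    cohorts.  ``stratified_tables`` is a list of (cohort label,
    GeneticModelTable or Table2x2)."""
    items = []
    for label, t in stratified_tables:
        table = t.table if isinstance(t, GeneticModelTable) else t
        items.append((label, table))
    s = StratumTables.from_list(items)
    return cmh_test(s), mh_odds_ratio_ci(s)


@dataclass(frozen=True)
class InflationResult:
    label: str
    lambda_: float
    n_permutations: int
    n_tests: int
    slope_stderr: float


def _chi2_quantiles(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    return stats.chi2.isf(p, 1)


def permutation_lambda(
    observed_p,
    permuted_p,
    label: str = "",
) -> InflationResult:
    """Genomic-inflation factor from a permutation-derived empirical null.

    ``permuted_p`` has one row per label permutation, each the same test
    battery recomputed under permuted case-control labels.  The expected p
    distribution is the rank-wise mean of each permutation's sorted
    -log10 p values; observed and expected p are mapped to chi-square(1)
    quantiles and lambda is the slope of the origin-anchored regression of
    observed on expected quantiles.  lambda = 1 exactly when observed and
    expected distributions coincide.
    """
    obs = np.sort(np.asarray(observed_p, dtype=float))[::-1]  # ascending -log10
    perm = np.asarray(permuted_p, dtype=float)
    if perm.ndim != 2 or perm.shape[0] < 1:
        raise ValueError("permuted_p must be a (n_perm, n_tests) array with n_perm >= 1")
    if perm.shape[1] != obs.shape[0]:
        raise ValueError("permuted battery size differs from observed")
    neglog = -np.log10(np.clip(perm, np.nextafter(0.0, 1.0), 1.0))
    expected_neglog = np.mean(np.sort(neglog, axis=1), axis=0)  # ascending
    expected_p = 10.0 ** (-expected_neglog)
    # obs sorted descending in p == ascending in -log10, aligning ranks with expected
    x = _chi2_quantiles(expected_p)
    y = _chi2_quantiles(obs)
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise ValueError("expected quantiles are all zero")
    lam = float(np.sum(x * y) / sxx)
    resid = y - lam * x
    dof = max(1, len(x) - 1)
    se = float(np.sqrt(np.sum(resid**2) / dof / sxx))
    return InflationResult(
        label=label,
        lambda_=lam,
        n_permutations=perm.shape[0],
        n_tests=perm.shape[1],
        slope_stderr=se,
    )


def _cmh_p_vectorised(a, n_case, n_ctrl, carriers_total) -> np.ndarray:
    """Single-stratum CMH (= 1-df MH chi-square) p-values, vectorised over
    genes, from carrier counts in cases (a) with fixed margins."""
    n = n_case + n_ctrl
    e = n_case * carriers_total / n
    v = (
        n_case
        * n_ctrl
        * carriers_total
        * (n - carriers_total)
        / (n * n * (n - 1.0))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(v > 0, (a - e) ** 2 / v, 0.0)
    return stats.chi2.sf(stat, 1)


def collapsing_lambda(
    carrier_matrix,
    status,
    n_perm: int = 10,
    rng: np.random.Generator | None = None,
    label: str = "",
) -> InflationResult:
    """Permutation-based lambda for a gene-level collapsing test battery.

    Computes the collapsing association p per gene column under the real
    case-control labels, then under ``n_perm`` label permutations, and
    feeds both into :func:`permutation_lambda`.  Seed via ``rng``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    data = getattr(carrier_matrix, "data", carrier_matrix)
    carr = np.asarray(data, dtype=float)
    status = np.asarray(status, dtype=float)
    n_case = int(status.sum())
    n_ctrl = int(len(status) - n_case)
    totals = carr.sum(axis=0)
    a_obs = status @ carr
    obs_p = _cmh_p_vectorised(a_obs, n_case, n_ctrl, totals)
    perm_p = np.empty((n_perm, carr.shape[1]))
    for i in range(n_perm):
        perm = rng.permutation(status)
        perm_p[i] = _cmh_p_vectorised(perm @ carr, n_case, n_ctrl, totals)
    return permutation_lambda(obs_p, perm_p, label=label)


class ExwasModel:
    """Single-variant exome-wide association model for one cohort.

    ``fit`` runs the Fisher scan under the requested genetic models and
    returns an :class:`ExwasResults` whose frame doubles as the per-cohort
    summary-statistic exchange format for the meta step.
    """

    def __init__(self, genotype_matrix: pd.DataFrame, status, models=GENETIC_MODELS):
        unknown = set(models) - set(GENETIC_MODELS)
        if unknown:
            raise ValueError(f"unknown genetic models: {sorted(unknown)}")
        self.genotype_matrix = genotype_matrix
        self.status = np.asarray(status, dtype=float)
        self.models = tuple(models)

    def fit(self) -> "ExwasResults":
        return ExwasResults(self, variant_scan(self.genotype_matrix, self.status, self.models))


@dataclass
class ExwasResults:
    model: ExwasModel
    table: pd.DataFrame = field(repr=False)

    def summary(self, top: int = 20) -> str:
        lines = [
            "Single-variant exome-wide association (Fisher exact)",
            f"models: {', '.join(self.model.models)}   "
            f"n = {len(self.model.status)} samples, "
            f"{self.table['variant_key'].nunique()} variants",
            "-" * 78,
        ]
        cols = ["variant_key", "model", "p", "direction", "a", "c", "maf"]
        head = self.table.sort_values("p", kind="mergesort")[cols].head(top)
        lines.append(head.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()
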