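"""Gene-level association testing on collapsed carrier tables.

Each cohort/ancestry stratum contributes one 2x2 table of carrier status by
phenotype group.  Within strata, association is assessed with the two-sided
Fisher exact test; across strata with the Cochran-Mantel-Haenszel (CMH)
test, reporting the Mantel-Haenszel pooled odds ratio with a
Robins-Breslow-Greenland (RBG) confidence interval.  A Firth
penalized-likelihood logistic regression is provided as a
covariate-adjusted sensitivity analysis.

Three case/control contrasts are supported: overall risk (all cases vs
controls), severity (aggressive vs non-aggressive cases), and aggressive
cases vs controls.

The statsmodels-style entry point is :class:`CollapsingModel`, whose
``fit`` returns a :class:`CollapsingResults` carrying the per-gene results
table and a ``summary()``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logsumexp
from scipy.stats import hypergeom

from .flags import Thresholds, compute_thresholds, significance_tier

__all__ = [
    "Table2x2",
    "StratumTables",
    "fisher_exact_two_sided",
    "CMHResult",
    "cmh_test",
    "MHOddsRatio",
    "mh_odds_ratio_ci",
    "FirthResult",
    "firth_logistic",
    "gene_collapsing_scan",
    "CollapsingModel",
    "CollapsingResults",
    "CONTRASTS",
]

_MINLIKE_RTOL = 1e-7

#: Supported case/control contrasts.
CONTRASTS = ("PCa_vs_Ctrl", "Agg_vs_nonAgg", "Agg_vs_Ctrl")


@dataclass(frozen=True)
class Table2x2:
    """A carrier-by-status 2x2 table.

    ``a``/``b`` are carriers/non-carriers in the first group (cases), ``c``/``d``
    in the second group (controls).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 table counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    @property
    def case_carrier_freq(self) -> float:
        return self.a / self.n_cases if self.n_cases else float("nan")

    @property
    def control_carrier_freq(self) -> float:
        return self.c / self.n_controls if self.n_controls else float("nan")

    def swapped(self) -> "Table2x2":
        """Swap group labels (cases <-> controls)."""
        return Table2x2(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class StratumTables:
    """An ordered set of 2x2 tables, one per cohort/ancestry stratum."""

    tables: tuple[tuple[str, Table2x2], ...]

    def __post_init__(self) -> None:
        if len(self.tables) < 1:
            raise ValueError("at least one stratum is required")
        labels = [lab for lab, _ in self.tables]
        if len(set(labels)) != len(labels):
            raise ValueError("stratum labels must be unique")

    @classmethod
    def from_list(cls, items) -> "StratumTables":
        return cls(tuple((str(lab), t) for lab, t in items))

    def __iter__(self):
        return iter(self.tables)

    def __len__(self) -> int:
        return len(self.tables)


def fisher_exact_two_sided(t: Table2x2) -> float:
    """Two-sided Fisher exact test p-value for a 2x2 table.

    Sums, over the hypergeometric support of the top-left cell given fixed
    margins, the point probabilities not exceeding the observed one
    (minimum-likelihood convention), in log space.  Degenerate margins give
    p = 1.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    k_carrier = a + c
    n_cases = a + b
    if min(k_carrier, n - k_carrier, n_cases, n - n_cases) == 0 or n == 0:
        return 1.0
    lo = max(0, k_carrier - (c + d))
    hi = min(k_carrier, n_cases)
    support = np.arange(lo, hi + 1)
    logpmf = hypergeom.logpmf(support, n, k_carrier, n_cases)
    obs = logpmf[a - lo]
    keep = logpmf <= obs + math.log1p(_MINLIKE_RTOL)
    if keep.all():
        return 1.0
    return float(min(1.0, math.exp(logsumexp(logpmf[keep]))))


@dataclass(frozen=True)
class CMHResult:
    statistic: float
    p: float
    dof: int = 1
    n_strata: int = 0
    flags: tuple[str, ...] = ()
    method: str = "asymptotic"


def _cmh_components(s: StratumTables) -> tuple[float, float, float, int]:
    """Return (sum a, sum E[a], sum Var[a], informative strata count)."""
    sa = se = sv = 0.0
    used = 0
    for _, t in s:
        n = t.n
        if n == 0:
            continue
        r1, r2 = t.a + t.b, t.c + t.d
        c1, c2 = t.a + t.c, t.b + t.d
        if min(r1, r2, c1, c2) == 0 or n < 2:
            # margin-degenerate stratum: E == a and Var == 0, contributes nothing
            continue
        sa += t.a
        se += r1 * c1 / n
        sv += r1 * r2 * c1 * c2 / (n * n * (n - 1))
        used += 1
    return sa, se, sv, used


def cmh_test(
    s: StratumTables,
    continuity: float = 0.0,
    method: str = "asymptotic",
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
) -> CMHResult:
    """Cochran-Mantel-Haenszel test of association across 2x2 strata.

    The 1-df statistic is ``(|sum(a - E[a])| - cc)^2 / sum(Var[a])`` with
    expectations and variances conditional on stratum margins; by default no
    continuity correction is applied and the p-value is two-sided from
    chi-square(1).  ``method="permutation"`` instead compares the observed
    statistic with stratified label permutations (equivalently, conditional
    hypergeometric draws of each stratum's carrier split), for sparse
    tables.  Strata with all-zero totals or degenerate margins are dropped.
    """
    flags: list[str] = []
    n_total = len(s)
    sa, se, sv, used = _cmh_components(s)
    if used < n_total:
        flags.append("degenerate-strata-dropped")
        warnings.warn(
            f"cmh_test: dropped {n_total - used} degenerate stratum/strata",
            stacklevel=2,
        )
    if used == 0 or sv <= 0:
        return CMHResult(0.0, 1.0, n_strata=0, flags=(*flags, "all-degenerate"))
    dev = abs(sa - se) - continuity
    stat = max(dev, 0.0) ** 2 / sv
    if method == "asymptotic":
        p = float(stats.chi2.sf(stat, 1))
        return CMHResult(float(stat), p, n_strata=used, flags=tuple(flags))
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng() if rng is None else rng
    # Conditional on margins, each stratum's a is hypergeometric.
    draws = np.zeros(n_perm)
    exp_total = 0.0
    var_total = sv
    for _, t in s:
        n = t.n
        r1, c1 = t.a + t.b, t.a + t.c
        if n < 2 or min(r1, n - r1, c1, n - c1) == 0:
            continue
        draws += rng.hypergeometric(c1, n - c1, r1, size=n_perm)
        exp_total += r1 * c1 / n
    perm_stat = (draws - exp_total) ** 2 / var_total
    p = (1.0 + np.sum(perm_stat >= stat - 1e-12)) / (n_perm + 1.0)
    return CMHResult(
        float(stat), float(p), n_strata=used, flags=tuple(flags), method="permutation"
    )


@dataclass(frozen=True)
class MHOddsRatio:
    or_mh: float
    ci_low: float
    ci_high: float
    se_log_or: float
    flags: tuple[str, ...] = ()


def mh_odds_ratio_ci(s: StratumTables, alpha: float = 0.05) -> MHOddsRatio:
    """Mantel-Haenszel pooled odds ratio with RBG confidence interval.

    ``OR_MH = sum(a_i d_i / n_i) / sum(b_i c_i / n_i)``; the CI uses the
    Robins-Breslow-Greenland variance estimate of log OR.  A zero
    denominator yields an infinite OR with an undefined CI (flagged).
    """
    R = S = 0.0
    sPR = sPSQR = sQS = 0.0
    for _, t in s:
        n = t.n
        if n == 0:
            continue
        P = (t.a + t.d) / n
        Q = (t.b + t.c) / n
        Ri = t.a * t.d / n
        Si = t.b * t.c / n
        R += Ri
        S += Si
        sPR += P * Ri
        sPSQR += P * Si + Q * Ri
        sQS += Q * Si
    if S == 0.0:
        if R == 0.0:
            return MHOddsRatio(
                float("nan"), float("nan"), float("nan"), float("nan"),
                flags=("no-informative-tables",),
            )
        return MHOddsRatio(
            float("inf"), float("nan"), float("nan"), float("nan"),
            flags=("infinite-or",),
        )
    or_mh = R / S
    if R == 0.0:
        return MHOddsRatio(0.0, float("nan"), float("nan"), float("nan"), flags=("zero-or",))
    var = sPR / (2 * R * R) + sPSQR / (2 * R * S) + sQS / (2 * S * S)
    se = math.sqrt(var)
    z = stats.norm.isf(alpha / 2)
    log_or = math.log(or_mh)
    return MHOddsRatio(
        or_mh, math.exp(log_or - z * se), math.exp(log_or + z * se), se
    )


# ---------------------------------------------------------------------------
# Firth penalized logistic regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FirthResult:
    """Firth logistic fit: penalized-likelihood estimates with per-coefficient
    penalized likelihood-ratio p-values."""

    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    loglike_penalized: float
    n_iter: int
    converged: bool
    exog_names: tuple[str, ...] = ()


def _firth_fit(
    y: np.ndarray,
    X: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
    fixed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    """Maximise the Jeffreys-penalized log-likelihood.

    With ``fixed=j`` the coefficient j is constrained to zero while the
    penalty keeps the full design's information determinant — the profile
    fit the penalized likelihood-ratio test needs.
    """
    n, k = X.shape
    free = np.array([j for j in range(k) if j != fixed])
    beta = np.zeros(k)

    def penalized_loglike(b):
        eta = X @ b
        # log-likelihood in a numerically safe form
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        p = expit(eta)
        W = p * (1 - p)
        XtWX = X.T @ (X * W[:, None])
        sign, logdet = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return -np.inf, XtWX
        return ll + 0.5 * logdet, XtWX

    pl, XtWX = penalized_loglike(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(X @ beta)
        W = p * (1 - p)
        XtWX = X.T @ (X * W[:, None])
        try:
            XtWX_inv = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError as exc:
            raise ValueError("design matrix is singular") from exc
        h = np.einsum("ij,jk,ik->i", X, XtWX_inv, X) * W
        score = X.T @ (y - p + h * (0.5 - p))
        if np.linalg.norm(score[free]) < tol:
            converged = True
            break
        step = np.zeros(k)
        step[free] = np.linalg.solve(XtWX[np.ix_(free, free)], score[free])
        # step-halving on the penalized likelihood
        new_pl, _ = penalized_loglike(beta + step)
        halvings = 0
        while new_pl < pl - 1e-12 and halvings < 25:
            step *= 0.5
            new_pl, _ = penalized_loglike(beta + step)
            halvings += 1
        beta = beta + step
        pl = new_pl
    pl, XtWX = penalized_loglike(beta)
    cov = np.linalg.inv(XtWX)
    return beta, cov, pl, it, converged


def firth_logistic(
    y,
    X,
    exog_names: tuple[str, ...] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
    lrt: bool = True,
) -> FirthResult:
    """Firth (Jeffreys-prior penalized) logistic regression.

    Newton iterations on the modified score run until the gradient norm
    drops below ``tol`` (default 1e-8) or ``max_iter`` (default 100)
    iterations; non-convergence is flagged on the result, never silent.
    Per-coefficient p-values come from the penalized likelihood-ratio test
    (refit with the coefficient constrained out); set ``lrt=False`` for the
    faster Wald p-values.  Finite estimates are returned under complete
    separation, which is the point of the penalty.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if n <= k:
        raise ValueError("firth_logistic requires more observations than parameters")
    if exog_names is None:
        exog_names = tuple(f"x{j}" for j in range(k))
    beta, cov, pl_full, n_iter, converged = _firth_fit(y, X, max_iter, tol)
    bse = np.sqrt(np.diag(cov))
    pvalues = np.empty(k)
    if lrt:
        for j in range(k):
            _, _, pl_red, _, _ = _firth_fit(y, X, max_iter, tol, fixed=j)
            lr = max(0.0, 2.0 * (pl_full - pl_red))
            pvalues[j] = stats.chi2.sf(lr, 1)
    else:
        z = beta / bse
        pvalues = 2 * stats.norm.sf(np.abs(z))
    if not converged:
        warnings.warn("firth_logistic did not converge", stacklevel=2)
    return FirthResult(
        params=beta,
        bse=bse,
        pvalues=pvalues,
        loglike_penalized=pl_full,
        n_iter=n_iter,
        converged=converged,
        exog_names=tuple(exog_names),
    )


# ---------------------------------------------------------------------------
# Gene-level scan
# ---------------------------------------------------------------------------


def _contrast_groups(phenotypes: pd.DataFrame, contrast: str):
    """Return (group1 mask, group2 mask) over the phenotype frame."""
    status = phenotypes["status"].astype(str)
    if contrast == "PCa_vs_Ctrl":
        return status == "case", status == "control"
    agg = pd.to_numeric(phenotypes.get("aggressive"), errors="coerce")
    if contrast == "Agg_vs_nonAgg":
        return (status == "case") & (agg == 1), (status == "case") & (agg == 0)
    if contrast == "Agg_vs_Ctrl":
        return (status == "case") & (agg == 1), status == "control"
    raise ValueError(f"unknown contrast {contrast!r}; expected one of {CONTRASTS}")


def stratum_tables_for(
    carrier: pd.Series, phenotypes: pd.DataFrame, contrast: str
) -> StratumTables:
    """Build per-stratum 2x2 tables for one gene x model carrier column."""
    g1, g2 = _contrast_groups(phenotypes, contrast)
    if not g1.any() or not g2.any():
        raise ValueError(f"contrast {contrast}: one of the groups is empty")
    carrier = carrier.reindex(phenotypes.index).fillna(False).astype(bool)
    items = []
    for stratum, idx in phenotypes.groupby("stratum", sort=True).groups.items():
        in1 = g1.loc[idx]
        in2 = g2.loc[idx]
        carr = carrier.loc[idx]
        a = int((carr & in1).sum())
        b = int((~carr & in1).sum())
        c = int((carr & in2).sum())
        d = int((~carr & in2).sum())
        if a + b + c + d == 0:
            continue
        items.append((stratum, Table2x2(a, b, c, d)))
    if not items:
        raise ValueError("no informative strata for contrast")
    return StratumTables.from_list(items)


def gene_collapsing_scan(
    matrix,
    phenotypes: pd.DataFrame,
    contrast: str = "PCa_vs_Ctrl",
    thresholds: Thresholds | None = None,
    cmh_method: str = "asymptotic",
) -> pd.DataFrame:
    """Run the gene-level collapsing association scan for one contrast.

    ``matrix`` is a :class:`~rvcollapse.qv.CarrierMatrix` (or a boolean
    DataFrame indexed by sample with ``gene.model`` columns); ``phenotypes``
    must carry ``stratum``, ``status`` and (for severity contrasts)
    ``aggressive`` columns indexed by sample id.  Returns one row per
    (gene, model): per-stratum Fisher p-values, the CMH meta p, the MH OR
    with RBG CI, carrier frequencies, and significance-tier annotation.
    Results are sorted by meta p-value.
    """
    data = getattr(matrix, "data", matrix)
    if thresholds is None:
        thresholds = compute_thresholds()
    rows = []
    for col in data.columns:
        gene, model = str(col).rsplit(".", 1)
        s = stratum_tables_for(data[col], phenotypes, contrast)
        cmh = cmh_test(s, method=cmh_method)
        mh = mh_odds_ratio_ci(s)
        a = sum(t.a for _, t in s)
        b = sum(t.b for _, t in s)
        c = sum(t.c for _, t in s)
        d = sum(t.d for _, t in s)
        per_stratum_p = {lab: fisher_exact_two_sided(t) for lab, t in s}
        rows.append(
            {
                "gene": gene,
                "qv_model": model,
                "contrast": contrast,
                "n_group1": a + b,
                "n_group2": c + d,
                "carriers_group1": a,
                "carriers_group2": c,
                "carrier_freq_group1": a / (a + b) if a + b else float("nan"),
                "carrier_freq_group2": c / (c + d) if c + d else float("nan"),
                "p_cmh": cmh.p,
                "cmh_statistic": cmh.statistic,
                "or_mh": mh.or_mh,
                "ci_low": mh.ci_low,
                "ci_high": mh.ci_high,
                "n_strata": len(s),
                "per_stratum_p": per_stratum_p,
                "tier": significance_tier(cmh.p, thresholds),
                "flags": ",".join((*cmh.flags, *mh.flags)),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["p_cmh", "gene", "qv_model"], kind="mergesort")
        out = out.reset_index(drop=True)
    return out


class CollapsingModel:
    """Gene-level collapsing association model.

    Parameters
    ----------
    carrier_matrix
        :class:`~rvcollapse.qv.CarrierMatrix` or boolean DataFrame
        (samples x ``gene.model`` columns).
    phenotypes
        DataFrame indexed by sample id with ``stratum``, ``status`` and
        optionally ``aggressive`` columns.
    contrast
        One of ``PCa_vs_Ctrl`` (risk), ``Agg_vs_nonAgg`` (severity),
        ``Agg_vs_Ctrl``.
    """

    def __init__(
        self,
        carrier_matrix,
        phenotypes: pd.DataFrame,
        contrast: str = "PCa_vs_Ctrl",
        thresholds: Thresholds | None = None,
    ):
        if contrast not in CONTRASTS:
            raise ValueError(f"unknown contrast {contrast!r}")
        self.carrier_matrix = carrier_matrix
        self.phenotypes = phenotypes
        self.contrast = contrast
        self.thresholds = thresholds or compute_thresholds()

    @classmethod
    def from_dataframes(cls, carrier_df, phenotype_df, **kwargs):
        return cls(carrier_df, phenotype_df, **kwargs)

    def fit(self, cmh_method: str = "asymptotic") -> "CollapsingResults":
        table = gene_collapsing_scan(
            self.carrier_matrix,
            self.phenotypes,
            self.contrast,
            thresholds=self.thresholds,
            cmh_method=cmh_method,
        )
        return CollapsingResults(self, table)


@dataclass
class CollapsingResults:
    """Results of a gene-level collapsing scan."""

    model: CollapsingModel
    table: pd.DataFrame = field(repr=False)

    def summary(self, top: int = 20) -> str:
        thr = self.model.thresholds
        lines = [
            "Gene-level collapsing association (CMH meta-analysis)",
            f"contrast: {self.model.contrast}   "
            f"suggestive P < {thr.suggestive:.2g}   study-wide P < {thr.study_wide:.2g}",
            "-" * 78,
        ]
        cols = [
            "gene",
            "qv_model",
            "p_cmh",
            "or_mh",
            "ci_low",
            "ci_high",
            "carrier_freq_group1",
            "carrier_freq_group2",
            "tier",
        ]
        head = self.table[cols].head(top)
        lines.append(
            head.to_string(
                index=False,
                float_format=lambda x: f"{x:.3g}",
            )
        )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()
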