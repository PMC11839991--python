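"""Qualifying-variant models and carrier collapsing.

A qualifying-variant (QV) model is a declarative filter over annotated
variants: allowed consequence classes, gnomAD and within-cohort frequency
ceilings, and an optional damaging-predictor requirement.  The default
registry ships eleven models (ten dominant, one recessive) and is fully
user-overridable from a YAML file.

Collapsing turns QC-passed genotypes into a boolean carrier matrix per
(gene, QV model): under a dominant model a sample is a carrier with at
least one QV; under the recessive model with a homozygous QV or at least
two distinct heterozygous QVs (putatively compound heterozygous, counted
without phase).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .qc import VariantRecord

__all__ = [
    "PTV_CONSEQUENCES",
    "MISSENSE_CONSEQUENCES",
    "SYNONYMOUS_CONSEQUENCES",
    "CONSEQUENCE_VOCABULARY",
    "QVModelSpec",
    "load_registry",
    "default_registry",
    "classify_variant",
    "CarrierMatrix",
    "build_carrier_matrix",
    "exclude_genes",
    "exome_wide_qv_count",
    "MatchResult",
    "match_controls_by_burden",
]

#: Protein-truncating consequence terms.
PTV_CONSEQUENCES = frozenset(
    {
        "stop_gained",
        "frameshift_variant",
        "splice_donor_variant",
        "splice_acceptor_variant",
    }
)
MISSENSE_CONSEQUENCES = frozenset({"missense_variant"})
SYNONYMOUS_CONSEQUENCES = frozenset({"synonymous_variant"})
CONSEQUENCE_VOCABULARY = PTV_CONSEQUENCES | MISSENSE_CONSEQUENCES | SYNONYMOUS_CONSEQUENCES

_GROUPS = {
    "ptv": PTV_CONSEQUENCES,
    "missense": MISSENSE_CONSEQUENCES,
    "synonymous": SYNONYMOUS_CONSEQUENCES,
}


@dataclass(frozen=True)
class QVModelSpec:
    """Declarative definition of one qualifying-variant model."""

    name: str
    mode: str  # "dominant" | "recessive"
    allowed_consequences: frozenset[str]
    max_gnomad_maf: float
    max_internal_maf: float
    require_damaging_prediction: bool = False
    use_popmax: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("dominant", "recessive"):
            raise ValueError(f"mode must be dominant or recessive, got {self.mode!r}")
        for f in ("max_gnomad_maf", "max_internal_maf"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must be in [0, 1], got {v}")
        unknown = self.allowed_consequences - CONSEQUENCE_VOCABULARY
        if unknown:
            raise ValueError(
                f"unknown consequence terms {sorted(unknown)}; "
                f"vocabulary: {sorted(CONSEQUENCE_VOCABULARY)}"
            )


def _spec_from_entry(name: str, entry: dict) -> QVModelSpec:
    terms: set[str] = set()
    for group in entry["consequences"]:
        try:
            terms |= _GROUPS[group]
        except KeyError:
            if group in CONSEQUENCE_VOCABULARY:
                terms.add(group)
            else:
                raise ValueError(
                    f"model {name!r}: unknown consequence group {group!r}"
                ) from None
    return QVModelSpec(
        name=name,
        mode=entry["mode"],
        allowed_consequences=frozenset(terms),
        max_gnomad_maf=float(entry["max_gnomad_maf"]),
        max_internal_maf=float(entry["max_internal_maf"]),
        require_damaging_prediction=bool(entry.get("require_damaging_prediction", False)),
        use_popmax=bool(entry.get("use_popmax", True)),
    )


def load_registry(path: str | Path | None = None) -> dict[str, QVModelSpec]:
    """Load a QV model registry from YAML (the shipped default when ``path``
    is None).  The default registry must contain exactly one recessive model."""
    if path is None:
        text = resources.files("rvcollapse.data").joinpath("qv_models.yaml").read_text()
        check_single_recessive = True
    else:
        text = Path(path).read_text()
        check_single_recessive = False
    raw = yaml.safe_load(text)
    registry = {name: _spec_from_entry(name, entry) for name, entry in raw.items()}
    if check_single_recessive:
        n_rec = sum(1 for s in registry.values() if s.mode == "recessive")
        if len(registry) != 11 or n_rec != 1:
            raise ValueError(
                "default registry must define eleven models with exactly one recessive"
            )
    return registry


_DEFAULT_REGISTRY: dict[str, QVModelSpec] | None = None


def default_registry() -> dict[str, QVModelSpec]:
    """The shipped eleven-model registry (cached)."""
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = load_registry()
    return _DEFAULT_REGISTRY


def classify_variant(
    v: VariantRecord, internal_maf: float, spec: QVModelSpec
) -> bool:
    """Is ``v`` a qualifying variant under ``spec``?

    True iff the consequence is allowed, the gnomAD MAF (popmax when
    available and ``spec.use_popmax``, else global) and the within-cohort
    MAF are at or below the model ceilings, and the damaging-predictor flag
    is set when required.  The variant is assumed to have passed the
    collapsing site filter.
    """
    if v.consequence not in CONSEQUENCE_VOCABULARY:
        raise ValueError(
            f"unknown consequence {v.consequence!r}; "
            f"vocabulary: {sorted(CONSEQUENCE_VOCABULARY)}"
        )
    if v.consequence not in spec.allowed_consequences:
        return False
    maf = v.gnomad_maf
    if spec.use_popmax and v.gnomad_popmax_maf is not None:
        maf = v.gnomad_popmax_maf
    if maf > spec.max_gnomad_maf:
        return False
    if internal_maf > spec.max_internal_maf:
        return False
    if (
        spec.require_damaging_prediction
        and v.consequence in MISSENSE_CONSEQUENCES
        and not v.damaging_flag
    ):
        return False
    return True


class CarrierMatrix:
    """Boolean carrier status per sample per (gene, QV model).

    ``data`` is a DataFrame indexed by sample id with ``"gene.model"``
    columns; ``provenance`` maps column -> sample -> tuple of contributing
    variant keys.
    """

    def __init__(self, data: pd.DataFrame, provenance: dict | None = None):
        self.data = data.astype(bool)
        self.provenance = provenance or {}

    @property
    def samples(self) -> pd.Index:
        return self.data.index

    @property
    def columns(self) -> pd.Index:
        return self.data.columns

    def genes(self) -> list[str]:
        return sorted({c.rsplit(".", 1)[0] for c in self.data.columns})

    def __getitem__(self, col: str) -> pd.Series:
        return self.data[col]

    def carrier_frequency(self, col: str) -> float:
        return float(self.data[col].mean())


def _recessive_carrier(dosages: np.ndarray) -> bool:
    """Recessive rule on a sample's QV dosage vector: a homozygous QV, or at
    least two distinct heterozygous QVs.  Missing dosages never contribute."""
    dosages = dosages[~np.isnan(dosages)]
    return bool(np.any(dosages == 2) or np.sum(dosages == 1) >= 2)


def build_carrier_matrix(
    genotypes: pd.DataFrame,
    qv_assignments: dict[str, dict[str, str]],
    specs: dict[str, QVModelSpec],
) -> CarrierMatrix:
    """Collapse QC-passed genotypes into a carrier matrix.

    Parameters
    ----------
    genotypes
        DataFrame of alt-allele dosages (0/1/2, NaN = missing), indexed by
        sample id with variant keys as columns.  Only QC-passed genotypes
        should be present (set failed genotypes to NaN upstream).
    qv_assignments
        Per model name, a mapping variant_key -> gene for that model's
        qualifying variants.
    specs
        Model name -> :class:`QVModelSpec`; every model in
        ``qv_assignments`` must be present.
    """
    cols: dict[str, pd.Series] = {}
    provenance: dict[str, dict[str, tuple[str, ...]]] = {}
    for model, assignment in qv_assignments.items():
        if model not in specs:
            raise ValueError(f"no QVModelSpec for model {model!r}")
        spec = specs[model]
        genes: dict[str, list[str]] = {}
        for key in sorted(assignment):
            if key not in genotypes.columns:
                raise ValueError(f"variant {key!r} not present in genotype matrix")
            genes.setdefault(assignment[key], []).append(key)
        for gene in sorted(genes):
            keys = genes[gene]
            sub = genotypes[keys].to_numpy(dtype=float)
            if spec.mode == "dominant":
                carrier = np.nansum(sub >= 1, axis=1) >= 1
            else:
                carrier = np.apply_along_axis(_recessive_carrier, 1, sub)
            col = f"{gene}.{model}"
            cols[col] = pd.Series(carrier, index=genotypes.index)
            prov: dict[str, tuple[str, ...]] = {}
            arr = genotypes[keys]
            for sample in genotypes.index[carrier]:
                row = arr.loc[sample]
                prov[sample] = tuple(k for k in keys if row[k] >= 1)
            provenance[col] = prov
    data = pd.DataFrame(cols, index=genotypes.index)
    data = data.reindex(sorted(data.columns), axis=1)
    return CarrierMatrix(data, provenance)


def exclude_genes(matrix: CarrierMatrix, exclusion_list) -> CarrierMatrix:
    """Drop all columns of genes on the exclusion list (e.g. genes known to
    track batch effects)."""
    excluded = set(exclusion_list)
    keep = [c for c in matrix.data.columns if c.rsplit(".", 1)[0] not in excluded]
    n_dropped = len(matrix.data.columns) - len(keep)
    if n_dropped and not keep:
        warnings.warn("exclude_genes removed every gene column", stacklevel=2)
    data = matrix.data[keep]
    provenance = {c: matrix.provenance.get(c, {}) for c in keep}
    out = CarrierMatrix(data, provenance)
    out.n_genes_dropped = n_dropped  # type: ignore[attr-defined]
    return out


def exome_wide_qv_count(
    sample_genotypes: pd.Series, qv_assignment: dict[str, str]
) -> int:
    """Number of qualifying variants a sample carries exome-wide under a
    dominant model (used for burden-matched control selection)."""
    keys = [k for k in qv_assignment if k in sample_genotypes.index]
    dosages = pd.to_numeric(sample_genotypes[keys], errors="coerce")
    return int((dosages >= 1).sum())


@dataclass(frozen=True)
class MatchResult:
    """Burden-matched control selection outcome."""

    selected: tuple[str, ...]
    mean_abs_count_difference: float
    standardized_mean_difference: float


def match_controls_by_burden(
    case_counts: pd.Series, pool_counts: pd.Series, ratio: int = 1
) -> MatchResult:
    """Select external controls whose exome-wide QV burden best matches the
    cases'.

    Deterministic greedy nearest-count matching without replacement: cases
    are processed in sample-id order and each receives the ``ratio`` pool
    samples with the closest burden count, ties broken by sample-id order.
    Reports the mean absolute per-pair count difference and the
    standardized difference of mean burden between cases and the selection.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    n_needed = ratio * len(case_counts)
    if len(pool_counts) < n_needed:
        raise ValueError(
            f"control pool has {len(pool_counts)} samples; "
            f"{n_needed} required for ratio {ratio}"
        )
    # pool sorted by (count, id): bisection finds nearest counts, and the
    # leftmost candidate at equal distance is the smallest id.
    pool = sorted((int(c), str(s)) for s, c in pool_counts.items())
    import bisect

    selected: list[str] = []
    diffs: list[int] = []
    sel_counts: list[int] = []
    for case_id in sorted(case_counts.index.astype(str)):
        target = int(case_counts[case_id])
        for _ in range(ratio):
            i = bisect.bisect_left(pool, (target, ""))
            best = None  # (diff, id, count, index); ties on diff go to smallest id
            for j in (i - 1, i):
                if 0 <= j < len(pool):
                    cnt, sid = pool[j]
                    cand = (abs(cnt - target), sid, cnt, j)
                    if best is None or cand[:2] < best[:2]:
                        best = cand
            # walk outward while equally distant candidates may exist
            j = i - 2
            while best and j >= 0 and target - pool[j][0] <= best[0]:
                cnt, sid = pool[j]
                cand = (abs(cnt - target), sid, cnt, j)
                if cand[:2] < best[:2]:
                    best = cand
                j -= 1
            j = i + 1
            while best and j < len(pool) and pool[j][0] - target <= best[0]:
                cnt, sid = pool[j]
                cand = (abs(cnt - target), sid, cnt, j)
                if cand[:2] < best[:2]:
                    best = cand
                j += 1
            assert best is not None
            diff, sid, cnt, j = best
            selected.append(sid)
            diffs.append(diff)
            sel_counts.append(cnt)
            pool.pop(j)
    case_arr = case_counts.to_numpy(dtype=float)
    sel_arr = np.asarray(sel_counts, dtype=float)
    pooled_sd = np.sqrt((case_arr.var(ddof=1) + sel_arr.var(ddof=1)) / 2.0) or np.nan
    smd = (
        float((case_arr.mean() - sel_arr.mean()) / pooled_sd)
        if np.isfinite(pooled_sd) and pooled_sd > 0
        else 0.0
    )
    return MatchResult(
        selected=tuple(selected),
        mean_abs_count_difference=float(np.mean(diffs)),
        standardized_mean_difference=smd,
    )
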