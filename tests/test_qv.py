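"""QV models, carrier collapsing and burden matching."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rvcollapse.qc import VariantRecord
from rvcollapse.qv import (
    QVModelSpec,
    build_carrier_matrix,
    classify_variant,
    default_registry,
    exclude_genes,
    exome_wide_qv_count,
    match_controls_by_burden,
)

from oracles import recessive_carrier_oracle


def variant(consequence="stop_gained", maf=0.0, damaging=False, key="chr1:100:A:C"):
    return VariantRecord(
        variant_key=key, gene="G", consequence=consequence,
        gnomad_maf=maf, gnomad_popmax_maf=maf, damaging_flag=damaging,
    )


PTV_SPEC = QVModelSpec(
    name="ptv", mode="dominant",
    allowed_consequences=frozenset({"stop_gained", "frameshift_variant",
                                    "splice_donor_variant", "splice_acceptor_variant"}),
    max_gnomad_maf=0.001, max_internal_maf=0.001,
)
FLEX_SPEC = QVModelSpec(
    name="flexdmg", mode="dominant",
    allowed_consequences=frozenset({"stop_gained", "frameshift_variant",
                                    "splice_donor_variant", "splice_acceptor_variant",
                                    "missense_variant"}),
    max_gnomad_maf=0.001, max_internal_maf=0.001,
    require_damaging_prediction=True,
)
REC_SPEC = QVModelSpec(
    name="rec", mode="recessive",
    allowed_consequences=frozenset({"stop_gained", "missense_variant"}),
    max_gnomad_maf=0.01, max_internal_maf=0.01,
    require_damaging_prediction=True,
)


class TestRegistry:
    def test_default_registry_has_ten_dominant_one_recessive(self):
        reg = default_registry()
        modes = [s.mode for s in reg.values()]
        assert len(reg) == 11
        assert modes.count("recessive") == 1
        assert modes.count("dominant") == 10

    def test_registry_can_be_overridden_from_file(self, tmp_path):
        from rvcollapse.qv import load_registry

        path = tmp_path / "models.yaml"
        path.write_text(
            "mymodel:\n  mode: dominant\n  consequences: [ptv]\n"
            "  max_gnomad_maf: 0.01\n  max_internal_maf: 0.01\n"
        )
        reg = load_registry(path)
        assert list(reg) == ["mymodel"]
        assert reg["mymodel"].max_gnomad_maf == 0.01


class TestClassifyVariant:
    def test_synonymous_never_qualifies_under_ptv(self):
        assert not classify_variant(variant("synonymous_variant"), 0.0, PTV_SPEC)

    def test_rare_stop_gain_qualifies_under_ptv(self):
        assert classify_variant(variant("stop_gained", maf=0.0), 0.0, PTV_SPEC)

    def test_undamaging_missense_fails_damaging_requirement(self):
        assert not classify_variant(
            variant("missense_variant", damaging=False), 0.0, FLEX_SPEC
        )

    def test_unknown_consequence_errors_with_vocabulary(self):
        v = VariantRecord(variant_key="chr1:5:A:C", gene="G",
                          consequence="upstream_gene_variant")
        with pytest.raises(ValueError, match="vocabulary"):
            classify_variant(v, 0.0, PTV_SPEC)

    def test_truth_table_over_all_predicate_combinations(self):
        # enumerate the 2^4 combinations of the four predicates and check
        # the classification equals their conjunction
        for cons_ok, gnomad_ok, internal_ok, dmg_ok in itertools.product(
            [True, False], repeat=4
        ):
            v = variant(
                consequence="missense_variant" if cons_ok else "synonymous_variant",
                maf=0.0005 if gnomad_ok else 0.01,
                damaging=dmg_ok,
            )
            internal = 0.0005 if internal_ok else 0.01
            expected = cons_ok and gnomad_ok and internal_ok and dmg_ok
            assert classify_variant(v, internal, FLEX_SPEC) is expected

    def test_popmax_preferred_when_available(self):
        v = VariantRecord(
            variant_key="chr1:9:A:C", gene="G", consequence="stop_gained",
            gnomad_maf=1e-5, gnomad_popmax_maf=0.02,
        )
        assert not classify_variant(v, 0.0, PTV_SPEC)


def genotypes_frame(rows, keys=("v1", "v2", "v3")):
    return pd.DataFrame(rows, columns=list(keys),
                        index=[f"s{i}" for i in range(len(rows))], dtype=float)


class TestCarrierMatrix:
    ASSIGN = {"rec": {"v1": "G", "v2": "G", "v3": "G"},
              "ptv": {"v1": "G", "v2": "G", "v3": "G"}}
    SPECS = {"rec": REC_SPEC, "ptv": PTV_SPEC}

    def test_recessive_rule_matches_27_case_enumeration(self):
        rows = list(itertools.product([0, 1, 2], repeat=3))
        gts = genotypes_frame(rows)
        matrix = build_carrier_matrix(gts, self.ASSIGN, self.SPECS)
        for i, row in enumerate(rows):
            assert bool(matrix["G.rec"][f"s{i}"]) == recessive_carrier_oracle(row), row

    def test_single_het_is_not_a_recessive_carrier(self):
        gts = genotypes_frame([[1, 0, 0]])
        matrix = build_carrier_matrix(gts, self.ASSIGN, self.SPECS)
        assert not matrix["G.rec"]["s0"]
        assert matrix["G.ptv"]["s0"]

    def test_homozygote_is_a_recessive_carrier(self):
        gts = genotypes_frame([[2, 0, 0]])
        matrix = build_carrier_matrix(gts, self.ASSIGN, self.SPECS)
        assert matrix["G.rec"]["s0"]

    def test_missing_genotype_never_confers_carrier_status(self):
        gts = genotypes_frame([[np.nan, np.nan, np.nan]])
        matrix = build_carrier_matrix(gts, self.ASSIGN, self.SPECS)
        assert not matrix["G.rec"]["s0"]
        assert not matrix["G.ptv"]["s0"]

    def test_recessive_carriers_are_a_subset_of_dominant_carriers(self, rng):
        rows = rng.integers(0, 3, size=(100, 3)).astype(float)
        matrix = build_carrier_matrix(genotypes_frame(rows), self.ASSIGN, self.SPECS)
        assert not (matrix["G.rec"] & ~matrix["G.ptv"]).any()

    def test_invariant_to_variant_input_order(self, rng):
        rows = rng.integers(0, 3, size=(50, 3)).astype(float)
        gts = genotypes_frame(rows)
        m1 = build_carrier_matrix(gts, self.ASSIGN, self.SPECS)
        m2 = build_carrier_matrix(gts[["v3", "v1", "v2"]], self.ASSIGN, self.SPECS)
        pd.testing.assert_frame_equal(m1.data, m2.data)

    def test_carrier_frequency_monotone_in_gnomad_maf_ceiling(self, rng):
        # widening the MAF ceiling admits a superset of QVs
        keys = [f"v{i}" for i in range(6)]
        mafs = [1e-5, 1e-4, 5e-4, 1e-3, 5e-3, 2e-2]
        records = {
            k: variant("stop_gained", maf=m, key=f"chr1:{100+i}:A:C")
            for i, (k, m) in enumerate(zip(keys, mafs))
        }
        gts = pd.DataFrame(
            rng.binomial(1, 0.2, size=(200, 6)).astype(float),
            columns=keys, index=[f"s{i}" for i in range(200)],
        )
        prev = 0.0
        for ceiling in [1e-5, 1e-4, 1e-3, 1e-2, 0.05]:
            spec = QVModelSpec(
                name="m", mode="dominant",
                allowed_consequences=frozenset({"stop_gained"}),
                max_gnomad_maf=ceiling, max_internal_maf=1.0,
            )
            assign = {
                "m": {k: "G" for k, r in records.items()
                      if classify_variant(r, 0.0, spec)}
            }
            if not assign["m"]:
                continue
            matrix = build_carrier_matrix(gts, assign, {"m": spec})
            freq = matrix.carrier_frequency("G.m")
            assert freq >= prev
            prev = freq


class TestExcludeGenes:
    def _matrix(self, genes):
        data = pd.DataFrame(
            {f"{g}.ptv": [True, False] for g in genes}, index=["s0", "s1"]
        )
        from rvcollapse.qv import CarrierMatrix

        return CarrierMatrix(data)

    def test_empty_list_is_identity(self):
        m = self._matrix(["A", "B"])
        out = exclude_genes(m, [])
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_only_listed_and_present_genes_are_removed(self):
        m = self._matrix([f"G{i}" for i in range(20)])
        listed = [f"G{i}" for i in range(10)] + [f"X{i}" for i in range(46)]
        out = exclude_genes(m, listed)
        assert out.data.shape[1] == 10
        assert out.n_genes_dropped == 10
        assert set(out.genes()) == {f"G{i}" for i in range(10, 20)}

    def test_excluding_every_gene_warns_and_empties_the_matrix(self):
        m = self._matrix(["A", "B"])
        with pytest.warns(UserWarning):
            out = exclude_genes(m, ["A", "B"])
        assert out.data.shape[1] == 0


class TestBurdenMatching:
    def test_zero_qvs_gives_zero_count(self):
        s = pd.Series({"v1": 0.0, "v2": 0.0})
        assert exome_wide_qv_count(s, {"v1": "A", "v2": "B"}) == 0

    def test_planted_count_is_recovered_and_additive(self, rng):
        keys = [f"v{i}" for i in range(20)]
        dosages = pd.Series(0.0, index=keys)
        carried = rng.choice(20, size=7, replace=False)
        dosages.iloc[carried] = 1.0
        assign = {k: ("A" if i < 10 else "B") for i, k in enumerate(keys)}
        total = exome_wide_qv_count(dosages, assign)
        assert total == 7
        part_a = exome_wide_qv_count(dosages, {k: g for k, g in assign.items() if g == "A"})
        part_b = exome_wide_qv_count(dosages, {k: g for k, g in assign.items() if g == "B"})
        assert part_a + part_b == total

    def test_identical_pool_matches_exactly(self):
        cases = pd.Series({"c0": 3, "c1": 5, "c2": 2})
        pool = pd.Series({"p0": 3, "p1": 5, "p2": 2, "p3": 9})
        res = match_controls_by_burden(cases, pool, ratio=1)
        assert res.mean_abs_count_difference == 0.0
        assert set(res.selected) == {"p0", "p1", "p2"}

    def test_greedy_prefers_exact_counts_while_supply_lasts(self):
        cases = pd.Series({f"c{i}": 5 for i in range(3)})
        pool = pd.Series({"p0": 4, "p1": 5, "p2": 6, "p3": 5, "p4": 5, "p5": 7})
        res = match_controls_by_burden(cases, pool, ratio=1)
        assert sorted(res.selected) == ["p1", "p3", "p4"]

    def test_insufficient_pool_errors(self):
        with pytest.raises(ValueError, match="pool"):
            match_controls_by_burden(
                pd.Series({"c0": 1}), pd.Series({"p0": 1}), ratio=8
            )

    def test_large_null_pool_matching_balances_mean_burden(self, rng):
        cases = pd.Series(rng.poisson(10, size=100),
                          index=[f"c{i:03d}" for i in range(100)])
        pool = pd.Series(rng.poisson(10, size=2000),
                         index=[f"p{i:04d}" for i in range(2000)])
        res = match_controls_by_burden(cases, pool, ratio=8)
        assert len(res.selected) == 800
        assert abs(res.standardized_mean_difference) < 0.1
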