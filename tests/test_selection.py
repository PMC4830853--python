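"""Significance selection, Bonferroni adjustment, Venn overlaps, MAF / LD
summaries of selected sets, and the Hayes-Goddard gene-count estimator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import gmb
from gmb.errors import GmbError
from gmb.selection import SelectionSet, comparison_report, report_to_text

from conftest import make_geno


def _results(pvals, model="M4", padj=None):
    return pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(len(pvals))],
            "model": model,
            "estimate": 0.1,
            "se": 0.05,
            "stat": 2.0,
            "p_nominal": pvals,
            "p_adjusted": padj if padj is not None else np.nan,
        }
    )


class TestBonferroni:
    def test_arithmetic(self):
        out = gmb.bonferroni_adjust(np.array([2e-8]), 46267)
        assert out[0] == pytest.approx(9.2534e-4)

    def test_capped_at_one(self):
        assert gmb.bonferroni_adjust(np.array([0.5]), 10)[0] == 1.0

    def test_family_of_one_is_identity(self):
        p = np.array([0.2, 0.9, 1e-5])
        assert np.allclose(gmb.bonferroni_adjust(p, 1), p)

    def test_never_decreases(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=100)
        assert np.all(gmb.bonferroni_adjust(p, 17) >= p)

    def test_invalid_p_rejected(self):
        with pytest.raises(GmbError):
            gmb.bonferroni_adjust(np.array([1.2]), 5)


class TestSelect:
    def test_boundary_inclusive(self):
        sel = gmb.select_significant(_results([0.001, 0.0010001]), threshold=0.001)
        assert sel.snp_ids == {"s0"}

    def test_enumeration_toy(self):
        p = [0.5] * 7 + [1e-5, 2e-4, 0.0009]
        sel = gmb.select_significant(_results(p), threshold=0.001)
        assert sel.snp_ids == {"s7", "s8", "s9"}

    def test_mode_defaults_per_model(self):
        p = [0.0005] * 4
        nominal = gmb.select_significant(_results(p, model="M4"))
        bonf = gmb.select_significant(_results(p, model="M1"))
        assert len(nominal) == 4 and len(bonf) == 0  # 4 * 0.0005 > 0.001

    def test_empty_when_nothing_passes(self):
        sel = gmb.select_significant(_results([0.2, 0.9], model="M2"))
        assert len(sel) == 0

    def test_nan_rows_never_selected(self):
        sel = gmb.select_significant(_results([np.nan, 1e-9]))
        assert sel.snp_ids == {"s1"}

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50),
           st.floats(1e-6, 0.5), st.floats(1e-6, 0.5))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_selection_monotone_in_threshold(self, pvals, t1, t2):
        lo, hi = sorted([t1, t2])
        res = _results(pvals)
        assert gmb.select_significant(res, threshold=lo).snp_ids <= \
            gmb.select_significant(res, threshold=hi).snp_ids

    def test_adjusted_subset_of_nominal(self):
        rng = np.random.default_rng(1)
        res = _results(rng.uniform(0, 0.01, 50), model="M1")
        bonf = gmb.select_significant(res, mode="bonferroni")
        nom = gmb.select_significant(res, mode="nominal")
        assert bonf.snp_ids <= nom.snp_ids


class TestOverlap:
    def _sets(self, *memberships):
        return [
            SelectionSet(model=f"M{k+1}", trait="t", threshold=0.001,
                         adjustment="nominal", snp_ids=frozenset(ids))
            for k, ids in enumerate(memberships)
        ]

    def test_identical_sets(self):
        ov = gmb.overlap(self._sets({"a", "b"}, {"a", "b"}))
        assert ov["regions"]["11"] == 2
        assert ov["regions"]["10"] == 0 and ov["regions"]["01"] == 0

    def test_disjoint_sets(self):
        ov = gmb.overlap(self._sets({"a"}, {"b"}, {"c"}))
        assert ov["all_models"] == 0
        assert ov["regions"]["100"] == 1 and ov["regions"]["111"] == 0

    def test_three_set_hand_enumeration(self):
        ov = gmb.overlap(self._sets({"a", "b", "c"}, {"b", "c", "d"}, {"c"}))
        assert ov["regions"]["111"] == 1  # c
        assert ov["regions"]["110"] == 1  # b
        assert ov["regions"]["100"] == 1  # a
        assert ov["regions"]["010"] == 1  # d
        assert ov["all_models"] == 1

    def test_inclusion_exclusion(self):
        rng = np.random.default_rng(2)
        universe = [f"s{j}" for j in range(40)]
        sets = self._sets(*[
            set(rng.choice(universe, size=15, replace=False)) for _ in range(3)
        ])
        ov = gmb.overlap(sets)
        assert sum(ov["regions"].values()) == ov["union"]

    def test_mismatched_panels_rejected(self):
        s1 = SelectionSet("M1", "t", 0.001, "nominal", {"a"}, panel={"a", "b"})
        s2 = SelectionSet("M2", "t", 0.001, "nominal", {"c"}, panel={"c", "d"})
        with pytest.raises(GmbError):
            gmb.overlap([s1, s2])


class TestSetSummaries:
    def _geno(self):
        rng = np.random.default_rng(3)
        codes = rng.choice([-1, 0, 1], size=(5000, 6), p=[0.25, 0.5, 0.25])
        codes[:, 5] = codes[:, 4]  # duplicated pair in full LD
        return make_geno(codes)

    def _sel(self, ids):
        return SelectionSet("M2", "t", 0.001, "bonferroni", frozenset(ids))

    def test_mean_maf(self):
        g = make_geno(np.array([[0, -1, 1]] * 4))  # MAFs 0.5, 0, 0
        assert gmb.mean_maf(self._sel({"s0"}), g) == pytest.approx(0.5)
        assert gmb.mean_maf(self._sel({"s0", "s1", "s2"}), g) == pytest.approx(0.5 / 3)

    def test_empty_selection_undefined(self):
        assert np.isnan(gmb.mean_maf(self._sel(set()), self._geno()))
        assert np.isnan(gmb.mean_pairwise_ld(self._sel({"s0"}), self._geno()))

    def test_duplicated_columns_full_ld(self):
        assert gmb.mean_pairwise_ld(self._sel({"s4", "s5"}), self._geno()) == pytest.approx(1.0)

    def test_independent_columns_near_zero_ld(self):
        ld = gmb.mean_pairwise_ld(self._sel({"s0", "s1", "s2", "s3"}), self._geno())
        assert ld < 0.03

    def test_unknown_id_rejected(self):
        with pytest.raises(GmbError):
            gmb.mean_maf(self._sel({"nope"}), self._geno())


class TestHayesGoddard:
    def test_zero_at_p_half(self):
        assert gmb.hayes_goddard_m(10.0, ne=1) == pytest.approx(0.0)

    def test_direct_evaluation(self):
        # N = 10.73 heterozygous QTL, Ne = 103: p = 1/206,
        # M = 10.73 * ln(205) = 57.12...
        m = gmb.hayes_goddard_m(10.73, 103)
        assert m == pytest.approx(10.73 * np.log(205.0), rel=1e-12)
        assert m == pytest.approx(57.12, abs=0.01)

    def test_monotone_in_ne(self):
        ms = [gmb.hayes_goddard_m(5.0, ne) for ne in (2, 10, 100, 1000)]
        assert all(b > a for a, b in zip(ms, ms[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(GmbError):
            gmb.hayes_goddard_m(5.0, 0.5)
        with pytest.raises(GmbError):
            gmb.hayes_goddard_m(0.0, 10)


class TestReport:
    def test_report_structure(self):
        g = make_geno(
            np.random.default_rng(4).choice([-1, 0, 1], size=(300, 8), p=[0.25, 0.5, 0.25])
        )
        sels = [
            SelectionSet("M2", "t", 0.001, "bonferroni", frozenset({"s0", "s1"})),
            SelectionSet("M4", "t", 0.001, "nominal", frozenset({"s1", "s2"})),
        ]
        rep = comparison_report(sels, g, n_qtl=10.73, ne=103)
        assert rep["models"]["M2"]["n_selected"] == 2
        assert rep["overlap"]["pairwise"]["M2&M4"]["count"] == 1
        assert rep["hayes_goddard"]["m_genes"] == pytest.approx(57.12, abs=0.01)
        text = report_to_text(rep)
        assert "M2" in text and "Hayes-Goddard" in text
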