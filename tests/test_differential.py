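"""Differential calling, the t-test, and dataset summary statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import phosflow as pf
from phosflow.model import QuantTable
from phosflow.simulate import KinaseMotif, SimConfig, simulate_study

from conftest import dummy_site


def _quant(num_rows, den_rows, conditions=("n", "d")):
    """QuantTable from per-site replicate tuples for two conditions."""
    num_rows, den_rows = np.atleast_2d(num_rows), np.atleast_2d(den_rows)
    data, design = {}, {}
    for j in range(num_rows.shape[1]):
        data[f"n.r{j}"] = num_rows[:, j]
        design[f"n.r{j}"] = conditions[0]
    for j in range(den_rows.shape[1]):
        data[f"d.r{j}"] = den_rows[:, j]
        design[f"d.r{j}"] = conditions[1]
    idx = pd.Index([f"s{i}" for i in range(num_rows.shape[0])], name="site_id")
    return QuantTable(pd.DataFrame(data, index=idx, dtype=float), design)


class TestT:
    def test_identical_groups_give_p_one(self):
        q = _quant([(3.0, 3.0, 3.0)], [(3.0, 3.0, 3.0)])
        out = pf.log2_ratio_and_test(q, ("n", "d"))
        assert out["log2fc"].iloc[0] == 0.0
        assert out["t"].iloc[0] == 0.0
        assert out["p"].iloc[0] == 1.0

    def test_exact_twofold(self):
        q = _quant([(4.0, 4.0, 4.0)], [(2.0, 2.0, 2.0)])
        out = pf.log2_ratio_and_test(q, ("n", "d"))
        assert out["log2fc"].iloc[0] == 1.0
        assert out["p"].iloc[0] == 0.0  # zero variance, distinct means

    def test_refuses_single_replicate(self):
        q = _quant([(4.0,)], [(2.0, 2.0)])
        with pytest.raises(ValueError, match="at least 2"):
            pf.log2_ratio_and_test(q, ("n", "d"))

    @pytest.mark.parametrize("equal_var", [True, False])
    def test_matches_scipy(self, equal_var):
        rng = np.random.default_rng(0)
        a = np.exp2(rng.normal(10, 1, size=(50, 3)))
        b = np.exp2(rng.normal(10, 1, size=(50, 4)))
        q = _quant(a, b)
        out = pf.log2_ratio_and_test(q, ("n", "d"), equal_var=equal_var)
        ref = stats.ttest_ind(np.log2(a), np.log2(b), axis=1, equal_var=equal_var)
        assert np.allclose(out["t"], ref.statistic, rtol=1e-12)
        assert np.allclose(out["p"], ref.pvalue, rtol=1e-10)


class TestClassify:
    @pytest.mark.parametrize(
        "ratio, p, expected",
        [
            (2.0, 0.01, "up"),
            (1.0, 0.0001, "ns"),
            (0.4, 0.01, "down"),
            (2.0, 0.05, "ns"),      # p at alpha is not < alpha
            (1.5, 0.049, "up"),     # ratio boundary is inclusive
            (1 / 1.5, 0.049, "down"),
            (1.49, 0.001, "ns"),
        ],
    )
    def test_quadrants(self, ratio, p, expected):
        assert pf.classify(np.log2(ratio), p) == expected

    @given(
        log2fc=st.floats(-4, 4),
        p=st.floats(0, 1),
        shrink=st.floats(0, 1),
        bump=st.floats(0, 1),
    )
    def test_monotone(self, log2fc, p, shrink, bump):
        """Raising p or shrinking |log2fc| never turns ns into up/down."""
        if pf.classify(log2fc, p) == "ns":
            weaker_fc = log2fc * shrink
            weaker_p = p + (1 - p) * bump
            assert pf.classify(weaker_fc, p) == "ns"
            assert pf.classify(log2fc, weaker_p) == "ns"

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            pf.classify(1.0, 0.01, fc_threshold=0.9)


@pytest.fixture(scope="module")
def null_study():
    cfg = SimConfig(
        seed=31, n_proteins=600, planted_activities=(),
        motif_library=(KinaseMotif("K1", "S", ()),),
    )
    return simulate_study(cfg)


class TestNullBehaviour:
    def test_null_p_values_uniform(self, null_study):
        result = pf.compare(null_study.quant, ("AC-B4", "AC-MG"))
        ks = stats.kstest(result.table["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_type_one_error_control(self, null_study):
        result = pf.compare(null_study.quant, ("AC-B4", "AC-MG"))
        n = len(result.table)
        frac = len(result.significant()) / n
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)

    def test_q_values_reported_not_used(self, null_study):
        result = pf.compare(null_study.quant, ("AC-B4", "AC-MG"))
        assert "q" in result.table
        assert (result.table["q"] >= result.table["p"] - 1e-12).all()


class TestSummaries:
    def test_residue_distribution_reported_counts(self):
        sites = (
            [dummy_site(f"p{i}", 1, "S") for i in range(4017)]
            + [dummy_site(f"q{i}", 1, "T") for i in range(592)]
            + [dummy_site(f"r{i}", 1, "Y") for i in range(233)]
        )
        dist = pf.residue_distribution(sites)
        assert {r: d["percent"] for r, d in dist.items()} == {
            "S": 83, "T": 12, "Y": 5
        }

    def test_residue_distribution_single_site(self):
        dist = pf.residue_distribution([dummy_site("p", 1, "S")])
        assert dist["S"] == {"count": 1, "percent": 100}
        assert dist["Y"]["count"] == 0

    @given(st.lists(st.sampled_from("STY"), min_size=1, max_size=200))
    def test_residue_distribution_vs_tally_oracle(self, residues):
        sites = [dummy_site(f"p{i}", 1, r) for i, r in enumerate(residues)]
        dist = pf.residue_distribution(sites)
        for r in "STY":
            count = sum(1 for x in residues if x == r)
            assert dist[r]["count"] == count
            assert dist[r]["percent"] == int(
                np.floor(100 * count / len(residues) + 0.5)
            )

    def test_sites_per_protein_reported_counts(self):
        sites = []
        for i in range(1306):
            sites.append(dummy_site(f"a{i}", 1, "S"))
        for i in range(505):
            sites += [dummy_site(f"b{i}", p, "S") for p in (1, 20)]
        for i in range(516):
            sites += [dummy_site(f"c{i}", p, "S") for p in (1, 20, 40)]
        hist = pf.sites_per_protein_histogram(sites)
        assert {b: d["percent"] for b, d in hist.items() if b != ">=7"} == {
            "1": 56.1, "2": 21.7, ">=3": 22.2
        }

    def test_sites_per_protein_all_single(self):
        sites = [dummy_site(f"p{i}", 1, "S") for i in range(10)]
        hist = pf.sites_per_protein_histogram(sites)
        assert hist["1"]["percent"] == 100.0
        assert hist["2"]["count"] == 0 and hist[">=3"]["count"] == 0

    @given(
        st.lists(st.integers(1, 9), min_size=1, max_size=50)
    )
    def test_sites_per_protein_vs_group_count_oracle(self, per_protein):
        sites = [
            dummy_site(f"p{i}", 15 * k + 1, "S")
            for i, n in enumerate(per_protein)
            for k in range(n)
        ]
        hist = pf.sites_per_protein_histogram(sites)
        assert hist["1"]["count"] == sum(1 for n in per_protein if n == 1)
        assert hist["2"]["count"] == sum(1 for n in per_protein if n == 2)
        assert hist[">=3"]["count"] == sum(1 for n in per_protein if n >= 3)
        assert hist[">=7"]["count"] == sum(1 for n in per_protein if n >= 7)
        assert (
            hist["1"]["count"] + hist["2"]["count"] + hist[">=3"]["count"]
            == len(per_protein)
        )


class TestOverlap:
    def test_identical_sets(self):
        sets = {k: {"a", "b", "c"} for k in "ABC"}
        cells = pf.venn_counts(sets)
        assert cells[frozenset("ABC")] == 3
        assert all(v == 0 for k, v in cells.items() if k != frozenset("ABC"))

    def test_disjoint_sets(self):
        sets = {"A": {"a"}, "B": {"b"}, "C": {"c"}}
        cells = pf.venn_counts(sets)
        assert cells[frozenset("ABC")] == 0
        assert cells[frozenset("A")] == 1

    @given(
        st.tuples(
            st.sets(st.integers(0, 30)),
            st.sets(st.integers(0, 30)),
            st.sets(st.integers(0, 30)),
        )
    )
    def test_vs_inclusion_exclusion_oracle(self, sets3):
        a, b, c = sets3
        cells = pf.venn_counts({"A": a, "B": b, "C": c})
        # exclusive cells by explicit set algebra
        assert cells[frozenset("ABC")] == len(a & b & c)
        assert cells[frozenset("AB")] == len((a & b) - c)
        assert cells[frozenset("A")] == len(a - b - c)
        assert sum(cells.values()) == len(a | b | c)


class TestUnionSize:
    def test_reported_two_omics_union(self):
        assert pf.union_size(6965, 2327, 1436) == 7856

    def test_no_overlap(self):
        assert pf.union_size(10, 0, 0) == 10

    def test_invalid_overlap(self):
        with pytest.raises(ValueError):
            pf.union_size(5, 3, 4)

    @given(
        st.sets(st.integers(0, 50)), st.sets(st.integers(0, 50))
    )
    def test_vs_set_union_oracle(self, a, b):
        assert pf.union_size(len(a), len(b), len(a & b)) == len(a | b)
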