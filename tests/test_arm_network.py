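from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herbsurv.arm_network import (
    build_graph,
    build_transactions,
    dosage,
    orient_rule,
    pair_counts,
    round_half_up,
    rule_stats,
    rules_table,
    top_rules,
)
from herbsurv.errors import DataError
from conftest import brute_force_pair_counts


def rx(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "date", "product_code", "product_kind",
                       "days", "daily_dose_g"])


class TestBuildTransactions:
    def test_single_patient_day(self):
        ts = build_transactions(rx([
            ("P1", date(2015, 1, 1), "A", "single_herb", 7, 1.0),
            ("P1", date(2015, 1, 1), "B", "single_herb", 7, 1.0),
        ]))
        assert ts.n_total == 1
        marg, joint = pair_counts(ts)
        assert marg["A"] == marg["B"] == joint[("A", "B")] == 1

    def test_duplicate_product_same_day_counted_once(self):
        ts = build_transactions(rx([
            ("P1", date(2015, 1, 1), "A", "single_herb", 7, 1.0),
            ("P1", date(2015, 1, 1), "A", "single_herb", 3, 1.0),
        ]))
        marg, _ = pair_counts(ts)
        assert ts.n_total == 1 and marg["A"] == 1

    def test_distinct_days_are_distinct_transactions(self):
        ts = build_transactions(rx([
            ("P1", date(2015, 1, 1), "A", "single_herb", 7, 1.0),
            ("P1", date(2015, 1, 2), "A", "single_herb", 7, 1.0),
            ("P2", date(2015, 1, 1), "A", "single_herb", 7, 1.0),
        ]))
        assert ts.n_total == 3

    def test_counts_equal_brute_force_on_fixture(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(10):
            for prod in rng.choice(list("ABCDE"), size=rng.integers(1, 4),
                                   replace=False):
                rows.append((f"P{i % 4}", date(2015, 1, 1 + i % 5), prod,
                             "single_herb", 7, 1.0))
        ts = build_transactions(rx(rows))
        marg, joint = pair_counts(ts)
        bm, bj = brute_force_pair_counts(ts.product_sets())
        assert marg == bm and joint == bj


class TestRuleStats:
    @pytest.mark.parametrize(
        "fx,fy,fxy,expected",
        [
            (399, 557, 145, (1.97, 36.34, 4.81)),
            (280, 324, 96, (1.30, 34.29, 7.81)),
            (540, 557, 91, (1.23, 16.85, 2.23)),
            (466, 540, 91, (1.23, 19.53, 2.67)),
            (280, 399, 88, (1.19, 31.43, 5.81)),
        ],
    )
    def test_published_pair_statistics(self, fx, fy, fxy, expected):
        s, c, l = rule_stats(fx, fy, fxy, 7376)
        assert (round_half_up(s), round_half_up(c), round_half_up(l)) == expected

    def test_perfect_cooccurrence(self):
        s, c, l = rule_stats(50, 50, 50, 50)
        assert (s, c, l) == (100.0, 100.0, 1.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(DataError):
            rule_stats(0, 10, 0, 100)
        with pytest.raises(DataError):
            rule_stats(10, 10, 0, 0)

    def test_inconsistent_frequencies_rejected(self):
        with pytest.raises(DataError):
            rule_stats(10, 10, 11, 100)

    @given(
        n=st.integers(2, 10000),
        data=st.data(),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_invariants_over_random_counts(self, n, data):
        fx = data.draw(st.integers(1, n))
        fy = data.draw(st.integers(1, n))
        fxy = data.draw(st.integers(0, min(fx, fy)))
        s, c, l = rule_stats(fx, fy, fxy, n)
        assert c >= s - 1e-12
        # lift symmetry
        s2, c2, l2 = rule_stats(fy, fx, fxy, n)
        assert l == pytest.approx(l2, rel=1e-12)
        # lift > 1 iff positive dependence
        if fxy * n > fx * fy:
            assert l > 1
        elif fxy * n < fx * fy:
            assert l < 1
        else:
            assert l == pytest.approx(1.0)


class TestOrientRule:
    @pytest.mark.parametrize(
        "a,b,fa,fb,expected",
        [
            ("HL", "HQ", 399, 557, ("HL", "HQ")),
            ("SZRT", "YJT", 280, 324, ("SZRT", "YJT")),
            ("GC", "HQ", 540, 557, ("GC", "HQ")),
            ("JG", "GC", 466, 540, ("JG", "GC")),
            ("HB", "HL", 280, 399, ("HB", "HL")),
        ],
    )
    def test_published_orientations(self, a, b, fa, fb, expected):
        assert orient_rule(a, b, fa, fb) == expected
        assert orient_rule(b, a, fb, fa) == expected  # order-insensitive

    def test_tie_breaks_lexicographically(self):
        assert orient_rule("ZZ", "AA", 10, 10) == ("AA", "ZZ")


class TestTopRules:
    def test_ranking_equals_brute_force(self):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(20):
            prods = rng.choice(list("ABCDEF"), size=rng.integers(2, 5),
                               replace=False)
            for prod in prods:
                rows.append((f"P{i}", date(2015, 1, 1), prod,
                             "single_herb", 7, 1.0))
        ts = build_transactions(rx(rows))
        rules = top_rules(ts, k=1000)
        bm, bj = brute_force_pair_counts(ts.product_sets())
        assert len(rules) == len(bj)
        ranked = sorted(bj.items(), key=lambda kv: -kv[1])
        assert rules[0].freq_xy == ranked[0][1]
        freqs = [r.freq_xy for r in rules]
        assert freqs == sorted(freqs, reverse=True)

    def test_k_larger_than_pair_count(self):
        ts = build_transactions(rx([
            ("P1", date(2015, 1, 1), "A", "single_herb", 7, 1.0),
            ("P1", date(2015, 1, 1), "B", "single_herb", 7, 1.0),
        ]))
        assert len(top_rules(ts, k=50)) == 1

    def test_empty_set_rejected(self):
        with pytest.raises(DataError):
            top_rules(build_transactions(rx([])), k=5)


class TestDosage:
    def test_two_row_hand_arithmetic(self):
        rows = rx([
            ("P1", date(2015, 1, 1), "A", "single_herb", 7, 3.0),
            ("P2", date(2015, 1, 2), "A", "single_herb", 7, 5.0),
        ])
        assert dosage("A", rows) == pytest.approx(4.0 * 7.0 * 2)

    def test_single_row(self):
        rows = rx([("P1", date(2015, 1, 1), "A", "single_herb", 10, 2.0)])
        assert dosage("A", rows) == pytest.approx(20.0)

    def test_published_dosage_cell(self):
        dose = 2575.0 / (399 * 7)
        rows = rx([
            (f"P{i}", date(2015, 1, 1 + i % 28), "HL", "single_herb", 7, dose)
            for i in range(399)
        ])
        assert round(dosage("HL", rows)) == 2575

    def test_absent_product_rejected(self):
        with pytest.raises(DataError):
            dosage("ZZ", rx([("P1", date(2015, 1, 1), "A", "single_herb",
                              7, 1.0)]))


def _published_rules():
    rows = [
        ("HL", "HQ", 399, 557, 145),
        ("SZRT", "YJT", 280, 324, 96),
        ("GC", "HQ", 540, 557, 91),
        ("JG", "GC", 466, 540, 91),
        ("HB", "HL", 280, 399, 88),
    ]
    from herbsurv.arm_network import RulePair

    out = []
    for x, y, fx, fy, fxy in rows:
        s, c, l = rule_stats(fx, fy, fxy, 7376)
        out.append(RulePair(x, y, fx, fy, fxy, s, c, 100.0 * fy / 7376, l))
    return out


class TestGraph:
    def test_two_clusters_from_published_pairs(self):
        g = build_graph(_published_rules())
        comps = sorted(g.components(), key=len, reverse=True)
        assert comps[0] == {"HQ", "GC", "HL", "JG", "HB"}
        assert comps[1] == {"SZRT", "YJT"}
        clusters = g.clusters
        assert len({clusters[n] for n in comps[0]}) == 1
        assert len({clusters[n] for n in comps[1]}) == 1
        assert clusters["HQ"] != clusters["SZRT"]

    def test_single_pair_graph(self):
        g = build_graph(_published_rules()[:1])
        assert g.components() == [{"HL", "HQ"}]

    def test_components_match_union_find_oracle(self):
        rng = np.random.default_rng(2)
        from herbsurv.arm_network import RulePair

        nodes = [f"N{i}" for i in range(20)]
        rules = []
        for _ in range(50):
            a, b = rng.choice(20, size=2, replace=False)
            rules.append(RulePair(nodes[a], nodes[b], 5, 5, 2, 1.0, 40.0,
                                  10.0, 4.0))
        g = build_graph(rules)

        parent = {n: n for n in nodes}

        def find(u):
            while parent[u] != u:
                parent[u] = parent[parent[u]]
                u = parent[u]
            return u

        for r in rules:
            parent[find(r.x)] = find(r.y)
        touched = {n for r in rules for n in (r.x, r.y)}
        oracle = {}
        for n in touched:
            oracle.setdefault(find(n), set()).add(n)
        assert sorted(map(sorted, g.components())) == sorted(
            map(sorted, oracle.values()))

    def test_threshold_excluding_everything_warns_empty(self):
        g = build_graph(_published_rules(), node_min_freq=10_000)
        assert g.graph.number_of_nodes() == 0


def test_rules_table_rendering():
    table = rules_table(_published_rules())
    assert list(table["lift"]) == [4.81, 7.81, 2.23, 2.67, 5.81]
    assert list(table["support_pct"]) == [1.97, 1.30, 1.23, 1.23, 1.19]
    assert list(table["confidence_pct"]) == [36.34, 34.29, 16.85, 19.53, 31.43]
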