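"""Hypergeometric enrichment, BH correction and connectivity-rate ranking."""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest

from associome import (
    AnnotationSet,
    benjamini_hochberg,
    connectivity_rate,
    hypergeometric_enrichment,
    rank_by_cr,
)
from associome.enrichment import (
    EnrichedProcess,
    load_annotation,
    propagate_with_ontology,
    write_annotation,
)

from conftest import build_kb, random_kb


def exact_upper_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """Independent oracle: P(X >= k) by exact combinatorial summation."""
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), comb(N, n))
    return total


class TestHypergeometric:
    def test_worked_case_is_one_third(self):
        ann = AnnotationSet(
            term_genes={"T1": {f"g{i}" for i in range(4)}},
            reference_universe={f"g{i}" for i in range(10)},
        )
        records = hypergeometric_enrichment({"g0", "g1", "g8"}, ann)
        assert len(records) == 1
        r = records[0]
        assert (r.k, r.n_study, r.K, r.N) == (2, 3, 4, 10)
        assert r.p_value == pytest.approx(1 / 3, abs=1e-12)

    def test_agrees_with_exhaustive_enumeration_for_small_universes(self):
        universe = [f"g{i}" for i in range(12)]
        for N in range(2, 13):
            for K in range(1, N + 1):
                for n in range(1, N + 1):
                    ann = AnnotationSet(
                        term_genes={"T": set(universe[:K])},
                        reference_universe=set(universe[:N]),
                    )
                    # study: n genes with max feasible overlap pattern
                    for k in range(max(1, n - (N - K)), min(K, n) + 1):
                        study = set(universe[:k]) | set(universe[K:K + n - k])
                        records = hypergeometric_enrichment(study, ann)
                        assert records[0].k == k
                        expect = float(exact_upper_tail(N, K, n, k))
                        assert records[0].p_value == pytest.approx(expect, abs=1e-12)

    def test_terms_without_study_genes_are_excluded(self):
        ann = AnnotationSet(
            term_genes={"T1": {"g0"}, "T2": {"g5"}},
            reference_universe={f"g{i}" for i in range(10)},
        )
        records = hypergeometric_enrichment({"g0"}, ann)
        assert [r.term_id for r in records] == ["T1"]

    def test_study_equal_to_universe_saturates(self):
        universe = {f"g{i}" for i in range(6)}
        ann = AnnotationSet(
            term_genes={"T1": {"g0", "g1"}, "T2": {"g3"}},
            reference_universe=universe,
        )
        for r in hypergeometric_enrichment(universe, ann):
            assert r.p_value == pytest.approx(1.0)
            assert r.q_value == pytest.approx(1.0)

    def test_empty_inputs_raise(self):
        ann = AnnotationSet(term_genes={"T": {"g0"}}, reference_universe={"g0"})
        with pytest.raises(ValueError):
            hypergeometric_enrichment(set(), ann)
        with pytest.raises(ValueError):
            hypergeometric_enrichment({"g0"}, AnnotationSet(reference_universe={"g0"}))

    def test_out_of_universe_study_genes_dropped_with_warning(self):
        ann = AnnotationSet(term_genes={"T": {"g0"}},
                            reference_universe={"g0", "g1"})
        with pytest.warns(UserWarning, match="outside the reference universe"):
            records = hypergeometric_enrichment({"g0", "alien"}, ann)
        assert records[0].n_study == 1


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        assert benjamini_hochberg([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_saturated(self):
        assert benjamini_hochberg([0.2]) == pytest.approx([0.2])
        assert benjamini_hochberg([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_deterministic_monotone_and_inflationary_on_random_vectors(self):
        # Note BH is not idempotent as an operator (re-adjusting q-values can
        # only inflate them: BH([0.1, 0.9]) = [0.2, 0.9] but
        # BH([0.2, 0.9]) = [0.4, 0.9]); the true invariants are determinism,
        # step-up monotonicity, q >= p, and one-sided inflation.
        rng = np.random.default_rng(17)
        for _ in range(50):
            ps = rng.random(size=rng.integers(1, 40)).tolist()
            qs = benjamini_hochberg(ps)
            assert benjamini_hochberg(ps) == pytest.approx(qs)  # deterministic
            assert all(q2 >= q1 - 1e-12
                       for q1, q2 in zip(qs, benjamini_hochberg(qs)))
            order = np.argsort(ps)
            sorted_qs = np.array(qs)[order]
            assert np.all(np.diff(sorted_qs) >= -1e-12)
            assert all(q >= p - 1e-12 for p, q in zip(ps, qs))
            assert all(0.0 <= q <= 1.0 for q in qs)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


class TestConnectivityRate:
    def test_worked_example_one_of_three_pairs(self):
        kb = build_kb(["D1"], ["a", "b", "c"], [("D1", "a")], [("a", "b")])
        assert connectivity_rate({"a", "b", "c"}, kb) == pytest.approx(1 / 3)

    def test_triangle_attains_maximum(self):
        kb = build_kb(["D1"], ["a", "b", "c"], [("D1", "a")],
                      [("a", "b"), ("b", "c"), ("a", "c")])
        assert connectivity_rate({"a", "b", "c"}, kb) == 1.0

    def test_small_groups_are_missing(self, tiny_kb):
        assert connectivity_rate({"g1"}, tiny_kb) is None
        assert connectivity_rate(set(), tiny_kb) is None

    def test_multi_typed_pair_counts_once(self):
        kb = build_kb(["D1"], ["a", "b"], [("D1", "a")],
                      [("a", "b", "association"), ("a", "b", "expression")])
        assert connectivity_rate({"a", "b"}, kb) == 1.0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            kb = random_kb(rng, n_genes=25, edge_prob=0.15)
            size = int(rng.integers(2, 12))
            group = set(rng.choice(sorted(kb.genes), size=size, replace=False))
            linked = {l.pair() for l in kb.interactions}
            bf = sum(1 for a, b in combinations(sorted(group), 2)
                     if (a, b) in linked) / (size * (size - 1) / 2)
            assert connectivity_rate(group, kb) == pytest.approx(bf)


class TestRanking:
    def make(self, term, q, cr):
        return EnrichedProcess(term_id=term, q_value=q, cr=cr)

    def test_descending_cr_with_missing_last(self):
        records = [self.make("A", 0.01, 0.5), self.make("B", 0.02, 1.0),
                   self.make("C", 0.001, None)]
        assert [r.term_id for r in rank_by_cr(records)] == ["B", "A", "C"]

    def test_ties_broken_by_q_then_term_id(self):
        records = [self.make("B", 0.02, 1.0), self.make("A", 0.01, 1.0),
                   self.make("C", 0.01, 1.0)]
        assert [r.term_id for r in rank_by_cr(records)] == ["A", "C", "B"]

    def test_empty_input(self):
        assert rank_by_cr([]) == []


class TestAnnotationIO:
    def test_plain_tsv_round_trip(self, tmp_path):
        ann = AnnotationSet(term_genes={"T1": {"g1", "g2"}, "T2": {"g2"}},
                            reference_universe={"g1", "g2", "g3"})
        path = tmp_path / "ann.tsv"
        write_annotation(ann, path)
        loaded = load_annotation(path, universe={"g1", "g2", "g3"})
        assert loaded.term_genes == ann.term_genes
        assert loaded.reference_universe == ann.reference_universe

    def test_gaf_columns_two_and_five(self, tmp_path):
        row = ["DB", "g1", "SYM", "", "GO:0001", "REF", "IEA", "", "P",
               "", "", "protein", "taxon:9606", "20130501", "UniProt"]
        path = tmp_path / "ann.gaf"
        path.write_text("!gaf-version: 2.1\n" + "\t".join(row) + "\n")
        ann = load_annotation(path)
        assert ann.term_genes == {"GO:0001": {"g1"}}

    def test_obo_propagation_follows_true_path_rule(self, tmp_path):
        obo = tmp_path / "mini.obo"
        obo.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:0001\nname: parent process\n\n"
            "[Term]\nid: GO:0002\nname: child process\nis_a: GO:0001\n"
        )
        ann = AnnotationSet(term_genes={"GO:0002": {"g1"}},
                            reference_universe={"g1", "g2"})
        out = propagate_with_ontology(ann, obo)
        assert out.term_genes["GO:0001"] == {"g1"}
        assert out.term_names["GO:0001"] == "parent process"
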