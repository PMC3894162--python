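"""Contingency building, exact Fisher tail, BH step-up, taxonomy projection."""

import math
import random
from fractions import Fraction
from math import comb, factorial

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytomine.association_stats import (ContingencyTable2x2,
                                         associate_compounds_to_diseases,
                                         benjamini_hochberg,
                                         build_contingency,
                                         conserved_compounds,
                                         fisher_exact_greater,
                                         project_taxonomy_content,
                                         taxonomy_enrichment,
                                         taxonomy_enrichment_all)
from phytomine.corpus_synthesis import TaxonNode, Taxonomy, generate_taxonomy


def enumeration_oracle(t: ContingencyTable2x2) -> float:
    """Independent oracle: enumerate all tables with the same margins via
    factorial-based hypergeometric probabilities, sum the tail P(X >= a)."""
    row1, row2, col1 = t.a + t.b, t.c + t.d, t.a + t.c
    n = t.n

    def prob(k):
        return (Fraction(factorial(row1), factorial(k) * factorial(row1 - k))
                * Fraction(factorial(row2),
                           factorial(col1 - k) * factorial(row2 - col1 + k))
                / Fraction(factorial(n),
                           factorial(col1) * factorial(n - col1)))

    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    return float(sum(prob(k) for k in range(t.a, hi + 1))) if t.a <= hi else 0.0


class TestContingency:
    def test_set_counting(self):
        u = set(range(10))
        compound = {0, 1, 2, 3}
        disease = {1, 2, 3, 4, 5}
        t = build_contingency(compound, disease, u)
        assert (t.a, t.b, t.c, t.d) == (3, 1, 2, 4)

    def test_disjoint_sets(self):
        t = build_contingency({0, 1}, {2, 3}, set(range(6)))
        assert t.a == 0

    def test_full_overlap(self):
        u = set(range(5))
        t = build_contingency(u, u, u)
        assert (t.a, t.b, t.c, t.d) == (5, 0, 0, 0)

    def test_subset_violation_rejected(self):
        with pytest.raises(ValueError):
            build_contingency({99}, set(), {1, 2})


class TestFisher:
    def test_hand_enumerated_value(self):
        # tail k in {3,4}: (C(4,3)C(6,2)+C(4,4)C(6,1)) / C(10,5) = 66/252
        p = fisher_exact_greater(ContingencyTable2x2(3, 1, 2, 4))
        assert p == pytest.approx(66 / 252, abs=1e-15)

    def test_zero_overlap_is_whole_tail(self):
        assert fisher_exact_greater(ContingencyTable2x2(0, 5, 3, 2)) == 1.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 0, 0, 0)

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = random.Random(0)
        for _ in range(300):
            t = ContingencyTable2x2(*(rng.randint(0, 8) for _ in range(4)))
            assert fisher_exact_greater(t) == \
                pytest.approx(enumeration_oracle(t), abs=1e-12)

    def test_matches_scipy_greater(self):
        scipy_stats = pytest.importorskip("scipy.stats")
        rng = random.Random(1)
        for _ in range(200):
            t = ContingencyTable2x2(*(rng.randint(0, 12) for _ in range(4)))
            _, p_ref = scipy_stats.fisher_exact([[t.a, t.b], [t.c, t.d]],
                                                alternative="greater")
            assert fisher_exact_greater(t) == pytest.approx(p_ref, rel=1e-9)


class TestBenjaminiHochberg:
    def test_step_up_hand_example(self):
        flags = benjamini_hochberg([0.001, 0.008, 0.039, 0.041], q=0.05)
        assert flags == [True, True, True, True]

    def test_all_ones_rejected_none(self):
        assert benjamini_hochberg([1.0, 1.0, 1.0], q=0.05) == [False] * 3

    def test_empty_family(self):
        assert benjamini_hochberg([], q=0.05) == []

    def test_flags_in_input_order(self):
        flags = benjamini_hochberg([0.9, 0.0001, 0.8], q=0.05)
        assert flags == [False, True, False]

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = random.Random(2)
        for _ in range(50):
            ps = [rng.random() * 0.999 + 1e-6 for _ in range(rng.randint(1, 40))]
            ours = benjamini_hochberg(ps, q=0.05)
            ref = sm.multipletests(ps, alpha=0.05, method="fdr_bh")[0]
            assert ours == list(ref)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1,
                    max_size=50),
           st.floats(min_value=0.01, max_value=0.2),
           st.floats(min_value=0.01, max_value=0.2))
    def test_monotone_in_q(self, ps, q1, q2):
        lo, hi = sorted((q1, q2))
        assert sum(benjamini_hochberg(ps, lo)) <= \
            sum(benjamini_hochberg(ps, hi))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.0], q=0.05)
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5], q=1.5)


class TestAssociate:
    def test_single_pair_complete_overlap_significance(self):
        """One compound fully inside the disease plant set in a 20-plant
        universe: p = 1/C(20,k), significant at q=0.05 for k >= 3 (family
        of size one)."""
        for k in (2, 3, 5):
            plants = [f"p{i}" for i in range(20)]
            content = [(p, "c1") for p in plants[:k]]
            signed = [(p, "d1", "positive") for p in plants[:k]]
            # anchor the universe at all 20 plants via the negative family
            content += [(p, "c0") for p in plants]
            signed += [(p, "d0", "negative") for p in plants]
            res = associate_compounds_to_diseases(content, signed, q=0.05)
            positive = [x for x in res if x.direction == "positive"]
            r = next(x for x in positive if x.compound_id == "c1")
            assert r.table.n == 20
            assert r.p == pytest.approx(1 / comb(20, k), rel=1e-12)
            flags = benjamini_hochberg([x.p for x in positive], 0.05)
            assert r.significant == flags[positive.index(r)]
            if k >= 3:
                assert r.significant

    def test_directions_form_separate_families(self):
        plants = [f"p{i}" for i in range(12)]
        content = [(p, "c1") for p in plants[:4]] + [(p, "c0") for p in plants]
        signed = [(p, "d1", "positive") for p in plants[:4]]
        signed += [(p, "d1", "negative") for p in plants[6:]]
        res = associate_compounds_to_diseases(content, signed, q=0.05)
        dirs = {r.direction for r in res}
        assert dirs == {"positive", "negative"}
        for direction in dirs:
            fam = [r for r in res if r.direction == direction]
            flags = benjamini_hochberg([r.p for r in fam], 0.05)
            assert [r.significant for r in fam] == flags

    def test_zero_overlap_tests_excluded(self):
        plants = [f"p{i}" for i in range(6)]
        content = [(p, "c1") for p in plants[:3]]
        signed = [(p, "d1", "positive") for p in plants[3:]]
        # universe is plants in both edge sets -> empty here
        with pytest.raises(ValueError):
            associate_compounds_to_diseases(content, signed)

    def test_universe_is_intersection_of_annotated_plants(self):
        content = [("p1", "c1"), ("p2", "c1"), ("p3", "c2")]
        signed = [("p1", "d1", "positive"), ("p2", "d1", "positive"),
                  ("p9", "d1", "positive")]
        res = associate_compounds_to_diseases(content, signed)
        # universe = {p1, p2}; c2's plants fall outside -> a = 0 -> excluded
        assert {r.compound_id for r in res} == {"c1"}
        assert res[0].table.n == 2


def _toy_taxonomy():
    nodes = [
        TaxonNode("F1", "family", None),
        TaxonNode("G1", "genus", "F1"), TaxonNode("G2", "genus", "F1"),
        TaxonNode("S1", "species", "G1"), TaxonNode("S2", "species", "G1"),
        TaxonNode("S3", "species", "G2"),
    ]
    content = {"F1": set(), "G1": {"A"}, "G2": set(),
               "S1": {"B"}, "S2": set(), "S3": {"C"}}
    return Taxonomy(nodes, content)


class TestProjection:
    def test_child_content_projected_to_parent(self):
        proj = project_taxonomy_content(_toy_taxonomy())
        assert proj.content["G1"] == {"A", "B"}

    def test_root_is_union_of_all(self):
        proj = project_taxonomy_content(_toy_taxonomy())
        assert proj.content["F1"] == {"A", "B", "C"}

    def test_idempotent_and_leaves_unchanged(self):
        once = project_taxonomy_content(_toy_taxonomy())
        twice = project_taxonomy_content(once)
        assert once.content == twice.content
        assert once.content["S1"] == {"B"}

    def test_root_distinct_compound_count_preserved(self):
        tax = generate_taxonomy((2, 2, 2, 2, 2),
                                tuple(f"c{i}" for i in range(9)),
                                localized_fraction=0.5, seed=3)
        proj = project_taxonomy_content(tax)
        all_leaf = set().union(*(tax.content[l] for l in tax.leaves()))
        root_union = set().union(*(proj.content[r] for r in proj.roots()))
        assert root_union == all_leaf


class TestEnrichment:
    def test_absent_compound_zero_overlap(self):
        proj = project_taxonomy_content(_toy_taxonomy())
        r = taxonomy_enrichment(proj, "C", "G1")
        assert r.table.a == 0 and r.p == 1.0 and not r.significant

    def test_unknown_node_or_compound_rejected(self):
        proj = project_taxonomy_content(_toy_taxonomy())
        with pytest.raises(KeyError):
            taxonomy_enrichment(proj, "A", "nope")
        with pytest.raises(KeyError):
            taxonomy_enrichment(proj, "nope", "G1")

    def test_genus_units_table(self):
        proj = project_taxonomy_content(_toy_taxonomy())
        r = taxonomy_enrichment(proj, "A", "G1")
        # 2 genera; A is in G1 only; subtree of G1 is {G1}
        assert (r.table.a, r.table.b, r.table.c, r.table.d) == (1, 0, 0, 1)


class TestConserved:
    def _flags(self, sig_pairs):
        proj = project_taxonomy_content(_toy_taxonomy())
        return [r for r in taxonomy_enrichment_all(proj, q=0.99)], proj

    def test_rule_and_errors(self):
        results, proj = self._flags(None)
        # manufacture significance flags directly
        from phytomine.association_stats import EnrichmentResult
        fake = [
            EnrichmentResult("A", "F1", results[0].table, 0.01, True),
            EnrichmentResult("A", "G1", results[0].table, 0.01, True),
            EnrichmentResult("B", "G1", results[0].table, 0.01, True),
        ]
        assert conserved_compounds(proj, fake, "F1", "G1") == {"A"}
        assert conserved_compounds(proj, [], "F1", "G1") == set()
        with pytest.raises(ValueError):
            conserved_compounds(proj, fake, "G1", "F1")
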