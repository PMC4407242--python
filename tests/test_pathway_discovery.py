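"""Pathway pattern matching: partitions, completeness, merging."""

from itertools import product

import numpy as np
import pytest

from associome import (
    DiseaseSlot,
    GeneSlot,
    NodeClassPattern,
    build_gene_partition,
    find_pathways,
    merge_pathways,
)
from associome.knowledge_base import Gene

from conftest import build_kb, random_kb


def five_slot_pattern(focal, partners):
    return NodeClassPattern(slots=[
        DiseaseSlot.of(focal),
        GeneSlot(label=f"specific:{focal}"),
        GeneSlot(label="comorbid"),
        GeneSlot(label="partner_specific"),
        DiseaseSlot.of(*partners),
    ])


def with_partner_specific(partition, partners):
    merged = set()
    for d in partners:
        merged |= partition.labels[f"specific:{d}"]
    partition.labels["partner_specific"] = merged
    return partition


def four_disease_kb():
    """PE-like fixture: gC comorbid with all four diseases; gA specific to the
    focal disease; gB specific to DM; exactly one valid chain."""
    return build_kb(
        diseases=["PE", "DM", "GD", "Ob"],
        genes=["gA", "gB", "gC", "gD"],
        associations=[
            ("PE", "gA"), ("PE", "gC"),
            ("DM", "gB"), ("DM", "gC"),
            ("GD", "gC"), ("Ob", "gC"),
            ("Ob", "gD"),
        ],
        interactions=[("gA", "gC"), ("gC", "gB")],
    )


class TestGenePartition:
    def test_comorbid_excluded_from_every_specific_set(self):
        kb = four_disease_kb()
        part = build_gene_partition(kb, "PE", ["DM", "GD", "Ob"])
        assert part.labels["comorbid"] == {"gC"}
        assert part.labels["specific:PE"] == {"gA"}
        assert part.labels["specific:DM"] == {"gB"}
        assert "gC" not in part.labels["specific:PE"]

    def test_gene_associated_with_no_configured_disease_is_unlabelled(self):
        kb = four_disease_kb()
        part = build_gene_partition(kb, "PE", ["DM"])
        labelled = set().union(*part.labels.values())
        # gD is associated only with Ob, which is not configured here
        assert "gD" not in labelled

    def test_unknown_disease_raises(self):
        with pytest.raises(KeyError):
            build_gene_partition(four_disease_kb(), "PE", ["nope"])

    def test_undefined_label_raises(self):
        part = build_gene_partition(four_disease_kb(), "PE", ["DM"])
        with pytest.raises(KeyError, match="undefined partition label"):
            part.members("typo")


class TestPatternValidation:
    def test_too_short_pattern_rejected(self):
        with pytest.raises(ValueError):
            NodeClassPattern(slots=[DiseaseSlot.of("A"), DiseaseSlot.of("B")])

    def test_gene_slot_at_boundary_rejected(self):
        with pytest.raises(ValueError):
            NodeClassPattern(slots=[GeneSlot(label="x"), GeneSlot(label="y"),
                                    DiseaseSlot.of("A")])


class TestFindPathways:
    def test_single_chain_fixture_returns_exactly_one_match(self):
        kb = four_disease_kb()
        partners = ["DM", "GD", "Ob"]
        part = with_partner_specific(build_gene_partition(kb, "PE", partners), partners)
        matches = find_pathways(kb, five_slot_pattern("PE", partners), part)
        assert len(matches) == 1
        assert matches[0].nodes == ("PE", "gA", "gC", "gB", "DM")

    def test_no_gene_gene_link_means_no_match(self):
        kb = build_kb(
            ["PE", "DM"], ["gA", "gB", "gC"],
            [("PE", "gA"), ("PE", "gC"), ("DM", "gB"), ("DM", "gC")],
            [],  # no interactions at all
        )
        partners = ["DM"]
        part = with_partner_specific(build_gene_partition(kb, "PE", partners), partners)
        assert find_pathways(kb, five_slot_pattern("PE", partners), part) == []

    def test_gene_cannot_fill_two_slots(self):
        # gA is specific to both PE and DM (associated with each but not all);
        # chain PE-gA-gC-gA-DM must not be returned
        kb = build_kb(
            ["PE", "DM", "GD"], ["gA", "gC"],
            [("PE", "gA"), ("DM", "gA"), ("PE", "gC"), ("DM", "gC"), ("GD", "gC")],
            [("gA", "gC")],
        )
        partners = ["DM", "GD"]
        part = with_partner_specific(build_gene_partition(kb, "PE", partners), partners)
        matches = find_pathways(kb, five_slot_pattern("PE", partners), part)
        for m in matches:
            interior = m.nodes[1:-1]
            assert len(set(interior)) == len(interior)
        assert matches == []

    def test_link_type_filter_restricts_gene_gene_steps(self):
        kb = four_disease_kb()
        partners = ["DM", "GD", "Ob"]
        part = with_partner_specific(build_gene_partition(kb, "PE", partners), partners)
        matches = find_pathways(kb, five_slot_pattern("PE", partners), part,
                                link_types={"binding"})
        assert matches == []

    def test_protein_node_satisfies_its_genes_label(self):
        kb = four_disease_kb()
        kb.add_gene(Gene(id="pA", symbol="pA", entity_class="protein",
                         coding_gene_id="gA"))
        from associome import Interaction

        kb.add_interaction(Interaction(a_id="pA", b_id="gC"))
        partners = ["DM", "GD", "Ob"]
        part = with_partner_specific(build_gene_partition(kb, "PE", partners), partners)
        matches = find_pathways(kb, five_slot_pattern("PE", partners), part)
        # pA stands in for gA on the label, but the disease-gene step still
        # needs an Association record, which only gA has
        assert all(m.nodes[1] == "gA" for m in matches)

    def test_completeness_against_brute_force_enumeration(self):
        rng = np.random.default_rng(31)
        for _ in range(8):
            kb = random_kb(rng, n_diseases=5, n_genes=20,
                           assoc_prob=0.25, edge_prob=0.15)
            focal = "D0"
            partners = ["D1", "D2"]
            part = with_partner_specific(
                build_gene_partition(kb, focal, partners), partners
            )
            pattern = five_slot_pattern(focal, partners)
            matches = find_pathways(kb, pattern, part)

            assoc = {(a.disease_id, a.gene_id) for a in kb.associations}
            linked = {l.pair() for l in kb.interactions}

            def connected(a, b):
                return ((a, b) if a <= b else (b, a)) in linked

            brute = set()
            genes = sorted(kb.genes)
            for g1, g2, g3 in product(genes, repeat=3):
                if len({g1, g2, g3}) < 3:
                    continue
                if g1 not in part.labels[f"specific:{focal}"]:
                    continue
                if g2 not in part.labels["comorbid"]:
                    continue
                if g3 not in part.labels["partner_specific"]:
                    continue
                if not ((focal, g1) in assoc and connected(g1, g2)
                        and connected(g2, g3)):
                    continue
                for d_end in partners:
                    if (d_end, g3) in assoc:
                        brute.add((focal, g1, g2, g3, d_end))
            assert {m.nodes for m in matches} == brute

    def test_every_match_revalidates_against_the_kb(self):
        kb = four_disease_kb()
        partners = ["DM", "GD", "Ob"]
        part = with_partner_specific(build_gene_partition(kb, "PE", partners), partners)
        for m in find_pathways(kb, five_slot_pattern("PE", partners), part):
            for records in m.evidence:
                assert records  # each consecutive pair has a supporting record


class TestMergePathways:
    def test_union_counts_each_node_once(self):
        kb = four_disease_kb()
        partners = ["DM", "GD", "Ob"]
        part = with_partner_specific(build_gene_partition(kb, "PE", partners), partners)
        matches = find_pathways(kb, five_slot_pattern("PE", partners), part)
        merged = merge_pathways(matches + matches)  # duplicates collapse
        assert merged.n_nodes == 5
        # 3 association edges (PE-gA, DM-gB ... only those used) + 2 interactions
        assert merged.n_links == merge_pathways(matches).n_links

    def test_invariant_to_match_order(self):
        rng = np.random.default_rng(37)
        kb = random_kb(rng, n_diseases=4, n_genes=15, assoc_prob=0.35, edge_prob=0.25)
        partners = ["D1", "D2"]
        part = with_partner_specific(build_gene_partition(kb, "D0", partners), partners)
        matches = find_pathways(kb, five_slot_pattern("D0", partners), part)
        fwd = merge_pathways(matches)
        rev = merge_pathways(list(reversed(matches)))
        assert fwd.nodes == rev.nodes
        assert fwd.association_edges == rev.association_edges
        assert fwd.interaction_edges == rev.interaction_edges

    def test_empty_match_list(self):
        merged = merge_pathways([])
        assert merged.n_nodes == 0 and merged.n_links == 0
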