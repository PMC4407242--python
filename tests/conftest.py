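"""Shared fixtures: small hand-built knowledge bases."""

from __future__ import annotations

import numpy as np
import pytest

from associome import Association, Disease, Gene, Interaction, KnowledgeBase


def build_kb(diseases, genes, associations, interactions) -> KnowledgeBase:
    """Assemble a KnowledgeBase from terse tuples.

    ``associations``: (disease_id, gene_id) pairs;
    ``interactions``: (a, b) or (a, b, link_type) tuples.
    """
    kb = KnowledgeBase()
    for d in diseases:
        kb.add_disease(Disease(id=d, name=d))
    for g in genes:
        kb.add_gene(g if isinstance(g, Gene) else Gene(id=g, symbol=g))
    for d, g in associations:
        kb.add_association(Association(disease_id=d, gene_id=g))
    for tup in interactions:
        a, b = tup[0], tup[1]
        link_type = tup[2] if len(tup) > 2 else "association"
        kb.add_interaction(Interaction(a_id=a, b_id=b, link_type=link_type))
    kb.validate()
    return kb


def random_kb(rng: np.random.Generator, n_diseases=5, n_genes=30,
              assoc_prob=0.2, edge_prob=0.1) -> KnowledgeBase:
    """Small Erdos-Renyi-style KB for brute-force oracle comparisons."""
    diseases = [f"D{i}" for i in range(n_diseases)]
    genes = [f"g{i}" for i in range(n_genes)]
    assocs = [(d, g) for d in diseases for g in genes if rng.random() < assoc_prob]
    inters = [
        (genes[i], genes[j])
        for i in range(n_genes) for j in range(i + 1, n_genes)
        if rng.random() < edge_prob
    ]
    return build_kb(diseases, genes, assocs, inters)


@pytest.fixture
def tiny_kb() -> KnowledgeBase:
    """Two diseases sharing one gene; a 4-gene interaction chain.

    D1 -> {g1, g2, g3};  D2 -> {g2, g3};  D3 -> {g3}
    edges: g1-g2 (association + expression), g2-g3, g3-g4
    """
    return build_kb(
        diseases=["D1", "D2", "D3"],
        genes=["g1", "g2", "g3", "g4", "g5"],
        associations=[("D1", "g1"), ("D1", "g2"), ("D1", "g3"),
                      ("D2", "g2"), ("D2", "g3"), ("D3", "g3")],
        interactions=[("g1", "g2", "association"), ("g1", "g2", "expression"),
                      ("g2", "g3", "binding"), ("g3", "g4", "association")],
    )
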