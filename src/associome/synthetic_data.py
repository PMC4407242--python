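"""Synthetic knowledge bases with planted comorbidity and enrichment signal.

The generator emulates the statistical structure the pipeline assumes of a
literature-derived disease–gene knowledge base:

* heavy-tailed per-disease association-set sizes (log-normal by default — a
  few diseases with hundreds of genes, most with a couple of dozen;
  a uniform alternative is available to check that downstream analyses do
  not depend on the family),
* a gene–gene interaction graph from a configuration model with a power-law
  degree sequence and typed links drawn from a categorical distribution over
  the link-type vocabulary,
* planted comorbid disease pairs sharing ``n_shared`` genes drawn from a
  common comorbid pool (so that pairs sharing a focal disease also yield a
  non-trivial all-disease intersection), with elevated interconnectivity
  ``rho`` among the shared genes, and
* annotation terms with planted enrichment in the comorbid core.

Planted interconnectivity is realized by **rewiring** existing background
edges onto planted gene pairs, preserving the total edge count so that
degree-matched nulls remain honest.  Each candidate planted pair is decided
once (with probability ``rho``), even when it occurs in several planted
pairs' shared sets.

Everything is reproducible from ``seed``; ground truth is returned (and can
be written) separately — the pipeline never reads it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .enrichment import AnnotationSet
from .knowledge_base import (
    Association,
    Disease,
    Gene,
    Interaction,
    KnowledgeBase,
)

__all__ = [
    "PlantedPair",
    "PlantedTerm",
    "SyntheticConfig",
    "GroundTruth",
    "generate_kb",
    "generate_annotation",
    "write_ground_truth",
]

#: Default link-type mix, loosely following the proportions seen in curated
#: molecular-interaction networks (plain association dominates, then
#: expression regulation, transport regulation, expression, ...).
DEFAULT_LINK_TYPE_WEIGHTS: dict[str, float] = {
    "association": 0.45,
    "expression": 0.11,
    "co-expression": 0.05,
    "up-regulation": 0.06,
    "down-regulation": 0.06,
    "regulation_of_activity": 0.04,
    "protein_protein": 0.02,
    "transport_regulation": 0.07,
    "catalysis": 0.01,
    "degradation_regulation": 0.02,
    "binding": 0.05,
    "other": 0.06,
}


@dataclass(frozen=True)
class PlantedPair:
    """A comorbid disease pair sharing ``n_shared`` genes, with probability
    ``rho`` that any two planted shared genes are directly linked."""

    disease_a: str
    disease_b: str
    n_shared: int
    rho: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must be in [0, 1]")
        if self.n_shared < 0:
            raise ValueError("n_shared must be non-negative")


@dataclass(frozen=True)
class PlantedTerm:
    """An annotation term drawing ``fraction_from_comorbid`` of its
    ``n_annotated`` genes from the comorbid ground-truth core."""

    term_id: str
    n_annotated: int
    fraction_from_comorbid: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_from_comorbid <= 1.0):
            raise ValueError("fraction_from_comorbid must be in [0, 1]")


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults are the package's study conditions."""

    n_diseases: int = 60
    n_genes: int = 1500
    # association-set size model: log-normal on log-size (heavy tail)
    assoc_size_model: str = "lognormal"  # "lognormal" | "uniform"
    mean_log_assoc_size: float = 3.0     # median ~20 genes per disease
    sd_log_assoc_size: float = 0.8
    uniform_size_range: tuple[int, int] = (5, 60)
    # interaction graph: configuration model with power-law degrees
    degree_exponent: float = 2.5
    min_degree: int = 1
    max_degree: int | None = None        # default: round(sqrt(n_genes))
    link_type_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LINK_TYPE_WEIGHTS)
    )
    # planted structure
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    comorbid_pool_size: int = 30
    planted_terms: list[PlantedTerm] = field(default_factory=list)
    n_background_terms: int = 50
    background_term_log_mean: float = 2.7
    background_term_log_sd: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if self.n_diseases < 1 or self.n_genes < 2:
            raise ValueError("need at least 1 disease and 2 genes")
        for p in self.planted_pairs:
            if p.n_shared > self.comorbid_pool_size:
                raise ValueError(
                    f"n_shared={p.n_shared} exceeds comorbid pool size "
                    f"{self.comorbid_pool_size}"
                )
            if p.n_shared > self.n_genes:
                raise ValueError("n_shared exceeds the gene universe")
        if self.comorbid_pool_size > self.n_genes:
            raise ValueError("comorbid pool larger than gene universe")


@dataclass
class GroundTruth:
    """What was planted; the pipeline never reads this."""

    planted_shared: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    comorbid_pool: set[str] = field(default_factory=set)
    comorbid_core: set[str] = field(default_factory=set)  # realized all-disease intersection
    planted_edges: set[tuple[str, str]] = field(default_factory=set)
    planted_term_genes: dict[str, set[str]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def _disease_id(i: int) -> str:
    return f"D{i + 1:03d}"


def _gene_id(i: int) -> str:
    return f"G{i + 1:04d}"


def _sample_set_sizes(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    if config.assoc_size_model == "lognormal":
        raw = rng.lognormal(config.mean_log_assoc_size, config.sd_log_assoc_size,
                            size=config.n_diseases)
        sizes = np.clip(np.rint(raw).astype(int), 1, config.n_genes // 2)
    elif config.assoc_size_model == "uniform":
        lo, hi = config.uniform_size_range
        sizes = rng.integers(lo, hi + 1, size=config.n_diseases)
    else:
        raise ValueError(f"unknown assoc_size_model {config.assoc_size_model!r}")
    return sizes


def _power_law_degree_sequence(config: SyntheticConfig, rng: np.random.Generator) -> list[int]:
    d_min = config.min_degree
    d_max = config.max_degree or max(d_min + 1, int(round(config.n_genes ** 0.5)))
    degrees = np.arange(d_min, d_max + 1)
    weights = degrees.astype(float) ** (-config.degree_exponent)
    weights /= weights.sum()
    seq = rng.choice(degrees, size=config.n_genes, p=weights)
    if seq.sum() % 2 == 1:
        seq[int(rng.integers(0, config.n_genes))] += 1
    return [int(x) for x in seq]


def generate_kb(config: SyntheticConfig) -> tuple[KnowledgeBase, GroundTruth]:
    """Generate a knowledge base with the configured planted structure.

    Returns (kb, ground_truth).  For each planted pair the realized
    shared-gene count is at least ``n_shared``; total interaction-edge count
    is preserved under rho-rewiring.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()

    disease_ids = [_disease_id(i) for i in range(config.n_diseases)]
    gene_ids = [_gene_id(i) for i in range(config.n_genes)]

    kb = KnowledgeBase()
    for d in disease_ids:
        kb.add_disease(Disease(id=d, name=f"synthetic disease {d}"))
    for g in gene_ids:
        kb.add_gene(Gene(id=g, symbol=g))

    # ---- planted shared genes drawn from a common comorbid pool
    planted_assignment: dict[str, set[str]] = {d: set() for d in disease_ids}
    if config.planted_pairs:
        pool = sorted(rng.choice(gene_ids, size=config.comorbid_pool_size, replace=False))
        truth.comorbid_pool = set(pool)
        for pair in config.planted_pairs:
            for d in (pair.disease_a, pair.disease_b):
                if d not in kb.diseases:
                    raise ValueError(f"planted pair names unknown disease {d!r}")
            shared = set(rng.choice(pool, size=pair.n_shared, replace=False))
            key = tuple(sorted((pair.disease_a, pair.disease_b)))
            truth.planted_shared[key] = shared
            planted_assignment[pair.disease_a] |= shared
            planted_assignment[pair.disease_b] |= shared

    # ---- association sets: planted genes first, uniform fill to target size
    sizes = _sample_set_sizes(config, rng)
    gene_array = np.array(gene_ids)
    disease_genes: dict[str, set[str]] = {}
    for d, size in zip(disease_ids, sizes):
        members = set(planted_assignment[d])
        target = max(int(size), len(members))
        while len(members) < target:
            extra = rng.choice(gene_array, size=target - len(members), replace=False)
            members.update(str(g) for g in extra)
        disease_genes[d] = members
    for d in disease_ids:
        for g in sorted(disease_genes[d]):
            kb.add_association(Association(disease_id=d, gene_id=g, source="synthetic"))

    # realized comorbid core: genes shared by every disease named in a planted pair
    if config.planted_pairs:
        planted_diseases = sorted(
            {p.disease_a for p in config.planted_pairs}
            | {p.disease_b for p in config.planted_pairs}
        )
        truth.comorbid_core = set.intersection(
            *(disease_genes[d] for d in planted_diseases)
        )

    # ---- interaction graph: configuration model, simple graph
    import networkx as nx

    seq = _power_law_degree_sequence(config, rng)
    g_multi = nx.configuration_model(seq, seed=int(rng.integers(0, 2**31 - 1)))
    graph = nx.Graph()
    graph.add_nodes_from(range(config.n_genes))
    for u, v in g_multi.edges():
        if u != v:
            graph.add_edge(u, v)  # parallel edges erased

    edges: set[tuple[str, str]] = set()
    for u, v in graph.edges():
        a, b = gene_ids[u], gene_ids[v]
        edges.add((a, b) if a <= b else (b, a))

    # ---- rho-interconnectivity by rewiring background edges onto pool pairs
    if config.planted_pairs:
        candidate_pairs: set[tuple[str, str]] = set()
        for shared in truth.planted_shared.values():
            for a, b in combinations(sorted(shared), 2):
                candidate_pairs.add((a, b))
        planted_edges = {
            pair for pair in sorted(candidate_pairs)
            if rng.random() < max(p.rho for p in config.planted_pairs)
        } if len({p.rho for p in config.planted_pairs}) == 1 else None
        if planted_edges is None:
            # per-pair rho: a candidate pair is decided once, at the max rho of
            # the planted pairs whose shared set contains it
            pair_rho: dict[tuple[str, str], float] = {}
            for planted in config.planted_pairs:
                key = tuple(sorted((planted.disease_a, planted.disease_b)))
                for a, b in combinations(sorted(truth.planted_shared[key]), 2):
                    pr = pair_rho.get((a, b), 0.0)
                    pair_rho[(a, b)] = max(pr, planted.rho)
            planted_edges = {
                pair for pair in sorted(pair_rho) if rng.random() < pair_rho[pair]
            }
        to_add = sorted(planted_edges - edges)
        planted_nodes = {g for pair in candidate_pairs for g in pair}
        removable = sorted(
            e for e in edges
            if e[0] not in planted_nodes and e[1] not in planted_nodes
        )
        if len(removable) < len(to_add):
            truth.warnings.append(
                f"only {len(removable)} background edges available to rewire "
                f"for {len(to_add)} planted links; edge count not preserved"
            )
        drop_idx = rng.choice(len(removable), size=min(len(to_add), len(removable)),
                              replace=False)
        for i in sorted(drop_idx, reverse=True):
            edges.discard(removable[i])
        edges.update(to_add)
        truth.planted_edges = set(planted_edges)

    # ---- typed links
    types = sorted(config.link_type_weights)
    weights = np.array([config.link_type_weights[t] for t in types], dtype=float)
    weights /= weights.sum()
    for a, b in sorted(edges):
        link_type = types[int(rng.choice(len(types), p=weights))]
        kb.add_interaction(Interaction(a_id=a, b_id=b, link_type=link_type))

    kb.validate()
    return kb, truth


def generate_annotation(config: SyntheticConfig, kb: KnowledgeBase,
                        truth: GroundTruth | None = None) -> tuple[AnnotationSet, GroundTruth]:
    """Generate an annotation with planted and background terms.

    Planted terms draw ``fraction_from_comorbid`` of their genes from the
    comorbid ground-truth core (falling back to the comorbid pool when the
    core is smaller than requested) and the rest uniformly; background terms
    are uniform draws.  Reproducible from ``config.seed`` (offset so the
    annotation stream is independent of the KB stream).
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    truth = truth if truth is not None else GroundTruth()
    gene_ids = sorted(kb.genes)
    gene_array = np.array(gene_ids)
    term_genes: dict[str, set[str]] = {}

    core = sorted(truth.comorbid_core) or sorted(truth.comorbid_pool)
    for term in config.planted_terms:
        n_from_core = int(round(term.fraction_from_comorbid * term.n_annotated))
        if n_from_core > len(core):
            raise ValueError(
                f"term {term.term_id!r} requests {n_from_core} comorbid genes "
                f"but only {len(core)} are available"
            )
        members = set(rng.choice(core, size=n_from_core, replace=False)) if n_from_core else set()
        others = [g for g in gene_ids if g not in members]
        n_rest = term.n_annotated - len(members)
        if n_rest > len(others):
            raise ValueError(f"term {term.term_id!r} larger than the gene universe")
        if n_rest:
            members.update(str(g) for g in rng.choice(others, size=n_rest, replace=False))
        term_genes[term.term_id] = members
        truth.planted_term_genes[term.term_id] = set(members)

    for i in range(config.n_background_terms):
        size = int(np.clip(
            round(rng.lognormal(config.background_term_log_mean,
                                config.background_term_log_sd)),
            2, len(gene_ids),
        ))
        term_id = f"T{i + 1:04d}"
        term_genes[term_id] = set(
            str(g) for g in rng.choice(gene_array, size=size, replace=False)
        )

    annotation = AnnotationSet(term_genes=term_genes, reference_universe=set(gene_ids))
    return annotation, truth


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Ground-truth TSV (record_type, key, gene/pair) written alongside the KB."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("record_type\tkey\tvalue\n")
        for (a, b), genes in sorted(truth.planted_shared.items()):
            for g in sorted(genes):
                fh.write(f"planted_shared\t{a}|{b}\t{g}\n")
        for g in sorted(truth.comorbid_pool):
            fh.write(f"comorbid_pool\t-\t{g}\n")
        for g in sorted(truth.comorbid_core):
            fh.write(f"comorbid_core\t-\t{g}\n")
        for a, b in sorted(truth.planted_edges):
            fh.write(f"planted_edge\t-\t{a}|{b}\n")
        for term, genes in sorted(truth.planted_term_genes.items()):
            for g in sorted(genes):
                fh.write(f"planted_term\t{term}\t{g}\n")
        for w in truth.warnings:
            fh.write(f"warning\t-\t{w}\n")
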