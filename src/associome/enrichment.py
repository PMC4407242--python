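"""GO overrepresentation with connectivity-rate (CR) re-ranking.

Overrepresentation of annotation terms in a study gene set is scored with the
exact hypergeometric upper tail, P(X >= k) for k study genes among K
annotated genes in a universe of N, followed by Benjamini–Hochberg FDR
control over all tested terms.  The reference set is the whole annotation
universe.

Each enriched term is additionally characterized by its **connectivity rate**:
the fraction of the term's study genes' unordered pairs that are directly
linked in the analysed molecular network,

    CR = (# connected pairs in the group) / C(|group|, 2),

undefined (missing) for groups of fewer than two genes.  Ranking by
descending CR demotes broad, loosely connected processes and promotes small
tightly interacting groups.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Set
from dataclasses import dataclass, field

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationSet",
    "EnrichedProcess",
    "load_annotation",
    "write_annotation",
    "propagate_with_ontology",
    "benjamini_hochberg",
    "hypergeometric_enrichment",
    "connectivity_rate",
    "rank_by_cr",
    "attach_connectivity_rates",
    "write_enrichment",
]


@dataclass
class AnnotationSet:
    """Term → gene mapping over an explicit reference universe."""

    term_genes: dict[str, set[str]] = field(default_factory=dict)
    reference_universe: set[str] = field(default_factory=set)
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.term_genes.items():
            extra = genes - self.reference_universe
            if extra:
                raise ValueError(
                    f"term {term!r} annotates genes outside the universe: {sorted(extra)[:5]}"
                )


def load_annotation(path, universe: Set[str] | None = None) -> AnnotationSet:
    """Load an annotation from GAF 2.1 or a plain ``term_id<TAB>gene_id`` TSV.

    GAF rows are recognized by their column count (>= 15; columns 2 and 5 are
    the gene id and GO id).  The universe defaults to the union of all
    annotated genes.
    """
    term_genes: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith(("!", "#")):
                continue
            parts = line.split("\t")
            if len(parts) >= 15:  # GAF 2.1
                gene_id, term_id = parts[1], parts[4]
            elif len(parts) >= 2:
                term_id, gene_id = parts[0], parts[1]
            else:
                continue
            if term_id == "term_id":
                continue
            term_genes.setdefault(term_id, set()).add(gene_id)
    annotated = set().union(*term_genes.values()) if term_genes else set()
    if universe is None:
        universe = annotated
    return AnnotationSet(term_genes=term_genes, reference_universe=set(universe) | annotated)


def write_annotation(annotation: AnnotationSet, path) -> None:
    """Plain two-column ``term_id<TAB>gene_id`` writer (sorted, byte-stable)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("term_id\tgene_id\n")
        for term in sorted(annotation.term_genes):
            for gene in sorted(annotation.term_genes[term]):
                fh.write(f"{term}\t{gene}\n")


def propagate_with_ontology(annotation: AnnotationSet, obo_path) -> AnnotationSet:
    """Propagate annotations to ancestor terms (true-path rule).

    Applied only when an ontology file is supplied; without one the term→gene
    map is used as-is (pre-propagated inputs).  ``is_a`` and ``part_of``
    relations are followed.
    """
    import networkx as nx
    import obonet

    graph = obonet.read_obo(obo_path)
    propagated = {t: set(g) for t, g in annotation.term_genes.items()}
    names = dict(annotation.term_names)
    for node, data in graph.nodes(data=True):
        if "name" in data:
            names.setdefault(node, data["name"])
    for term in list(annotation.term_genes):
        if term not in graph:
            continue
        # obonet edges point child -> parent for is_a/part_of
        for ancestor in nx.descendants(graph, term):
            propagated.setdefault(ancestor, set()).update(annotation.term_genes[term])
    propagated = {t: g for t, g in propagated.items() if g}
    return AnnotationSet(
        term_genes=propagated,
        reference_universe=set(annotation.reference_universe),
        term_names=names,
    )


@dataclass
class EnrichedProcess:
    """One annotation term with enrichment statistics and connectivity rate."""

    term_id: str
    term_name: str = ""
    k: int = 0          # study genes annotated to the term
    n_study: int = 0    # study set size (within the universe)
    K: int = 0          # universe genes annotated to the term
    N: int = 0          # universe size
    p_value: float = 1.0
    q_value: float = 1.0
    cr: float | None = None
    study_genes: set[str] = field(default_factory=set)


def benjamini_hochberg(p_values: Iterable[float]) -> list[float]:
    """Step-up BH q-values, mapped back to input order and capped at 1.

    Idempotent and monotone non-decreasing in sorted-p order.
    """
    ps = list(p_values)
    if not ps:
        return []
    for p in ps:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
    _, q, _, _ = multipletests(ps, method="fdr_bh")
    return [min(float(x), 1.0) for x in q]


def hypergeometric_enrichment(study: Set[str], annotation: AnnotationSet) -> list[EnrichedProcess]:
    """Exact upper-tail hypergeometric enrichment over all annotation terms.

    Study genes outside the reference universe are dropped with a warning
    (recorded on the returned records' module logger).  Terms with no study
    gene are excluded.  q-values are BH-adjusted over all tested terms.
    """
    study = set(study)
    if not study:
        raise ValueError("empty study set")
    if not annotation.term_genes:
        raise ValueError("empty annotation")
    universe = annotation.reference_universe
    outside = study - universe
    if outside:
        import warnings

        warnings.warn(
            f"{len(outside)} study genes outside the reference universe dropped",
            stacklevel=2,
        )
        study = study & universe
        if not study:
            raise ValueError("no study genes inside the reference universe")

    N = len(universe)
    n = len(study)
    records: list[EnrichedProcess] = []
    for term_id in sorted(annotation.term_genes):
        annotated = annotation.term_genes[term_id]
        hits = study & annotated
        k = len(hits)
        if k == 0:
            continue
        K = len(annotated)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(k - 1, N, K, n))
        records.append(EnrichedProcess(
            term_id=term_id,
            term_name=annotation.term_names.get(term_id, ""),
            k=k, n_study=n, K=K, N=N, p_value=min(p, 1.0),
            study_genes=hits,
        ))
    qs = benjamini_hochberg([r.p_value for r in records])
    for r, q in zip(records, qs):
        r.q_value = max(q, r.p_value)  # BH step-up already guarantees q >= p
    return records


def connectivity_rate(group: Set[str], kb_or_links) -> float | None:
    """Fraction of a gene group's unordered pairs directly linked in the
    analysed network; None for groups of fewer than two genes.

    ``kb_or_links`` may be a KnowledgeBase or an iterable of interaction
    records (each with a ``pair()`` method) defining the network.
    """
    group = set(group)
    m = len(group)
    if m < 2:
        return None
    if hasattr(kb_or_links, "interactions"):
        links = kb_or_links.interactions
    else:
        links = kb_or_links
    connected = {
        l.pair() for l in links
        if l.a_id in group and l.b_id in group
    }
    return len(connected) / (m * (m - 1) // 2)


def attach_connectivity_rates(records: Iterable[EnrichedProcess], kb_or_links) -> None:
    """Compute CR for each enriched term's study genes on the given network."""
    for r in records:
        r.cr = connectivity_rate(r.study_genes, kb_or_links)


def rank_by_cr(records: Iterable[EnrichedProcess]) -> list[EnrichedProcess]:
    """Order enriched terms by descending CR; ties broken by ascending
    q-value then term id; missing-CR records listed after scored ones."""
    scored = [r for r in records if r.cr is not None]
    missing = [r for r in records if r.cr is None]
    scored.sort(key=lambda r: (-r.cr, r.q_value, r.term_id))
    missing.sort(key=lambda r: (r.q_value, r.term_id))
    return scored + missing


def write_enrichment(records: Iterable[EnrichedProcess], path) -> None:
    cols = ["term_id", "name", "k", "n", "K", "N", "p", "q", "CR"]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write("\t".join([
                r.term_id, r.term_name, str(r.k), str(r.n_study),
                str(r.K), str(r.N),
                format(r.p_value, ".6g"), format(r.q_value, ".6g"),
                "NA" if r.cr is None else format(r.cr, ".6g"),
            ]) + "\n")
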