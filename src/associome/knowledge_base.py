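"""Disease–gene–interaction knowledge base: data model and I/O.

The knowledge base is the universe every permutation null samples from.  It
holds four collections — diseases, genes (gene or protein nodes), disease–gene
associations, and typed gene–gene interactions — with referential integrity
over all identifiers.  Identifiers are case-sensitive opaque strings; no
synonym resolution is attempted.

File dialects
-------------
Associations: TSV with header ``disease_id<TAB>gene_id<TAB>source``; lines
starting with ``#`` are comments.  An optional declared-universe comment
(``#universe-diseases: D1 D2 ...`` / ``#universe-genes: ...``) turns unknown
identifiers into load errors instead of implicit declarations.

Interactions: SIF dialect ``node_a<TAB>link_type<TAB>node_b``, one record per
typed link.  An optional sidecar node table ``id<TAB>entity_class<TAB>
coding_gene_id`` declares gene/protein duality.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import networkx as nx

__all__ = [
    "LINK_TYPES",
    "Gene",
    "Disease",
    "Association",
    "Interaction",
    "KnowledgeBase",
    "KnowledgeBaseError",
    "load_knowledge_base",
    "write_knowledge_base",
    "collapse_to_protein_network",
    "to_networkx",
    "write_graphml",
    "write_sif",
]

#: Controlled vocabulary of interaction link types.  Unlisted types are kept
#: verbatim but flagged with a load warning.
LINK_TYPES = frozenset(
    {
        "association",
        "expression",
        "co-expression",
        "up-regulation",
        "down-regulation",
        "regulation_of_activity",
        "protein_protein",
        "transport_regulation",
        "catalysis",
        "degradation_regulation",
        "binding",
        "other",
    }
)


class KnowledgeBaseError(ValueError):
    """Raised on malformed input files or referential-integrity violations."""


@dataclass(frozen=True)
class Gene:
    """A gene or protein node.

    ``entity_class`` distinguishes gene from protein vertices; a protein may
    name its coding gene through ``coding_gene_id`` (used when collapsing a
    mixed network to protein level).
    """

    id: str
    symbol: str = ""
    entity_class: str = "gene"  # "gene" | "protein"
    coding_gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.entity_class not in ("gene", "protein"):
            raise KnowledgeBaseError(
                f"entity_class must be 'gene' or 'protein', got {self.entity_class!r}"
            )


@dataclass(frozen=True)
class Disease:
    id: str
    name: str = ""


@dataclass(frozen=True)
class Association:
    """One disease–gene association with a free-text provenance tag."""

    disease_id: str
    gene_id: str
    source: str = ""


@dataclass(frozen=True)
class Interaction:
    """One typed link between two gene/protein nodes.

    Several records between the same pair with different link types may
    coexist.  Direction is preserved for reporting but ignored for degree and
    connectivity.
    """

    a_id: str
    b_id: str
    link_type: str = "association"
    directed: bool = False

    def pair(self) -> tuple[str, str]:
        """Unordered endpoint pair, canonically sorted."""
        return (self.a_id, self.b_id) if self.a_id <= self.b_id else (self.b_id, self.a_id)


@dataclass
class KnowledgeBase:
    """In-memory disease–gene association and interaction store."""

    genes: dict[str, Gene] = field(default_factory=dict)
    diseases: dict[str, Disease] = field(default_factory=dict)
    associations: list[Association] = field(default_factory=list)
    interactions: list[Interaction] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    # Derived lookups, built lazily and invalidated on mutation.
    _disease_genes: dict[str, set[str]] | None = field(default=None, repr=False)
    _partners: dict[str, set[str]] | None = field(default=None, repr=False)
    _record_degree: dict[str, int] | None = field(default=None, repr=False)

    # ------------------------------------------------------------------ build
    def add_gene(self, gene: Gene) -> None:
        existing = self.genes.get(gene.id)
        if existing is not None and existing != gene:
            raise KnowledgeBaseError(f"duplicate gene id {gene.id!r} with conflicting metadata")
        self.genes[gene.id] = gene
        self._invalidate()

    def add_disease(self, disease: Disease) -> None:
        existing = self.diseases.get(disease.id)
        if existing is not None and existing != disease:
            raise KnowledgeBaseError(
                f"duplicate disease id {disease.id!r} with conflicting metadata"
            )
        self.diseases[disease.id] = disease
        self._invalidate()

    def add_association(self, assoc: Association) -> None:
        if assoc.disease_id not in self.diseases:
            raise KnowledgeBaseError(f"association references unknown disease {assoc.disease_id!r}")
        if assoc.gene_id not in self.genes:
            raise KnowledgeBaseError(f"association references unknown gene {assoc.gene_id!r}")
        self.associations.append(assoc)
        self._invalidate()

    def add_interaction(self, link: Interaction) -> None:
        if link.a_id == link.b_id:
            raise KnowledgeBaseError(f"self-link on {link.a_id!r} rejected")
        for end in (link.a_id, link.b_id):
            if end not in self.genes:
                raise KnowledgeBaseError(f"interaction references unknown node {end!r}")
        self.interactions.append(link)
        self._invalidate()

    def _invalidate(self) -> None:
        self._disease_genes = None
        self._partners = None
        self._record_degree = None

    # ---------------------------------------------------------------- queries
    def genes_for(self, disease_id: str) -> set[str]:
        """Set of gene ids associated with ``disease_id`` (may be empty)."""
        if disease_id not in self.diseases:
            raise KeyError(f"unknown disease id {disease_id!r}")
        return set(self._disease_gene_map().get(disease_id, set()))

    def degree(self, gene_id: str, mode: str = "partners") -> int:
        """Interaction degree of a gene.

        ``mode="partners"`` (default) counts distinct interaction partners;
        ``mode="records"`` counts link records, so a pair linked by two typed
        edges contributes two.
        """
        if gene_id not in self.genes:
            raise KeyError(f"unknown gene id {gene_id!r}")
        if mode == "partners":
            return len(self._partner_map().get(gene_id, set()))
        if mode == "records":
            return self._record_degree_map().get(gene_id, 0)
        raise ValueError(f"unknown degree mode {mode!r}")

    def partners(self, gene_id: str) -> set[str]:
        if gene_id not in self.genes:
            raise KeyError(f"unknown gene id {gene_id!r}")
        return set(self._partner_map().get(gene_id, set()))

    def eligible_diseases(self) -> list[str]:
        """Diseases associated with at least one gene, sorted by id.

        Diseases with no associated gene are discarded from every null-model
        analysis.
        """
        dmap = self._disease_gene_map()
        return sorted(d for d in self.diseases if dmap.get(d))

    def _disease_gene_map(self) -> dict[str, set[str]]:
        if self._disease_genes is None:
            m: dict[str, set[str]] = {}
            for a in self.associations:
                m.setdefault(a.disease_id, set()).add(a.gene_id)
            self._disease_genes = m
        return self._disease_genes

    def _partner_map(self) -> dict[str, set[str]]:
        if self._partners is None:
            m: dict[str, set[str]] = {}
            for link in self.interactions:
                m.setdefault(link.a_id, set()).add(link.b_id)
                m.setdefault(link.b_id, set()).add(link.a_id)
            self._partners = m
        return self._partners

    def _record_degree_map(self) -> dict[str, int]:
        if self._record_degree is None:
            m: dict[str, int] = {}
            for link in self.interactions:
                m[link.a_id] = m.get(link.a_id, 0) + 1
                m[link.b_id] = m.get(link.b_id, 0) + 1
            self._record_degree = m
        return self._record_degree

    # ------------------------------------------------------------- invariants
    def validate(self) -> None:
        """Check referential integrity; raise KnowledgeBaseError on violation."""
        seen_pairs: set[tuple[str, str]] = set()
        for a in self.associations:
            if a.disease_id not in self.diseases:
                raise KnowledgeBaseError(f"dangling disease id {a.disease_id!r}")
            if a.gene_id not in self.genes:
                raise KnowledgeBaseError(f"dangling gene id {a.gene_id!r}")
            key = (a.disease_id, a.gene_id)
            if key in seen_pairs:
                raise KnowledgeBaseError(f"duplicate association {key}")
            seen_pairs.add(key)
        for link in self.interactions:
            if link.a_id not in self.genes or link.b_id not in self.genes:
                raise KnowledgeBaseError(f"dangling interaction endpoint in {link}")
            if link.a_id == link.b_id:
                raise KnowledgeBaseError(f"self-link {link}")
        for g in self.genes.values():
            if g.coding_gene_id is not None and g.coding_gene_id not in self.genes:
                raise KnowledgeBaseError(
                    f"protein {g.id!r} references unknown coding gene {g.coding_gene_id!r}"
                )


# ---------------------------------------------------------------------- I/O


def _parse_universe_header(line: str) -> tuple[str, set[str]] | None:
    for key in ("universe-diseases", "universe-genes"):
        prefix = f"#{key}:"
        if line.startswith(prefix):
            return key, set(line[len(prefix):].split())
    return None


def load_knowledge_base(
    assoc_path,
    interaction_path,
    nodes_path=None,
) -> KnowledgeBase:
    """Load a knowledge base from an association TSV and an interaction SIF.

    Diseases and genes are declared implicitly by the rows that mention them
    unless the association file carries a declared-universe header, in which
    case out-of-universe identifiers are load errors.  Malformed rows are
    rejected with their line numbers.  Self-links and unknown link types are
    recorded as warnings (self-links are dropped).
    """
    kb = KnowledgeBase()

    declared_nodes: dict[str, Gene] = {}
    if nodes_path is not None:
        with open(nodes_path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if lineno == 1 and parts[0] in ("id", "gene_id"):
                    continue
                if len(parts) < 2:
                    raise KnowledgeBaseError(
                        f"{nodes_path}:{lineno}: expected id<TAB>entity_class"
                    )
                node_id, entity_class = parts[0], parts[1]
                coding = parts[2] if len(parts) > 2 and parts[2] else None
                declared_nodes[node_id] = Gene(
                    id=node_id, symbol=node_id, entity_class=entity_class,
                    coding_gene_id=coding,
                )

    universe_diseases: set[str] | None = None
    universe_genes: set[str] | None = None
    assoc_rows: list[tuple[int, str, str, str]] = []
    with open(assoc_path, encoding="utf-8") as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parsed = _parse_universe_header(line)
                if parsed is not None:
                    key, ids = parsed
                    if key == "universe-diseases":
                        universe_diseases = ids
                    else:
                        universe_genes = ids
                continue
            parts = line.split("\t")
            if not header_seen:
                header_seen = True
                if parts[0] == "disease_id":
                    continue
            if len(parts) < 2:
                raise KnowledgeBaseError(
                    f"{assoc_path}:{lineno}: expected disease_id<TAB>gene_id[<TAB>source]"
                )
            source = parts[2] if len(parts) > 2 else ""
            assoc_rows.append((lineno, parts[0], parts[1], source))

    for lineno, d_id, g_id, _ in assoc_rows:
        if universe_diseases is not None and d_id not in universe_diseases:
            raise KnowledgeBaseError(
                f"{assoc_path}:{lineno}: disease {d_id!r} not in declared universe"
            )
        if universe_genes is not None and g_id not in universe_genes:
            raise KnowledgeBaseError(
                f"{assoc_path}:{lineno}: gene {g_id!r} not in declared universe"
            )

    int_rows: list[tuple[int, str, str, str]] = []
    with open(interaction_path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] in ("node_a", "a_id") and lineno == 1:
                continue
            if len(parts) < 3:
                raise KnowledgeBaseError(
                    f"{interaction_path}:{lineno}: expected node_a<TAB>link_type<TAB>node_b"
                )
            int_rows.append((lineno, parts[0], parts[1], parts[2]))

    if universe_diseases is not None:
        for d_id in sorted(universe_diseases):
            kb.add_disease(Disease(id=d_id, name=d_id))
    for _, d_id, _, _ in assoc_rows:
        if d_id not in kb.diseases:
            kb.add_disease(Disease(id=d_id, name=d_id))

    def ensure_gene(g_id: str) -> None:
        if g_id in kb.genes:
            return
        kb.genes[g_id] = declared_nodes.get(g_id, Gene(id=g_id, symbol=g_id))

    if universe_genes is not None:
        for g_id in sorted(universe_genes):
            ensure_gene(g_id)
    for node_id in declared_nodes:
        ensure_gene(node_id)
    for _, _, g_id, _ in assoc_rows:
        ensure_gene(g_id)
    for _, a_id, _, b_id in int_rows:
        ensure_gene(a_id)
        ensure_gene(b_id)

    seen_pairs: set[tuple[str, str]] = set()
    for lineno, d_id, g_id, source in assoc_rows:
        key = (d_id, g_id)
        if key in seen_pairs:
            kb.warnings.append(
                f"{assoc_path}:{lineno}: duplicate association {key}, keeping first"
            )
            continue
        seen_pairs.add(key)
        kb.add_association(Association(disease_id=d_id, gene_id=g_id, source=source))

    for lineno, a_id, link_type, b_id in int_rows:
        if a_id == b_id:
            kb.warnings.append(f"{interaction_path}:{lineno}: self-link on {a_id!r} dropped")
            continue
        if link_type not in LINK_TYPES:
            kb.warnings.append(
                f"{interaction_path}:{lineno}: link type {link_type!r} not in vocabulary"
            )
        kb.add_interaction(Interaction(a_id=a_id, b_id=b_id, link_type=link_type))

    kb.validate()
    return kb


def write_knowledge_base(kb: KnowledgeBase, assoc_path, interaction_path, nodes_path=None) -> None:
    """Write the TSV/SIF files `load_knowledge_base` reads; byte-stable
    (rows sorted lexicographically by id)."""
    with open(assoc_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("disease_id\tgene_id\tsource\n")
        rows = sorted((a.disease_id, a.gene_id, a.source) for a in kb.associations)
        for d_id, g_id, source in rows:
            fh.write(f"{d_id}\t{g_id}\t{source}\n")
    with open(interaction_path, "w", encoding="utf-8", newline="\n") as fh:
        rows2 = sorted((i.pair()[0], i.link_type, i.pair()[1]) for i in kb.interactions)
        for a_id, link_type, b_id in rows2:
            fh.write(f"{a_id}\t{link_type}\t{b_id}\n")
    if nodes_path is not None:
        with open(nodes_path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("id\tentity_class\tcoding_gene_id\n")
            for g_id in sorted(kb.genes):
                g = kb.genes[g_id]
                fh.write(f"{g.id}\t{g.entity_class}\t{g.coding_gene_id or ''}\n")


# -------------------------------------------------------- protein collapse


def collapse_to_protein_network(kb: KnowledgeBase, node_ids: set[str] | None = None) -> KnowledgeBase:
    """Collapse a mixed gene/protein network to protein level.

    Every link incident to a gene node is re-attached to that gene's protein
    node; gene nodes are removed.  Self-links produced by the reassignment are
    dropped and duplicate (pair, link_type) records deduplicated.  A gene node
    with no corresponding protein is reported in warnings and dropped.
    Idempotent: a protein-only network passes through unchanged.
    """
    if node_ids is None:
        node_ids = set(kb.genes)
    node_ids = set(node_ids)

    # protein -> coding gene map inverted: gene id -> its protein node id
    gene_to_protein: dict[str, str] = {}
    for g in kb.genes.values():
        if g.entity_class == "protein" and g.coding_gene_id is not None:
            gene_to_protein[g.coding_gene_id] = g.id

    out = KnowledgeBase()
    dropped: list[str] = []
    kept: set[str] = set()
    for node_id in sorted(node_ids):
        node = kb.genes[node_id]
        if node.entity_class == "protein":
            out.add_gene(node)
            kept.add(node_id)
        elif node_id in gene_to_protein:
            pid = gene_to_protein[node_id]
            if pid in node_ids:
                kept.add(node_id)  # will be remapped
        else:
            dropped.append(node_id)
    if dropped:
        out.warnings.append(
            "gene nodes without a protein counterpart dropped: " + ",".join(sorted(dropped))
        )

    def remap(node_id: str) -> str | None:
        node = kb.genes[node_id]
        if node.entity_class == "protein":
            return node_id if node_id in out.genes else None
        pid = gene_to_protein.get(node_id)
        return pid if pid is not None and pid in out.genes else None

    seen: set[tuple[str, str, str]] = set()
    for link in kb.interactions:
        if link.a_id not in node_ids or link.b_id not in node_ids:
            continue
        a2, b2 = remap(link.a_id), remap(link.b_id)
        if a2 is None or b2 is None or a2 == b2:
            continue
        pair = (a2, b2) if a2 <= b2 else (b2, a2)
        key = (pair[0], pair[1], link.link_type)
        if key in seen:
            continue
        seen.add(key)
        out.add_interaction(Interaction(a_id=pair[0], b_id=pair[1], link_type=link.link_type))

    out.diseases = dict(kb.diseases)
    for a in kb.associations:
        target = remap(a.gene_id)
        if target is not None:
            rec = replace(a, gene_id=target)
            if (rec.disease_id, rec.gene_id) not in {
                (x.disease_id, x.gene_id) for x in out.associations
            }:
                out.associations.append(rec)
    out._invalidate()
    return out


# ----------------------------------------------------------------- exports


def to_networkx(kb: KnowledgeBase, gene_ids: set[str] | None = None) -> nx.MultiGraph:
    """Interaction multigraph (one edge per typed link record)."""
    g = nx.MultiGraph()
    ids = sorted(gene_ids) if gene_ids is not None else sorted(kb.genes)
    for node_id in ids:
        node = kb.genes[node_id]
        g.add_node(node_id, symbol=node.symbol, entity_class=node.entity_class)
    allowed = set(ids)
    for link in sorted(kb.interactions, key=lambda x: (x.pair(), x.link_type)):
        if link.a_id in allowed and link.b_id in allowed:
            a, b = link.pair()
            g.add_edge(a, b, link_type=link.link_type, directed=link.directed)
    return g


def write_graphml(kb: KnowledgeBase, path, gene_ids: set[str] | None = None) -> None:
    """GraphML export; byte-stable because nodes/edges are added in sorted order."""
    g = to_networkx(kb, gene_ids)
    buf = io.BytesIO()
    nx.write_graphml(g, buf)
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def write_sif(kb: KnowledgeBase, path, gene_ids: set[str] | None = None) -> None:
    allowed = set(gene_ids) if gene_ids is not None else set(kb.genes)
    rows = sorted(
        (link.pair()[0], link.link_type, link.pair()[1])
        for link in kb.interactions
        if link.a_id in allowed and link.b_id in allowed
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for a, t, b in rows:
            fh.write(f"{a}\t{t}\t{b}\n")
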