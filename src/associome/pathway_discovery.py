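"""Disease-to-disease pathway enumeration over node-class patterns.

A pathway pattern is an ordered list of slots: the first and last slots name
diseases (a fixed id or a choice set), interior slots constrain genes by a
partition label (e.g. "specific:PE", "comorbid").  The canonical pattern is

    <focal disease> - <gene specific to focal> - <comorbid gene>
    - <gene specific to a partner disease> - <partner disease>

Consecutive disease–gene steps must be supported by an Association record,
gene–gene steps by an Interaction record (any link type by default).  The
complete match set is enumerated; interior genes are pairwise distinct within
a match, and output order is deterministic (lexicographic by node-id
sequence).

The gene partition labels genes by their disease combinations: genes
associated with every configured disease are "comorbid" (and excluded from
every "specific" set); genes associated with a given disease but not comorbid
are "specific:<disease>".
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

__all__ = [
    "DiseaseSlot",
    "GeneSlot",
    "NodeClassPattern",
    "GenePartition",
    "PathwayMatch",
    "MergedNetwork",
    "build_gene_partition",
    "find_pathways",
    "merge_pathways",
    "write_matches",
]


@dataclass(frozen=True)
class DiseaseSlot:
    """A disease slot: matched by any disease id in ``choices``."""

    choices: frozenset[str]

    @classmethod
    def of(cls, *ids: str) -> "DiseaseSlot":
        return cls(choices=frozenset(ids))


@dataclass(frozen=True)
class GeneSlot:
    """A gene slot constrained to a partition label."""

    label: str


@dataclass
class NodeClassPattern:
    """Ordered slot sequence; disease slots bound the pattern, gene slots fill
    the interior; length >= 3."""

    slots: Sequence[DiseaseSlot | GeneSlot]

    def __post_init__(self) -> None:
        if len(self.slots) < 3:
            raise ValueError("pattern needs at least 3 slots")
        if not isinstance(self.slots[0], DiseaseSlot) or not isinstance(self.slots[-1], DiseaseSlot):
            raise ValueError("first and last slots must be disease slots")
        for s in self.slots[1:-1]:
            if not isinstance(s, GeneSlot):
                raise ValueError("interior slots must be gene slots")


@dataclass
class GenePartition:
    """Gene labels derived from disease combinations.

    ``labels["comorbid"]`` is the intersection over all configured diseases;
    ``labels["specific:<D>"]`` holds genes associated with D minus the
    comorbid set.  Genes associated with none of the configured diseases are
    unlabelled.
    """

    labels: dict[str, set[str]] = field(default_factory=dict)

    def members(self, label: str) -> set[str]:
        if label not in self.labels:
            raise KeyError(f"undefined partition label {label!r}")
        return self.labels[label]


def build_gene_partition(kb, focal_disease: str, partner_diseases: Iterable[str]) -> GenePartition:
    """Label genes as comorbid (shared by all diseases) or disease-specific."""
    partners = list(partner_diseases)
    all_diseases = [focal_disease] + partners
    gene_sets = {d: kb.genes_for(d) for d in all_diseases}  # KeyError on unknown
    comorbid = set.intersection(*gene_sets.values()) if gene_sets else set()
    labels: dict[str, set[str]] = {"comorbid": comorbid}
    for d in all_diseases:
        labels[f"specific:{d}"] = gene_sets[d] - comorbid
    return GenePartition(labels=labels)


@dataclass(frozen=True)
class PathwayMatch:
    """One disease→gene…gene→disease chain with its supporting records."""

    nodes: tuple[str, ...]
    evidence: tuple[tuple, ...]  # per consecutive pair: tuple of records


def _expand_duality(kb, members: set[str]) -> set[str]:
    """A slot is satisfied by a labelled gene node or its protein node
    (and vice versa)."""
    out = set(members)
    for g in kb.genes.values():
        if g.entity_class == "protein" and g.coding_gene_id in members:
            out.add(g.id)
        if g.entity_class == "protein" and g.id in members and g.coding_gene_id:
            out.add(g.coding_gene_id)
    return out


def find_pathways(kb, pattern: NodeClassPattern, partition: GenePartition,
                  link_types: set[str] | None = None) -> list[PathwayMatch]:
    """Enumerate the complete set of chains satisfying the pattern.

    Disease–gene steps require an Association record; gene–gene steps an
    Interaction record (restricted to ``link_types`` when given).  Interior
    genes are pairwise distinct within a match.
    """
    # adjacency with evidence
    disease_genes: dict[str, dict[str, list]] = {}
    for a in kb.associations:
        disease_genes.setdefault(a.disease_id, {}).setdefault(a.gene_id, []).append(a)
    gene_partners: dict[str, dict[str, list]] = {}
    for link in kb.interactions:
        if link_types is not None and link.link_type not in link_types:
            continue
        gene_partners.setdefault(link.a_id, {}).setdefault(link.b_id, []).append(link)
        gene_partners.setdefault(link.b_id, {}).setdefault(link.a_id, []).append(link)
    gene_diseases: dict[str, dict[str, list]] = {}
    for a in kb.associations:
        gene_diseases.setdefault(a.gene_id, {}).setdefault(a.disease_id, []).append(a)

    slot_members: list[set[str] | None] = []
    for s in pattern.slots:
        if isinstance(s, GeneSlot):
            slot_members.append(_expand_duality(kb, partition.members(s.label)))
        else:
            slot_members.append(None)

    matches: list[PathwayMatch] = []
    n_slots = len(pattern.slots)

    def extend(idx: int, nodes: list[str], evidence: list[tuple]) -> None:
        if idx == n_slots:
            matches.append(PathwayMatch(nodes=tuple(nodes), evidence=tuple(evidence)))
            return
        slot = pattern.slots[idx]
        prev = nodes[-1]
        prev_slot = pattern.slots[idx - 1]
        if isinstance(slot, DiseaseSlot):
            # gene -> disease step
            nbrs = gene_diseases.get(prev, {})
            for d in sorted(slot.choices):
                if d in nbrs:
                    extend(idx + 1, nodes + [d], evidence + [tuple(nbrs[d])])
        else:
            members = slot_members[idx]
            if isinstance(prev_slot, DiseaseSlot):
                nbrs = disease_genes.get(prev, {})
            else:
                nbrs = gene_partners.get(prev, {})
            for g in sorted(nbrs):
                if g in members and g not in nodes:
                    extend(idx + 1, nodes + [g], evidence + [tuple(nbrs[g])])

    first = pattern.slots[0]
    for d in sorted(first.choices):
        if d in kb.diseases:
            extend(1, [d], [])
    matches.sort(key=lambda m: m.nodes)
    return matches


@dataclass
class MergedNetwork:
    """Node-and-link union over a set of pathway matches."""

    nodes: set[str] = field(default_factory=set)
    association_edges: set[tuple[str, str]] = field(default_factory=set)
    interaction_edges: set[tuple[str, str, str]] = field(default_factory=set)  # (a, b, type)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_links(self) -> int:
        return len(self.association_edges) + len(self.interaction_edges)

    @property
    def n_connected_pairs(self) -> int:
        pairs = {e for e in self.association_edges}
        pairs |= {(a, b) for a, b, _ in self.interaction_edges}
        return len(pairs)


def merge_pathways(matches: Iterable[PathwayMatch]) -> MergedNetwork:
    """Deduplicated union of all matches' nodes and supporting links.

    Invariant to the order of matches.
    """
    net = MergedNetwork()
    for m in matches:
        net.nodes.update(m.nodes)
        for records in m.evidence:
            for rec in records:
                if hasattr(rec, "link_type"):  # Interaction
                    a, b = rec.pair()
                    net.interaction_edges.add((a, b, rec.link_type))
                else:  # Association
                    key = (rec.disease_id, rec.gene_id)
                    net.association_edges.add(key)
    return net


def write_matches(matches: Iterable[PathwayMatch], path) -> None:
    """TSV export: one row per match, pipe-joined node ids."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("pathway\n")
        for m in matches:
            fh.write("|".join(m.nodes) + "\n")
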