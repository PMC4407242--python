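"""Permutation nulls: random disease pairs and degree-matched random networks.

Two empirical nulls underpin every significance call in the pipeline:

1. **Random disease pairs** — the relation indices (I, J, M) of an observed
   disease pair are compared against their distribution over uniformly drawn
   pairs of distinct *eligible* diseases (those associated with at least one
   gene; diseases with no gene are discarded).

2. **Degree-matched random networks** — the connectivity of an observed gene
   set is compared against random gene sets in which the i-th vertex is drawn
   from Q_i, the set of knowledge-base genes whose interaction degree equals
   the i-th template vertex's degree.  Links between sampled vertices are
   induced from the knowledge base.

Empirical p-values use the "same or larger" convention: p = #(null >= obs)/n,
so p can be exactly 0.  An add-one corrected variant ((k+1)/(n+1)) is
available behind ``tie_convention="add-one"``.

In exact-degree mode Q_i depends only on the template vertex's degree, so the
Q-sets of any two vertices are either identical or disjoint; sequential
sampling without replacement is then exactly uniform over all assignments of
distinct genes to vertices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .relation_indices import intersection_index, jaccard_index, meet_min_index

__all__ = [
    "NullDistribution",
    "DegreeMatchedSampler",
    "sample_random_disease_pairs",
    "empirical_pvalue",
    "relation_index_null",
    "build_q_sets",
    "sample_random_network",
    "connectivity_null",
    "induced_link_counts",
]


@dataclass
class NullDistribution:
    """Realized statistics of one permutation null."""

    statistic_name: str  # I | J | M | connectivity_pairs | connectivity_links
    values: list = field(default_factory=list)
    seed: int | None = None
    n_missing: int = 0  # missing-value replicates, excluded from values

    @property
    def n(self) -> int:
        return len(self.values)

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"# statistic={self.statistic_name} n={self.n} "
                     f"seed={self.seed} n_missing={self.n_missing}\n")
            fh.write("value\n")
            for v in self.values:
                fh.write(f"{v:.10g}\n" if isinstance(v, float) else f"{v}\n")


def empirical_pvalue(observed, null: NullDistribution | list,
                     tie_convention: str = "paper") -> float:
    """Proportion of null replicates with the same or larger statistic.

    ``tie_convention="paper"`` gives #(null >= obs)/n (p may be exactly 0);
    ``"add-one"`` gives (#(null >= obs)+1)/(n+1), never 0.
    """
    if observed is None:
        raise ValueError("observed statistic is missing")
    values = null.values if isinstance(null, NullDistribution) else list(null)
    n = len(values)
    if n == 0:
        raise ValueError("empty null distribution")
    k = sum(1 for v in values if v >= observed)
    if tie_convention == "paper":
        return k / n
    if tie_convention == "add-one":
        return (k + 1) / (n + 1)
    raise ValueError(f"unknown tie convention {tie_convention!r}")


# ----------------------------------------------------- random disease pairs


def sample_random_disease_pairs(kb, n: int, seed: int) -> list[tuple[str, str]]:
    """Draw ``n`` unordered pairs of distinct eligible diseases, uniformly.

    Eligibility requires at least one associated gene.  Reproducible from
    ``seed``; pairs are returned with ids in sorted order within each pair.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    eligible = kb.eligible_diseases()
    m = len(eligible)
    if m < 2:
        raise ValueError("need at least 2 eligible diseases")
    rng = np.random.default_rng(seed)
    ii = rng.integers(0, m, size=n)
    jj = rng.integers(0, m - 1, size=n)
    jj = jj + (jj >= ii)  # uniform over ordered distinct pairs
    out = []
    for i, j in zip(ii, jj):
        a, b = eligible[i], eligible[j]
        out.append((a, b) if a <= b else (b, a))
    return out


def relation_index_null(kb, n: int, seed: int,
                        include=None, exclude=None) -> dict[str, NullDistribution]:
    """Null distributions of I, J and M over ``n`` random disease pairs."""
    from .relation_indices import apply_curation

    pairs = sample_random_disease_pairs(kb, n, seed)
    gene_sets: dict[str, set] = {}

    def gset(d):
        if d not in gene_sets:
            gene_sets[d] = apply_curation(kb.genes_for(d), include, exclude)
        return gene_sets[d]

    nulls = {s: NullDistribution(statistic_name=s, seed=seed) for s in ("I", "J", "M")}
    for a, b in pairs:
        sa, sb = gset(a), gset(b)
        nulls["I"].values.append(intersection_index(sa, sb))
        j = jaccard_index(sa, sb)
        if j is None:
            nulls["J"].n_missing += 1
        else:
            nulls["J"].values.append(j)
        m = meet_min_index(sa, sb)
        if m is None:
            nulls["M"].n_missing += 1
        else:
            nulls["M"].values.append(m)
    return nulls


# ------------------------------------------------ degree-matched networks


@dataclass
class DegreeMatchedSampler:
    """Q-sets for one analysed template network.

    ``q_sets[i]`` lists the knowledge-base genes whose degree matches the
    degree of template vertex i (exact match, with nearest-degree fallback
    when the exact set is empty — fallback vertices are recorded).
    The template's own genes are not excluded from their Q-sets.
    """

    template: list[str]
    template_degrees: list[int]
    q_sets: list[list[str]]
    fallback_vertices: list[int] = field(default_factory=list)
    degree_mode: str = "partners"

    def validate_feasibility(self) -> None:
        """Distinctness must be satisfiable for every group of vertices
        sharing one candidate pool."""
        groups: dict[frozenset, int] = {}
        for q in self.q_sets:
            key = frozenset(q)
            groups[key] = groups.get(key, 0) + 1
        # Exact-mode Q-sets are equal or disjoint, so the per-group check
        # suffices; overlapping fallback sets are re-checked at sample time.
        for key, count in groups.items():
            if len(key) < count:
                raise ValueError(
                    f"distinctness unsatisfiable: {count} vertices share a "
                    f"candidate pool of size {len(key)}"
                )


def build_q_sets(kb, template_gene_ids, degree_mode: str = "partners") -> DegreeMatchedSampler:
    """Build the degree-matched candidate sets Q_i for a template gene set.

    Q_i holds every knowledge-base gene with exactly the degree of template
    vertex i.  If no gene matches (possible only under non-default degree
    modes), the nearest available degree is used instead, ties resolved
    toward the smaller degree, and the vertex is recorded as a fallback.
    """
    template = list(template_gene_ids)
    if not template:
        raise ValueError("empty template")
    for g in template:
        if g not in kb.genes:
            raise KeyError(f"template gene {g!r} not in knowledge base")

    by_degree: dict[int, list[str]] = {}
    for g_id in sorted(kb.genes):
        by_degree.setdefault(kb.degree(g_id, mode=degree_mode), []).append(g_id)
    available = sorted(by_degree)

    q_sets: list[list[str]] = []
    degrees: list[int] = []
    fallback: list[int] = []
    for i, g in enumerate(template):
        d = kb.degree(g, mode=degree_mode)
        degrees.append(d)
        if d in by_degree:
            q_sets.append(list(by_degree[d]))
        else:
            nearest = min(available, key=lambda x: (abs(x - d), x))
            q_sets.append(list(by_degree[nearest]))
            fallback.append(i)

    sampler = DegreeMatchedSampler(
        template=template, template_degrees=degrees, q_sets=q_sets,
        fallback_vertices=fallback, degree_mode=degree_mode,
    )
    sampler.validate_feasibility()
    return sampler


def induced_link_counts(kb, gene_ids) -> tuple[int, int]:
    """(connected pairs, link records) of the subnetwork induced by a gene set."""
    genes = set(gene_ids)
    pairs = 0
    links = 0
    pmap = kb._partner_map()
    counts = _pair_record_counts(kb)
    for a, b in combinations(sorted(genes), 2):
        if b in pmap.get(a, ()):  # connected
            pairs += 1
            links += counts[(a, b)]
    return pairs, links


def _pair_record_counts(kb) -> dict[tuple[str, str], int]:
    counts: dict[tuple[str, str], int] = {}
    for link in kb.interactions:
        key = link.pair()
        counts[key] = counts.get(key, 0) + 1
    return counts


def sample_random_network(sampler: DegreeMatchedSampler, kb, rng) -> tuple[list[str], int, int]:
    """One degree-matched random network replicate.

    Returns (sampled genes in template order, connected-pair count,
    link-record count).  Genes are distinct within a replicate; links are
    induced from the knowledge base.  ``rng`` is a numpy Generator (pass
    ``np.random.default_rng(seed)`` for reproducibility).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    for _attempt in range(100):
        chosen: list[str] = []
        taken: set[str] = set()
        ok = True
        for q in sampler.q_sets:
            candidates = [g for g in q if g not in taken]
            if not candidates:
                ok = False
                break
            pick = candidates[int(rng.integers(0, len(candidates)))]
            chosen.append(pick)
            taken.add(pick)
        if ok:
            pairs, links = induced_link_counts(kb, chosen)
            return chosen, pairs, links
    raise ValueError("distinctness unsatisfiable after 100 sampling attempts")


def connectivity_null(kb, template_gene_ids, n: int, seed: int,
                      statistic: str = "pairs",
                      degree_mode: str = "partners",
                      _collect_samples: bool = False) -> NullDistribution:
    """Null distribution of induced connectivity over ``n`` degree-matched
    random networks.

    ``statistic="pairs"`` (default) counts distinct connected pairs;
    ``"links"`` counts link records, so multi-typed edges count per type.
    """
    if n <= 0:
        raise ValueError("replicate count must be positive")
    if statistic not in ("pairs", "links"):
        raise ValueError(f"unknown connectivity statistic {statistic!r}")
    sampler = build_q_sets(kb, template_gene_ids, degree_mode=degree_mode)
    rng = np.random.default_rng(seed)
    null = NullDistribution(statistic_name=f"connectivity_{statistic}", seed=seed)
    samples = [] if _collect_samples else None
    for _ in range(n):
        genes, pairs, links = sample_random_network(sampler, kb, rng)
        null.values.append(pairs if statistic == "pairs" else links)
        if samples is not None:
            samples.append(genes)
    null.sampler = sampler  # type: ignore[attr-defined]
    if samples is not None:
        null.samples = samples  # type: ignore[attr-defined]
    return null
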