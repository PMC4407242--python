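"""Relation indices between the gene sets of two diseases.

Three set-overlap indices quantify how strongly diseases A and B share
associated genes:

* intersection index ``I_AB = |A ∩ B|``,
* Jaccard index ``J_AB = |A ∩ B| / |A ∪ B|``,
* Meet/Min index ``M_AB = |A ∩ B| / min(|A|, |B|)``.

Degenerate empty-set cases yield ``None`` (missing), never 0, so that
null-distribution machinery can exclude rather than silently deflate them.
Always ``0 <= J_AB <= M_AB <= 1`` on non-degenerate input.
"""

from __future__ import annotations

from collections.abc import Iterable, Set
from dataclasses import dataclass, field

__all__ = [
    "intersection_index",
    "jaccard_index",
    "meet_min_index",
    "RelationIndexReport",
    "compute_report",
    "apply_curation",
    "write_reports",
]


def intersection_index(a: Set, b: Set) -> int:
    """``|A ∩ B|``."""
    return len(set(a) & set(b))


def jaccard_index(a: Set, b: Set) -> float | None:
    """``|A ∩ B| / |A ∪ B|``; None when both sets are empty."""
    a, b = set(a), set(b)
    union = len(a | b)
    if union == 0:
        return None
    return len(a & b) / union


def meet_min_index(a: Set, b: Set) -> float | None:
    """``|A ∩ B| / min(|A|, |B|)``; None when either set is empty."""
    a, b = set(a), set(b)
    if not a or not b:
        return None
    return len(a & b) / min(len(a), len(b))


def apply_curation(
    genes: Set[str],
    include: Iterable[str] | None = None,
    exclude: Iterable[str] | None = None,
) -> set[str]:
    """Optional expert-curation filter on a gene set (defaults to a no-op).

    ``include``, when given, restricts the set to the listed genes;
    ``exclude`` removes the listed genes afterwards.
    """
    out = set(genes)
    if include is not None:
        out &= set(include)
    if exclude is not None:
        out -= set(exclude)
    return out


@dataclass
class RelationIndexReport:
    """I/J/M for one disease pair, optionally with empirical p-values."""

    disease_a: str
    disease_b: str
    size_a: int
    size_b: int
    i_ab: int
    j_ab: float | None
    m_ab: float | None
    shared_genes: set[str] = field(default_factory=set)
    p_i: float | None = None
    p_j: float | None = None
    p_m: float | None = None
    n_null: int | None = None
    seed: int | None = None


def compute_report(
    kb,
    disease_a: str,
    disease_b: str,
    include: Iterable[str] | None = None,
    exclude: Iterable[str] | None = None,
) -> RelationIndexReport:
    """Relation indices for one disease pair of a knowledge base.

    The optional curation include/exclude filter is applied to both gene sets
    before any index is computed.
    """
    a = apply_curation(kb.genes_for(disease_a), include, exclude)
    b = apply_curation(kb.genes_for(disease_b), include, exclude)
    shared = a & b
    return RelationIndexReport(
        disease_a=disease_a,
        disease_b=disease_b,
        size_a=len(a),
        size_b=len(b),
        i_ab=len(shared),
        j_ab=jaccard_index(a, b),
        m_ab=meet_min_index(a, b),
        shared_genes=shared,
    )


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return format(x, ".6g")
    return str(x)


def write_reports(reports: Iterable[RelationIndexReport], path) -> None:
    """TSV writer: one row per disease pair."""
    cols = [
        "disease_a", "disease_b", "size_a", "size_b",
        "I", "J", "M", "p_I", "p_J", "p_M", "n_null", "seed",
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in reports:
            row = [
                r.disease_a, r.disease_b, str(r.size_a), str(r.size_b),
                str(r.i_ab), _fmt(r.j_ab), _fmt(r.m_ab),
                _fmt(r.p_i), _fmt(r.p_j), _fmt(r.p_m),
                _fmt(r.n_null), _fmt(r.seed),
            ]
            fh.write("\t".join(row) + "\n")
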