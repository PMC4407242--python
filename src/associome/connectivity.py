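"""Comorbid gene sets, induced subnetworks and connectivity significance.

The comorbid gene set of a disease combination is the intersection of the
diseases' associated-gene sets.  Its connectivity — how many of its gene
pairs are directly linked in the knowledge base — is scored against the
degree-matched random-network null; the same procedure applies to disease
pairs and to higher-order combinations (e.g. the set shared by all four
analysed diseases).
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass, field

from .null_models import connectivity_null, empirical_pvalue, induced_link_counts

__all__ = [
    "ConnectivityReport",
    "comorbid_gene_set",
    "induced_subnetwork",
    "connectivity_report",
    "write_connectivity_reports",
]


def comorbid_gene_set(kb, disease_ids: Iterable[str]) -> set[str]:
    """Genes associated concurrently with every listed disease.

    Anti-monotone in the number of diseases: adding a disease can only
    shrink the set.
    """
    ids = list(disease_ids)
    if not ids:
        raise ValueError("need at least one disease")
    result: set[str] | None = None
    for d in ids:
        genes = kb.genes_for(d)  # raises KeyError on unknown disease
        result = genes if result is None else (result & genes)
        if not result:
            return set()
    return result


def induced_subnetwork(kb, gene_ids: Iterable[str]):
    """All knowledge-base interactions with both endpoints in ``gene_ids``.

    Returns (link records, connected-pair count, link-record count).
    """
    genes = set(gene_ids)
    for g in genes:
        if g not in kb.genes:
            raise KeyError(f"unknown gene id {g!r}")
    links = [l for l in kb.interactions if l.a_id in genes and l.b_id in genes]
    pairs = len({l.pair() for l in links})
    return links, pairs, len(links)


@dataclass
class ConnectivityReport:
    """Observed connectivity of one disease combination plus its null p-value."""

    disease_ids: tuple[str, ...]
    comorbid_genes: set[str] = field(default_factory=set)
    n_genes: int = 0
    n_connected_pairs: int = 0
    n_links: int = 0
    p_value: float | None = None
    n_null: int | None = None
    seed: int | None = None
    statistic: str = "pairs"


def connectivity_report(kb, disease_ids: Iterable[str], n_null: int, seed: int,
                        statistic: str = "pairs",
                        tie_convention: str = "paper",
                        degree_mode: str = "partners") -> ConnectivityReport:
    """Score the comorbid gene set of a disease combination against the
    degree-matched null.

    The observed statistic is the connectivity (connected pairs by default)
    of the subnetwork induced by the comorbid set; p is the proportion of
    ``n_null`` degree-matched random networks with the same or greater
    connectivity.
    """
    ids = tuple(disease_ids)
    genes = comorbid_gene_set(kb, ids)
    report = ConnectivityReport(disease_ids=ids, comorbid_genes=genes,
                                n_genes=len(genes), statistic=statistic)
    if genes:
        report.n_connected_pairs, report.n_links = induced_link_counts(kb, genes)
    if len(genes) >= 2:
        null = connectivity_null(kb, sorted(genes), n=n_null, seed=seed,
                                 statistic=statistic, degree_mode=degree_mode)
        observed = report.n_connected_pairs if statistic == "pairs" else report.n_links
        report.p_value = empirical_pvalue(observed, null, tie_convention)
        report.n_null = null.n
        report.seed = seed
    return report


def write_connectivity_reports(reports: Iterable[ConnectivityReport], path) -> None:
    cols = ["diseases", "n_genes", "n_connected_pairs", "n_links",
            "statistic", "p_value", "n_null", "seed", "genes"]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in reports:
            fh.write("\t".join([
                "|".join(r.disease_ids),
                str(r.n_genes), str(r.n_connected_pairs), str(r.n_links),
                r.statistic,
                "NA" if r.p_value is None else format(r.p_value, ".6g"),
                "NA" if r.n_null is None else str(r.n_null),
                "NA" if r.seed is None else str(r.seed),
                "|".join(sorted(r.comorbid_genes)),
            ]) + "\n")
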