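"""End-to-end analysis orchestration.

`run_full_analysis` chains the pipeline stages — relation indices with their
disease-pair null, connectivity with the degree-matched null (per pair and
for the all-disease intersection), enrichment with CR re-ranking, and pathway
pattern matching — into one deterministic report bundle with a run manifest.
Every stage is also usable standalone through the library (or the CLI
subcommands).

All randomness derives from the mandatory config seed; running the same
config twice yields byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .connectivity import connectivity_report, write_connectivity_reports
from .enrichment import (
    attach_connectivity_rates,
    hypergeometric_enrichment,
    load_annotation,
    propagate_with_ontology,
    rank_by_cr,
    write_enrichment,
)
from .knowledge_base import load_knowledge_base, write_graphml, write_sif
from .null_models import empirical_pvalue, relation_index_null
from .pathway_discovery import (
    DiseaseSlot,
    GeneSlot,
    NodeClassPattern,
    build_gene_partition,
    find_pathways,
    merge_pathways,
    write_matches,
)
from .relation_indices import compute_report, write_reports

__all__ = [
    "AnalysisConfig",
    "ValidationReport",
    "StageError",
    "validate_config",
    "run_full_analysis",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage label."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    """Everything one analysis run needs; the seed is mandatory."""

    assoc_path: str
    interaction_path: str
    focal_disease: str
    partner_diseases: list[str]
    seed: int
    nodes_path: str | None = None
    annotation_path: str | None = None
    obo_path: str | None = None
    n_disease_pairs: int = 10_000
    n_networks: int = 1_000
    tie_convention: str = "paper"      # "paper" | "add-one"
    connectivity_stat: str = "pairs"   # "pairs" | "links"
    degree_mode: str = "partners"      # "partners" | "records"
    protein_level: bool = False
    curation_include: list[str] | None = None
    curation_exclude: list[str] | None = None
    pattern: list[dict] | None = None  # slot dicts; default 5-slot pattern

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if raw is None or "seed" not in raw:
            raise StageError("validate", "config must set an explicit seed")
        return cls(**raw)

    def default_pattern(self) -> NodeClassPattern:
        return NodeClassPattern(slots=[
            DiseaseSlot.of(self.focal_disease),
            GeneSlot(label=f"specific:{self.focal_disease}"),
            GeneSlot(label="comorbid"),
            GeneSlot(label="__partner_specific__"),
            DiseaseSlot.of(*self.partner_diseases),
        ])

    def build_pattern(self) -> NodeClassPattern:
        if self.pattern is None:
            return self.default_pattern()
        slots: list = []
        for entry in self.pattern:
            if "diseases" in entry:
                slots.append(DiseaseSlot.of(*entry["diseases"]))
            elif "label" in entry:
                slots.append(GeneSlot(label=entry["label"]))
            else:
                raise StageError("validate", f"bad pattern slot {entry!r}")
        return NodeClassPattern(slots=slots)


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_config(config: AnalysisConfig, kb=None) -> ValidationReport:
    """Check config invariants; distinguish errors from warnings."""
    report = ValidationReport()
    if config.seed is None:
        report.errors.append("seed is mandatory")
    for label, path in (("associations", config.assoc_path),
                        ("interactions", config.interaction_path)):
        if path is not None and not os.path.exists(path):
            report.errors.append(f"{label} file not found: {path}")
    if config.n_disease_pairs <= 0 or config.n_networks <= 0:
        report.errors.append("replicate counts must be positive")
    if config.tie_convention not in ("paper", "add-one"):
        report.errors.append(f"unknown tie convention {config.tie_convention!r}")
    if config.connectivity_stat not in ("pairs", "links"):
        report.errors.append(f"unknown connectivity statistic {config.connectivity_stat!r}")
    if not config.partner_diseases:
        report.errors.append("at least one partner disease required")
    if kb is not None and report.ok:
        for d in [config.focal_disease] + list(config.partner_diseases):
            if d not in kb.diseases:
                report.errors.append(f"disease {d!r} absent from the knowledge base")
        if report.ok and config.pattern is not None:
            valid_labels = {"comorbid", "__partner_specific__"} | {
                f"specific:{d}"
                for d in [config.focal_disease] + list(config.partner_diseases)
            }
            for entry in config.pattern:
                label = entry.get("label")
                if label is not None and label not in valid_labels:
                    report.errors.append(f"pattern references undefined partition label {label!r}")
    return report


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full_analysis(config: AnalysisConfig, out_dir) -> dict:
    """Run every stage and write the report bundle into ``out_dir``.

    Returns the manifest dict.  On any stage failure, partial outputs are
    removed and a stage-labelled StageError is raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []

    def target(name: str) -> Path:
        p = out / name
        created.append(p)
        return p

    manifest: dict = {
        "tool": "associome",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "focal_disease": config.focal_disease,
            "partner_diseases": list(config.partner_diseases),
            "n_disease_pairs": config.n_disease_pairs,
            "n_networks": config.n_networks,
            "tie_convention": config.tie_convention,
            "connectivity_stat": config.connectivity_stat,
            "degree_mode": config.degree_mode,
            "protein_level": config.protein_level,
        },
        "inputs": {},
        "warnings": [],
    }

    try:
        # ------------------------------------------------------------ load
        report = validate_config(config)
        if not report.ok:
            raise StageError("validate", "; ".join(report.errors))
        kb = load_knowledge_base(config.assoc_path, config.interaction_path,
                                 config.nodes_path)
        manifest["inputs"]["associations"] = _sha256(config.assoc_path)
        manifest["inputs"]["interactions"] = _sha256(config.interaction_path)
        if config.nodes_path:
            manifest["inputs"]["nodes"] = _sha256(config.nodes_path)
        manifest["warnings"].extend(kb.warnings)
        report = validate_config(config, kb)
        if not report.ok:
            raise StageError("validate", "; ".join(report.errors))
        if config.protein_level:
            from .knowledge_base import collapse_to_protein_network

            kb = collapse_to_protein_network(kb)
            manifest["warnings"].extend(kb.warnings)

        include, exclude = config.curation_include, config.curation_exclude
        diseases = [config.focal_disease] + list(config.partner_diseases)

        # --------------------------------------------------------- indices
        try:
            nulls = relation_index_null(kb, config.n_disease_pairs, config.seed,
                                        include, exclude)
            pair_reports = []
            for partner in config.partner_diseases:
                r = compute_report(kb, config.focal_disease, partner, include, exclude)
                r.p_i = empirical_pvalue(r.i_ab, nulls["I"], config.tie_convention)
                r.p_j = (None if r.j_ab is None
                         else empirical_pvalue(r.j_ab, nulls["J"], config.tie_convention))
                r.p_m = (None if r.m_ab is None
                         else empirical_pvalue(r.m_ab, nulls["M"], config.tie_convention))
                r.n_null = config.n_disease_pairs
                r.seed = config.seed
                pair_reports.append(r)
            write_reports(pair_reports, target("indices.tsv"))
            for name, null in nulls.items():
                null.write_tsv(target(f"null_index_{name}.tsv"))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("indices", str(exc)) from exc

        # ---------------------------------------------------- connectivity
        try:
            combos = [[config.focal_disease, p] for p in config.partner_diseases]
            combos.append(diseases)
            conn_reports = [
                connectivity_report(
                    kb, combo, n_null=config.n_networks,
                    seed=config.seed + i + 1,
                    statistic=config.connectivity_stat,
                    tie_convention=config.tie_convention,
                    degree_mode=config.degree_mode,
                )
                for i, combo in enumerate(combos)
            ]
            write_connectivity_reports(conn_reports, target("connectivity.tsv"))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("connectivity", str(exc)) from exc

        # ------------------------------------------------------ enrichment
        comorbid_all = conn_reports[-1].comorbid_genes
        enrichment_records = []
        if config.annotation_path:
            try:
                annotation = load_annotation(config.annotation_path,
                                             universe=set(kb.genes))
                manifest["inputs"]["annotation"] = _sha256(config.annotation_path)
                if config.obo_path:
                    annotation = propagate_with_ontology(annotation, config.obo_path)
                    manifest["inputs"]["ontology"] = _sha256(config.obo_path)
                if comorbid_all:
                    enrichment_records = hypergeometric_enrichment(comorbid_all, annotation)
                    attach_connectivity_rates(enrichment_records, kb)
                    enrichment_records = rank_by_cr(enrichment_records)
                else:
                    manifest["warnings"].append(
                        "empty all-disease comorbid set; enrichment skipped"
                    )
                write_enrichment(enrichment_records, target("enrichment.tsv"))
            except StageError:
                raise
            except Exception as exc:
                raise StageError("enrich", str(exc)) from exc

        # -------------------------------------------------------- pathways
        try:
            partition = build_gene_partition(kb, config.focal_disease,
                                             config.partner_diseases)
            partner_specific = set()
            for d in config.partner_diseases:
                partner_specific |= partition.labels[f"specific:{d}"]
            partition.labels["__partner_specific__"] = partner_specific
            pattern = config.build_pattern()
            matches = find_pathways(kb, pattern, partition)
            merged = merge_pathways(matches)
            write_matches(matches, target("pathways.tsv"))
            merged_ids = {n for n in merged.nodes if n in kb.genes}
            write_graphml(kb, target("pathway_network.graphml"), merged_ids)
            write_sif(kb, target("pathway_network.sif"), merged_ids)
            manifest["pathways"] = {
                "n_matches": len(matches),
                "merged_nodes": merged.n_nodes,
                "merged_links": merged.n_links,
                "merged_connected_pairs": merged.n_connected_pairs,
            }
        except StageError:
            raise
        except Exception as exc:
            raise StageError("pathways", str(exc)) from exc

        # -------------------------------------------------------- manifest
        manifest["indices"] = [
            {
                "pair": [r.disease_a, r.disease_b],
                "I": r.i_ab, "J": r.j_ab, "M": r.m_ab,
                "p_I": r.p_i, "p_J": r.p_j, "p_M": r.p_m,
            }
            for r in pair_reports
        ]
        manifest["connectivity"] = [
            {
                "diseases": list(r.disease_ids),
                "n_genes": r.n_genes,
                "n_connected_pairs": r.n_connected_pairs,
                "n_links": r.n_links,
                "p": r.p_value,
            }
            for r in conn_reports
        ]
        manifest_path = target("manifest.json")
        with open(manifest_path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest
    except Exception:
        for p in created:
            if p.exists():
                p.unlink()
        raise
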