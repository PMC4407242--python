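"""Which processes are overrepresented among comorbid genes — and which of
those are tightly wired?

Runs exact hypergeometric enrichment with BH FDR over a synthetic annotation,
then re-ranks the enriched terms by their connectivity rate (CR): the
fraction of each term's gene pairs that are directly linked in the analysed
network.  High CR promotes small, specific, tightly interacting processes
over broad generic ones.
"""

from associome import (
    PlantedPair,
    PlantedTerm,
    SyntheticConfig,
    comorbid_gene_set,
    generate_annotation,
    generate_kb,
    hypergeometric_enrichment,
    rank_by_cr,
)
from associome.enrichment import attach_connectivity_rates

cfg = SyntheticConfig(
    n_diseases=30, n_genes=600, seed=5,
    planted_pairs=[PlantedPair("D001", "D002", 14, 0.6)],
    comorbid_pool_size=16,
    planted_terms=[PlantedTerm("PT_real_process", 12, 0.7)],
    n_background_terms=30,
)
kb, truth = generate_kb(cfg)
annotation, truth = generate_annotation(cfg, kb, truth)

study = comorbid_gene_set(kb, ["D001", "D002"])
records = hypergeometric_enrichment(study, annotation)
attach_connectivity_rates(records, kb)
ranked = rank_by_cr(records)

print(f"study set: {len(study)} genes shared by D001 and D002")
print(f"{len(ranked)} terms with at least one study gene\n")
print(f"{'term':>18} {'k':>3} {'K':>4} {'p':>9} {'q':>9} {'CR':>6}")
for r in ranked[:5]:
    cr = "  --" if r.cr is None else f"{r.cr:.2f}"
    print(f"{r.term_id:>18} {r.k:>3} {r.K:>4} {r.p_value:>9.2e} "
          f"{r.q_value:>9.2e} {cr:>6}")
print("\nCR = connected gene pairs / all possible pairs within the term's")
print("study genes.  The CR ranking puts tightly wired groups on top; among")
print("them the planted process stands out with a q-value orders of")
print("magnitude below the incidental small background terms.")
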