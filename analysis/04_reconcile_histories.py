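#!/usr/bin/env python
"""Reconcile the worked-example gene trees onto their species cladograms.

Three scenarios: the sedentarian annelids (nested duplications plus a
clitellate loss), the gastropods (hypsogastropod loss + re-duplication),
and the spiralian-wide cladogram with per-lineage duplications and a
single-copy root.  Writes per-branch event maps under results/.
"""

from klfsp.examples import (
    gastropod_gene_tree,
    gastropod_species_tree,
    sedentaria_gene_tree,
    sedentaria_species_tree,
    spiralia_gene_tree,
    spiralia_species_tree,
)
from klfsp.pipeline import render_report
from klfsp.reconcile import (
    ancestral_counts_from_event_map,
    event_map_from_reconciliation,
    lca_reconcile,
)

scenarios = {
    "sedentaria": (sedentaria_gene_tree(), sedentaria_species_tree()),
    "gastropoda": (gastropod_gene_tree(), gastropod_species_tree()),
    "spiralia": (spiralia_gene_tree(), spiralia_species_tree()),
}

for name, (gt, sp) in scenarios.items():
    rec = lca_reconcile(gt, sp)
    emap = event_map_from_reconciliation(rec)
    with open(f"results/reconciliation_{name}.tsv", "w") as fh:
        fh.write(render_report(emap, format="tsv"))
    print(f"{name}: {rec.duplication_count} duplication(s), {rec.loss_count} loss(es)")
    for bid in sorted(emap.branches):
        ev = emap.branches[bid]
        if ev.duplications or ev.losses:
            print(f"  {bid}: {ev.duplications} dup, {ev.losses} loss")

# the reconciled spiralian ancestor carries a single copy
emap = event_map_from_reconciliation(
    lca_reconcile(spiralia_gene_tree(), spiralia_species_tree())
)
root_copies = ancestral_counts_from_event_map(emap)["Spiralia"]
print(f"spiralia root copy number after root-branch events: {root_copies}")
assert root_copies == 1
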