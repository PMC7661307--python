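# klfsp — comparative genomics of KLF/SP zinc-finger gene families

`klfsp` is a toolkit for reconstructing the duplication–loss history of the
KLF/SP family of C2H2 zinc-finger transcription factors (and gene families
with a similar structure) across a species phylogeny, with particular
attention to the spiralian SP6-9 group, where tandem intronless paralogs in
cephalopods point to duplication via retrotransposition.

It is aimed at molecular evolution researchers who have protein sequences,
externally inferred gene trees, and genome annotations, and want to go from
those to a per-branch map of gene duplications and losses.

## What it computes

**Candidate screening.** A protein qualifies as a KLF/SP family member when
it contains the triple-C2H2 spacer architecture

```
C-X4-C-X12-H-X3-H -x7- C-X4-C-X12-H-X3-H -x7- C-X2-C-X12-H-X3-H
```

(X = any residue; the literal pattern spans 81 positions) with a conserved
aspartate at position 44 of the matched window (D44). A Buttonhead (Btd)
box N-terminal to the zinc fingers distinguishes SP members from KLFs.
Candidate sequences can be truncated and concatenated over their conserved
motifs (SID, R2, R3, SP-box, Btd, C2H2) to build alignment blocks for
external tree inference (MUSCLE/RAxML/MrBayes are consumed, not invoked).

**Tree support.** Non-trivial bipartitions, split-frequency tables, and the
average standard deviation of split frequencies (ASDSF) between two MCMC
runs: for each split at frequency ≥ 0.10 in at least one run,
sd = |f₁ − f₂|/√2, averaged over splits. Posterior supports are categorised
with strict thresholds: above 0.5 (white), 0.7 (grey), 0.95 (black).

**Reconciliation.** LCA mapping of rooted binary gene trees onto a species
tree: node *v* is a duplication iff it maps to the same species node as one
of its children; losses are read off the depth gaps along gene-tree edges
and attributed to specific branches. The resulting cost
(duplications + losses) is minimal, which the test suite verifies against
an exhaustive oracle. Ancestral copy numbers are inferred independently by
Sankoff parsimony over integer states with per-copy gain/loss costs;
missing leaves are cost-free. Because raw count parsimony can contradict
gene-tree signal, override directives replace count-based events inside a
named clade with gene-tree-derived events, provenance-tagged.

**Retroduplication.** From GFF3 gene models: intron counts, tandem clusters
within a 1.5 Mb window, flip-invariant gene order/orientation signatures,
intronless-retrocopy classification (an intronless gene with an
intron-bearing family member in the same species), and placement of
retroduplication events on the species tree via the reconciliation.

**Simulation.** A birth–death simulator generates ground-truth families
along a species tree (duplication rate λ, loss rate μ, retroduplication
fraction ρ), together with protein FASTA carrying the screening
architecture, GFF3 with tandem/intronless geometry, and truth tables, so
the whole pipeline is testable end to end without downloads.

## Worked example

The sedentarian-annelid scenario: six lineages
`(Orb,(Sab,(Serp,(Clit,(Cap,Ech)))))` and a gene tree in which two
clitellate paralogs group with single Serpulidae/Capitellidae/Echiura
orthologues while a second clade holds two paralogs of each of those
lineages and one of Clitellata:

```python
from klfsp.examples import sedentaria_gene_tree, sedentaria_species_tree
from klfsp.reconcile import lca_reconcile

rec = lca_reconcile(sedentaria_gene_tree(), sedentaria_species_tree())
print(rec.duplications["Cap+Clit+Ech+Serp"])  # 2
print(rec.duplications["Clit"], rec.losses["Clit"])  # 1 1
print(rec.duplication_count, rec.loss_count)  # 3 1
```

Two duplications on the branch to the Serpulidae/Clitellata/Capitellidae/
Echiura ancestor, then one loss and one further duplication on the
Clitellata branch — the most parsimonious history for that topology
(cost 4, confirmed by the brute-force oracle).

The `analysis/` directory walks the full story as numbered scripts:
simulate a family (01), screen its proteome (02), convergence diagnostics
(03), reconcile the annelid/gastropod/spiralian examples (04), infer
cephalopod retroduplications from synteny and intron structure (05), and
render the final per-branch star/X event report with the hypsogastropod
override applied (06). Each writes its tables under `results/`.

A `klfsp` console script exposes the same stages
(`screen`, `asdsf`, `reconcile`, `ancestral`, `combine`, `synteny`,
`simulate`, `report`, `run`); `klfsp run --config cfg.yaml` executes the
pipeline end to end and writes a manifest.

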