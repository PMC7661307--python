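# Methods

## Candidate screening

Family membership is architecture-based. The screening pattern is a list
of fixed residues (C or H) and exact integer spacers; the default encodes
the triple-C2H2 layout C-X4-C-X12-H-X3-H-X7-C-X4-C-X12-H-X3-H-X7-C-X2-C-
X12-H-X3-H, whose literal realization spans 81 positions, with finger
spans (0,23), (30,53), (60,81) within a window. Descriptions of this
architecture sometimes quote a total of 88 residues; since the literal
spacer string sums to 81 and no alternative spacer assignment is uniquely
implied, the implementation follows the literal pattern and exposes all
eleven spacer lengths plus the aspartate position through
`ArchitecturePattern.from_spacers` / the YAML `architecture:` block, so an
88-position reading can be configured without code changes.

Conventions that matter:

* The aspartate check (default `d_position` 44, 1-based within the matched
  window) is interpreted in window coordinates because no other coordinate
  frame is defined for it. Position 44 falls in a spacer of the second
  finger, so the check is independent of the fixed residues.
* The ambiguity character X in *input* sequences matches spacer positions
  only, never a fixed C/H and never the D44 aspartate — conservative
  candidate calling: an ambiguous residue is not evidence of a match.
* All matching windows are reported, including overlapping ones;
  downstream consumers (classification, concat blocks) take the leftmost.
  Scanning is plain O(n·m) over fixed offsets; the test suite checks exact
  equivalence against an independently written naive matcher.
* SP-vs-KLF calls: non-member without a D44-qualifying hit; SP when a Btd
  annotation ends strictly before the first qualifying hit's start; KLF
  otherwise. SP therefore implies a Btd annotation.

The short motif definitions (SID, PVDLS, R2, R3, SP-box, Btd, 9aaTAD) are
config-supplied regular expressions. The shipped defaults are
**non-canonical placeholders** — plausible literals used by the simulator
and tests (e.g. Btd `C.CP.C`, PVDLS `PVDLS`) — because curated consensus
strings vary between studies; real screens should override them via the
`motifs:` config block.

Concatenated motif blocks join the subsequences of present motifs in a
configured order (default SID, R2, R3, SP-box, Btd, C2H2, where C2H2 is
the leftmost architecture window); absent motifs are listed, not
gap-padded, and duplicate annotations of one motif use the leftmost with a
warning.

## Split frequencies and ASDSF

Bipartitions are extracted treating trees as unrooted; trivial splits
(one leaf on either side) are excluded, and each split is canonicalised as
the side not containing the lexicographically smallest leaf. The ASDSF
between two runs averages |f₁ − f₂|/√2 (two-sample standard deviation,
divisor n−1) over splits whose frequency reaches `min_freq` in at least
one run. `min_freq` defaults to 0.10, the common Bayesian-MCMC practice;
both the convention and the threshold are configurable. An empty
qualifying set returns 0 with a warning — the statistic is undefined
there, and 0 is the conservative "no disagreement observed" reading.
Support categories use strict inequalities (above 0.5 / 0.7 / 0.95), so a
posterior of exactly 0.95 is grey, not black.

## Duplication–loss reconciliation

`lca_reconcile` implements the classical LCA mapping for rooted binary
trees: leaves map to their species, internal nodes to the LCA of their
children's images; a node is a duplication iff it shares its image with a
child. Losses are attributed per branch by walking each gene edge
u→v through the species tree: at every species node where the lineage is
present but only the child toward M(v) retains it, the off-path child
branch records one loss; a duplication at u places the lineage at M(u)
itself, a speciation consumes the split at M(u). Events above the species
root are not charged (standard convention). Optimality (cost = minimum
duplications + losses) is not assumed: the suite and the acceptance sweep
compare against `brute_force_reconcile`, an exhaustive enumeration over
all valid mappings, on hundreds of random instances.

Polytomies in species trees are rejected rather than auto-resolved: the
choice of resolution changes event counts, so it belongs to the user.
Branches are identified by the node below them — leaf label, internal
label when the newick provides one, otherwise the sorted descendant leaf
labels joined with `+`.

## Copy-number parsimony and the evidence combiner

`ancestral_copy_number` is a Sankoff dynamic program over integer states
0..`max_copies` (default 8) with per-copy step costs (`gain_cost`,
`loss_cost`, both default 1). Missing leaves score zero in every state:
absence from a transcriptome is not evidence of gene loss. Ties at the
root are all reported; the canonical single assignment takes the smallest
state at every tie, a determinism rule that asserts no biology.

Count parsimony and gene-tree reconciliation are deliberately separate
inference routes. They can disagree: on the spiralian example, six
two-copy lineages against three one-copy lineages make a two-copy root
cheaper (cost 3) than the single-copy root (cost 4) that per-lineage
duplication clades in the gene trees support; and a loss followed by a
re-duplication leaves the observed count unchanged, invisible to counts
alone (the hypsogastropod case). The combiner therefore starts from the
count-based event map and replaces events inside explicitly named clades
with gene-tree-derived events (an `OverrideDirective`, or the supplied
reconciliation maps), tagging those branches `override`. Overlapping
override clades are an error listing the conflicting branches; disjoint
directives commute, and the operation is idempotent.

## Gene architecture and retroduplication

Coordinates are 0-based half-open internally; GFF3's 1-based inclusive
convention is converted at the I/O boundary (gffutils for reading).
Intron count is exons − 1. Tandem clustering is greedy left-to-right per
scaffold under a complete-linkage diameter criterion on gene *start*
coordinates (window default 1.5 Mb): "within W of each other" is read as
pairwise, and start-to-start distance is chosen over span gaps (both the
metric and window are configurable). Strand agreement is reported per
cluster, not required — same-direction order is treated as evidence, not
a filter. Order signatures canonicalise a cluster's (family label,
orientation) sequence to the lexicographic minimum of the forward reading
and its flip (reverse order, inverted orientations), making equality
invariant to which strand a scaffold was assembled on.

Retrocopy calls use intron presence as the only signal (no poly-A or
target-site-duplication detection): intronless with an intron-bearing
family member in the same species → candidate; intron-bearing →
parental-like; all-intronless family → ambiguous, because without a
parental lineage the direction of copying is unidentifiable.
Retroduplication events are emitted for each maximal gene-tree clade of
candidates whose sister contains a parental-like gene, at the clade's
parent node — which must be labelled a duplication by the reconciliation —
on the species branch that node maps to. The event count is therefore
bounded by the reconciliation's duplication count.

## Simulator

One root copy evolves along the species tree; each copy independently
duplicates at rate λ and dies at rate μ per unit branch length
(exponential waiting times), and a duplication is flagged retro with
probability ρ. Intron structure is inherited except through retro events,
whose products (and their descendants) are intronless. Every event is
logged as (branch, time, type, parent copy, child copy); the true gene
tree is the pruned tree of surviving copies with unary nodes suppressed.
Two identities are enforced by tests: replaying the log reproduces the
leaf copy counts (count(s) = 1 + Σ dups − losses over the root path), and
with μ = 0 the LCA reconciliation of the true gene tree recovers the true
per-branch duplication map exactly.

Emission is deliberately stylised. Proteins are a fixed template (optional
Btd segment, linker, architecture window with D at the checked position);
point mutations hit spacer positions only, holding D44, because the goal
is to exercise spacing logic rather than model substitution — an optional
uniform-over-all-sites mode and D44/Btd ablation flags provide negative
controls. Gene models place a species' copies in tandem on one scaffold at
`cluster_spacing` (default 0.5 Mb), same strand, with `intron_count`
introns (default 4, exons 150 bp, introns 200 bp) unless retro-derived.
Species trees must carry branch lengths (event counts scale with them)
even though the analysis cladograms are lengthless. A live-copy cap
(`max_copies`, default 8 per species) aborts runaway birth processes with
guidance rather than looping.

What passing on simulated data does *not* show: real proteomes have
divergent motifs, fragmentary ORFs and alignment error; real gene trees
have topological error the reconciliation inherits; real annotations can
mis-split genes, which moves intron counts. The simulator emulates the
statistical *structure* the inference assumes (architecture presence,
tandem geometry, intronless retro copies, birth–death counts), not those
noise processes.

## Fixtures and problem sizes

The worked-example trees in `klfsp.examples` are synthetic
reconstructions of verbally described duplication/loss scenarios
(sedentarian annelids, gastropods, cephalopods, a spiralian cladogram);
they are the unique simple topologies consistent with those descriptions
and are labelled as reconstructions, not published tree files. The
spiralian cladogram adopts one current consensus resolution
(Rotifera basal to (Gastrotricha+Platyhelminthes) + lophotrochozoans);
alternative resolutions would move branch identities but not the
single-copy root conclusion for lineage-monophyletic gene trees.

Randomised verification uses instances small enough for the exhaustive
oracles to stay exact and fast: 500 reconciliations on 2–5 species /
2–6 genes, 200 Sankoff problems on 2–8 species with states ≤ 4, and 1000
scanner sequences of 30–300 residues, a third with planted windows. These
sizes make the oracle sweeps complete in well under a minute each while
covering the combinatorial space densely for trees this small.

## Known limitations

* Reconciliation assumes the gene tree is correct and rooted; no
  error-aware rearrangement, no transfer events, no probabilistic model.
* The screening pattern requires exact spacer lengths; genuinely variable
  spacers need a profile method (out of scope here).
* ASDSF values from published analyses are not reproducible without the
  original MCMC samples; the module reproduces the statistic, not those
  runs.
* Greedy-leftmost clustering is one deterministic choice among optimal
  diameter partitions; boundary genes at exactly the window edge can
  cluster differently under other tie-breaks.
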