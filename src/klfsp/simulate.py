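"""Ground-truth gene-family simulator.

Gene families evolve along a species tree by a per-copy linear birth-death
process: each extant copy duplicates at rate ``duplication_rate`` and is
lost at rate ``loss_rate`` per unit branch length; a duplication is a
retroduplication with probability ``retro_fraction``, producing an
intronless copy (intron structure is otherwise inherited).  The simulator
records every event in an :class:`EventLog`, builds the true gene tree of
surviving copies, and can emit protein FASTA with the triple-C2H2
architecture, GFF3 gene models with tandem placement, and the truth tables
(copy-number matrix and per-branch event map) the inference modules try to
recover.

Sequence emission is intentionally minimal: point mutations hit spacer
positions of the zinc-finger window only (the conserved aspartate is held
fixed), because the goal is to exercise the scanner's spacing logic, not
to model realistic substitution.  An optional uniform model over all
window positions exists for negative tests, and ablation flags can break
the D44 check or delete the Btd box.

Species trees need branch lengths here even though the downstream analysis
cladograms are lengthless: event counts scale with branch length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .motifs import AMINO_ACIDS, ArchitecturePattern
from .reconcile import (
    BranchEvents,
    EventMap,
    SpeciesTreeIndex,
    branch_id,
)

__all__ = [
    "SimulationConfig",
    "Event",
    "SimulatedGene",
    "SimulatedFamily",
    "ProteinTemplate",
    "simulate_family",
    "emit_proteins",
    "emit_annotations",
    "truth_tables",
    "replay_counts",
    "write_outputs",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Rates and geometry of the simulated family.

    Rates are per copy per unit branch length; ``retro_fraction`` is the
    probability that a duplication proceeds through an mRNA intermediate.
    """

    duplication_rate: float = 0.0
    loss_rate: float = 0.0
    retro_fraction: float = 0.0
    max_copies: int = 8
    intron_count: int = 4
    cluster_spacing: int = 500_000
    mutation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duplication_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.retro_fraction <= 1.0:
            raise ValueError("retro_fraction must be in [0, 1]")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")


@dataclass(frozen=True)
class Event:
    branch: str           # species-tree branch_id on which the event fell
    time: float           # time from the top of that branch
    type: str             # "duplication" | "retroduplication" | "loss"
    parent_copy: str
    child_copy: str | None


@dataclass(frozen=True)
class SimulatedGene:
    gene_id: str
    species: str
    retro: bool  # intronless (retro-derived) copy


class _Lineage:
    __slots__ = ("copy_id", "intronless")

    def __init__(self, copy_id: str, intronless: bool):
        self.copy_id = copy_id
        self.intronless = intronless


@dataclass
class SimulatedFamily:
    species: SpeciesTreeIndex
    gene_tree: dendropy.Tree | None  # None when the family went extinct
    event_log: list
    genes: dict                      # species label -> list[SimulatedGene]
    config: SimulationConfig

    @property
    def all_genes(self) -> list:
        return [g for gs in self.genes.values() for g in gs]


class _CopyFactory:
    def __init__(self) -> None:
        self.n = 0

    def new(self) -> str:
        self.n += 1
        return f"g{self.n}"


def simulate_family(
    species: SpeciesTreeIndex | dendropy.Tree, config: SimulationConfig
) -> SimulatedFamily:
    """Simulate one gene family from a single root copy.

    Deterministic under a fixed ``config.seed``.  Aborts with guidance if
    the number of live copies ever exceeds ``config.max_copies`` (lower the
    duplication rate or shorten branches).
    """
    if isinstance(species, dendropy.Tree):
        species = SpeciesTreeIndex(species)
    for node in species.tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            raise ValueError(
                "species tree must carry branch lengths for simulation"
            )
    rng = np.random.default_rng(config.seed)
    log: list[Event] = []
    genes: dict = {lab: [] for lab in species.leaf_by_label}
    factory = _CopyFactory()
    lam, mu = config.duplication_rate, config.loss_rate
    budget = {"dups": 0}
    max_events = max(config.max_copies, 1) * 64

    def evolve(node: dendropy.Node, t: float, lin: _Lineage):
        """Evolve one copy from time t on the branch above ``node``; returns
        a newick fragment for the surviving subtree, or None."""
        L = node.edge.length if node.parent_node is not None else 0.0
        rate = lam + mu
        wait = rng.exponential(1.0 / rate) if rate > 0 else float("inf")
        if t + wait < L:
            t += wait
            if rng.random() < (lam / rate):
                budget["dups"] += 1
                if budget["dups"] > max_events:
                    raise RuntimeError(
                        "copy explosion: duplication count exceeded the cap; "
                        "reduce duplication_rate or branch lengths, or raise max_copies"
                    )
                retro = bool(rng.random() < config.retro_fraction)
                child = _Lineage(factory.new(), lin.intronless or retro)
                log.append(
                    Event(
                        branch=branch_id(node),
                        time=t,
                        type="retroduplication" if retro else "duplication",
                        parent_copy=lin.copy_id,
                        child_copy=child.copy_id,
                    )
                )
                a = evolve(node, t, lin)
                b = evolve(node, t, child)
                if a and b:
                    return f"({a},{b})"
                return a or b
            log.append(Event(branch_id(node), t, "loss", lin.copy_id, None))
            return None
        # survived to the bottom of the branch
        if node.is_leaf():
            sp = node.taxon.label
            gene_id = f"{sp}_{lin.copy_id}"  # copy id kept for traceability
            genes[sp].append(SimulatedGene(gene_id, sp, lin.intronless))
            if len(genes[sp]) > config.max_copies:
                raise RuntimeError(
                    f"copy explosion: {sp} exceeded max_copies={config.max_copies}; "
                    "reduce duplication_rate or branch lengths, or raise max_copies"
                )
            return f"{sp}|{gene_id}"
        parts = []
        for child_node in node.child_nodes():
            sub = evolve(child_node, 0.0, _Lineage(lin.copy_id, lin.intronless))
            if sub:
                parts.append(sub)
        if not parts:
            return None
        if len(parts) == 1:
            return parts[0]
        return f"({','.join(parts)})"

    root_lineage = _Lineage(factory.new(), False)
    newick = evolve(species.root, 0.0, root_lineage)
    gene_tree = (
        dendropy.Tree.get(data=newick + ";", schema="newick", preserve_underscores=True) if newick else None
    )
    return SimulatedFamily(species, gene_tree, log, genes, config)


# ---------------------------------------------------------------- sequences

@dataclass(frozen=True)
class ProteinTemplate:
    """Template protein: optional Btd segment, a linker, and the
    zinc-finger window with aspartate at the checked position."""

    pattern: ArchitecturePattern = ArchitecturePattern()
    n_terminus: str = "MSAQTPLE"
    btd: str | None = "CQCPNC"   # matches the placeholder Btd regex C.CP.C
    linker: str = "GSTPSLQAGPAT"
    c_terminus: str = "KRSLE"

    def window(self) -> str:
        chars: list[str] = []
        for el in self.pattern.elements:
            if isinstance(el, int):
                chars.extend("A" * el)
            else:
                chars.append(el)
        chars[self.pattern.d_position - 1] = "D"
        return "".join(chars)

    def sequence(self) -> str:
        parts = [self.n_terminus]
        if self.btd:
            parts.append(self.btd)
        parts += [self.linker, self.window(), self.c_terminus]
        return "".join(parts)

    def window_offset(self) -> int:
        off = len(self.n_terminus) + (len(self.btd) if self.btd else 0)
        return off + len(self.linker)

    def mutable_offsets(self) -> list[int]:
        """Absolute offsets of spacer positions (D44 position excluded)."""
        off = self.window_offset()
        out, pos = [], 0
        for el in self.pattern.elements:
            if isinstance(el, int):
                for k in range(el):
                    if pos + k + 1 != self.pattern.d_position:
                        out.append(off + pos + k)
                pos += el
            else:
                pos += 1
        return out


def emit_proteins(
    family: SimulatedFamily,
    template: ProteinTemplate | None = None,
    mutation_rate: float | None = None,
    seed: int | None = None,
    break_d44: bool = False,
    drop_btd: bool = False,
    uniform_over_all_sites: bool = False,
):
    """One protein per surviving gene copy.

    Mutations hit the zinc-finger spacer positions only (holding D44), so
    every emitted record keeps the architecture; set
    ``uniform_over_all_sites`` to mutate fixed residues too (negative
    controls), ``break_d44``/``drop_btd`` for targeted ablations.
    """
    from .motifs import ProteinRecord

    template = template or ProteinTemplate()
    mu = family.config.mutation_rate if mutation_rate is None else mutation_rate
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mutation_rate must be in [0, 1]")
    rng = np.random.default_rng(family.config.seed + 7919 if seed is None else seed)
    if drop_btd:
        template = replace(template, btd=None)
    base = template.sequence()
    if break_d44:
        i = template.window_offset() + template.pattern.d_position - 1
        base = base[:i] + "E" + base[i + 1 :]
    sites = (
        list(range(len(base))) if uniform_over_all_sites else template.mutable_offsets()
    )
    records = []
    for gene in sorted(family.all_genes, key=lambda g: g.gene_id):
        seq = list(base)
        if mu > 0:
            for i in sites:
                if rng.random() < mu:
                    seq[i] = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
        records.append(
            ProteinRecord(
                id=gene.gene_id, sequence="".join(seq), taxon=gene.species
            )
        )
    return records


def emit_annotations(family: SimulatedFamily, exon_length: int = 150, intron_length: int = 200):
    """GFF-style gene models: per species, copies sit in tandem on one
    scaffold spaced by ``cluster_spacing``, same strand; retro-derived
    copies are single-exon, others carry ``intron_count`` introns."""
    from .synteny import GeneModel

    cfg = family.config
    models = []
    for sp in sorted(family.genes):
        for i, gene in enumerate(sorted(family.genes[sp], key=lambda g: g.gene_id)):
            start = i * cfg.cluster_spacing
            if gene.retro:
                exons = [(start, start + exon_length * (cfg.intron_count + 1))]
            else:
                exons = []
                pos = start
                for _ in range(cfg.intron_count + 1):
                    exons.append((pos, pos + exon_length))
                    pos += exon_length + intron_length
            end = exons[-1][1]
            models.append(
                GeneModel(
                    gene_id=gene.gene_id,
                    species=sp,
                    scaffold=f"scf_{sp}",
                    start=start,
                    end=end,
                    strand="+",
                    exons=tuple(exons),
                    family="sim",
                )
            )
    return models


def truth_tables(family: SimulatedFamily):
    """(copy-number matrix, true per-branch event map) from the family."""
    matrix = {sp: len(gs) for sp, gs in family.genes.items()}
    branches: dict = {}
    for ev in family.event_log:
        d, l = branches.get(ev.branch, (0, 0))
        if ev.type == "loss":
            branches[ev.branch] = (d, l + 1)
        else:
            branches[ev.branch] = (d + 1, l)
    emap = EventMap(
        family.species,
        {
            bid: BranchEvents(*branches.get(bid, (0, 0)), provenance="truth")
            for bid in family.species.branch_ids()
        },
    )
    return matrix, emap


def replay_counts(family: SimulatedFamily) -> dict:
    """Leaf copy counts derived from the EventLog alone (replay identity):
    count(species) = 1 + sum over root-path branches of (dups - losses)."""
    per_branch: dict = {}
    for ev in family.event_log:
        delta = -1 if ev.type == "loss" else 1
        per_branch[ev.branch] = per_branch.get(ev.branch, 0) + delta
    counts = {}
    for lab, leaf in family.species.leaf_by_label.items():
        total = 1
        node = leaf
        while node is not None:
            total += per_branch.get(branch_id(node), 0)
            node = family.species.parent[node]
        counts[lab] = total
    return counts


def write_outputs(family: SimulatedFamily, outdir: str, template: ProteinTemplate | None = None) -> dict:
    """Write FASTA / GFF3 / newick / TSV / JSON artifacts; returns paths."""
    import os

    from .synteny import write_gff3

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "fasta": os.path.join(outdir, "proteins.fasta"),
        "gff": os.path.join(outdir, "genes.gff3"),
        "gene_tree": os.path.join(outdir, "gene_tree.nwk"),
        "counts": os.path.join(outdir, "copy_number.tsv"),
        "events": os.path.join(outdir, "events.json"),
    }
    records = emit_proteins(family, template=template)
    with open(paths["fasta"], "w") as fh:
        for r in records:
            fh.write(f">{r.id} {r.taxon}\n{r.sequence}\n")
    write_gff3(emit_annotations(family), paths["gff"])
    with open(paths["gene_tree"], "w") as fh:
        if family.gene_tree is not None:
            fh.write(family.gene_tree.as_string(schema="newick", unquoted_underscores=True).strip() + "\n")
    matrix, emap = truth_tables(family)
    with open(paths["counts"], "w") as fh:
        fh.write("species\tcount\n")
        for sp in sorted(matrix):
            fh.write(f"{sp}\t{matrix[sp]}\n")
    with open(paths["events"], "w") as fh:
        json.dump(
            {
                "event_log": [vars(e) for e in family.event_log],
                "event_map": {
                    bid: {
                        "duplications": ev.duplications,
                        "losses": ev.losses,
                        "provenance": ev.provenance,
                    }
                    for bid, ev in sorted(emap.branches.items())
                },
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return paths
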