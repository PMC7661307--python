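"""Gene-tree / species-tree reconciliation and copy-number parsimony.

Three inference routes, kept deliberately separate:

* :func:`lca_reconcile` — classical last-common-ancestor mapping of a
  rooted binary gene tree onto a rooted binary species tree.  Each gene
  node maps to the LCA of its descendant species; a node is a duplication
  iff it maps to the same species node as one of its children; losses are
  read off the depth gaps along each gene-tree edge and attributed to the
  specific off-path species branches.  The mapping minimises
  duplications + losses among all valid reconciliations.
* :func:`ancestral_copy_number` — Sankoff dynamic programming over integer
  copy counts 0..max_copies on the species tree, with per-copy gain/loss
  costs.  Missing leaves (incomplete transcriptome sampling) contribute
  zero cost in every state: missing data is not evidence of absence.
* :func:`combine_evidence` — count parsimony alone need not recover the
  history supported by gene-tree topology (e.g. several independent
  two-copy lineages can drag the root state up).  Override directives
  replace the count-based events inside a named clade with gene-tree
  derived events, provenance-tagged, mirroring the practice of preferring
  phylogenetic signal over raw count parsimony for selected clades.

Gene-tree leaves are labelled ``species|gene``; species trees are newick
cladograms with unique leaf labels.  Branches are identified by the node
below them: the leaf label, an internal node label when present, otherwise
the sorted descendant leaf labels joined with ``+``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "SpeciesTreeIndex",
    "Reconciliation",
    "CostModel",
    "EventMap",
    "BranchEvents",
    "OverrideDirective",
    "parse_gene_leaf",
    "lca_reconcile",
    "count_losses",
    "ancestral_copy_number",
    "combine_evidence",
    "brute_force_reconcile",
    "event_map_from_reconciliation",
    "event_map_from_copy_number",
    "ancestral_counts_from_event_map",
    "AncestralCopyNumber",
    "branch_id",
    "read_species_tree",
    "read_gene_tree",
    "species_tree_from_string",
    "gene_tree_from_string",
]


def parse_gene_leaf(label: str) -> tuple[str, str]:
    """Split a ``species|gene`` leaf label."""
    if "|" not in label:
        raise ValueError(f"gene leaf {label!r} is not of the form 'species|gene'")
    species, gene = label.split("|", 1)
    return species, gene


def branch_id(node: dendropy.Node) -> str:
    """Stable identifier for the branch subtending ``node``."""
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    return "+".join(sorted(lf.taxon.label for lf in node.leaf_iter()))


class SpeciesTreeIndex:
    """Rooted binary species tree with depths, parents and LCA queries."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.root = tree.seed_node
        self.depth: dict = {}
        self.parent: dict = {}
        self.leaf_by_label: dict = {}
        labels = set()
        for node in tree.preorder_node_iter():
            kids = node.child_nodes()
            if kids and len(kids) != 2:
                raise ValueError(
                    "species tree must be binary for reconciliation; resolve the "
                    f"polytomy at {branch_id(node)!r} explicitly (resolution choice "
                    "changes event counts)"
                )
            self.depth[node] = 0 if node.parent_node is None else self.depth[node.parent_node] + 1
            self.parent[node] = node.parent_node
            if node.is_leaf():
                if node.taxon.label in labels:
                    raise ValueError(f"duplicate species label {node.taxon.label!r}")
                labels.add(node.taxon.label)
                self.leaf_by_label[node.taxon.label] = node
        self.nodes = list(tree.preorder_node_iter())

    def leaf(self, label: str) -> dendropy.Node:
        try:
            return self.leaf_by_label[label]
        except KeyError:
            raise ValueError(f"unknown species label {label!r}") from None

    def lca(self, a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
        while self.depth[a] > self.depth[b]:
            a = self.parent[a]
        while self.depth[b] > self.depth[a]:
            b = self.parent[b]
        while a is not b:
            a, b = self.parent[a], self.parent[b]
        return a

    def is_ancestor_or_equal(self, anc: dendropy.Node, node: dendropy.Node) -> bool:
        while node is not None and self.depth[node] >= self.depth[anc]:
            if node is anc:
                return True
            node = self.parent[node]
        return False

    def ancestors_or_self(self, node: dendropy.Node) -> list:
        out = []
        while node is not None:
            out.append(node)
            node = self.parent[node]
        return out

    def branch_ids(self) -> list:
        return [branch_id(n) for n in self.nodes]


@dataclass
class Reconciliation:
    """LCA mapping with event labels and per-branch event counts."""

    gene_tree: dendropy.Tree
    species: SpeciesTreeIndex
    node_map: dict              # gene node -> species node
    events: dict                # gene internal node -> "speciation"|"duplication"
    duplications: dict          # branch_id -> count
    losses: dict                # branch_id -> count

    @property
    def duplication_count(self) -> int:
        return sum(self.duplications.values())

    @property
    def loss_count(self) -> int:
        return sum(self.losses.values())

    @property
    def cost(self) -> int:
        return self.duplication_count + self.loss_count


def _check_binary(tree: dendropy.Tree, what: str) -> None:
    for node in tree.preorder_node_iter():
        kids = node.child_nodes()
        if kids and len(kids) != 2:
            raise ValueError(f"{what} must be binary")


def lca_reconcile(gene_tree: dendropy.Tree, species: SpeciesTreeIndex | dendropy.Tree) -> Reconciliation:
    """LCA reconciliation of a rooted binary gene tree onto a species tree.

    Returns the unique LCA mapping with duplication labels, and losses
    attributed to the species branch on which each loss occurred.  The
    total cost (duplications + losses) is minimal over all duplication-loss
    reconciliations of the pair.
    """
    if isinstance(species, dendropy.Tree):
        species = SpeciesTreeIndex(species)
    _check_binary(gene_tree, "gene tree")
    M: dict = {}
    events: dict = {}
    genes_seen = set()
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            sp, gene = parse_gene_leaf(node.taxon.label)
            if gene in genes_seen:
                raise ValueError(f"duplicate gene id {gene!r}")
            genes_seen.add(gene)
            M[node] = species.leaf(sp)
        else:
            c1, c2 = node.child_nodes()
            M[node] = species.lca(M[c1], M[c2])
            events[node] = (
                "duplication" if M[node] is M[c1] or M[node] is M[c2] else "speciation"
            )
    dups = {bid: 0 for bid in species.branch_ids()}
    losses = {bid: 0 for bid in species.branch_ids()}
    for node, ev in events.items():
        if ev == "duplication":
            dups[branch_id(M[node])] += 1
    # Losses: walk each gene edge u->v through the species tree.  At every
    # species node where the gene lineage is present but only the child
    # toward M(v) retains it, the off-path child branch records one loss.
    # A duplication at u places the lineage at M(u) itself; a speciation
    # consumes the split at M(u), so the walk starts one step lower.
    for u in gene_tree.preorder_node_iter():
        if u.is_leaf():
            continue
        for v in u.child_nodes():
            top, bottom = M[u], M[v]
            path = []
            w = bottom
            while w is not top:
                path.append(w)
                w = species.parent[w]
            path.append(top)
            path.reverse()  # top .. bottom
            start = 0 if events[u] == "duplication" else 1
            for i in range(start, len(path) - 1):
                w, on_path = path[i], path[i + 1]
                for child in w.child_nodes():
                    if child is not on_path:
                        losses[branch_id(child)] += 1
    return Reconciliation(gene_tree, species, M, events, dups, losses)


def count_losses(rec: Reconciliation) -> dict:
    """Per-branch loss counts of a reconciliation (branch_id -> count)."""
    return dict(rec.losses)


def brute_force_reconcile(
    gene_tree: dendropy.Tree, species: SpeciesTreeIndex | dendropy.Tree
) -> int:
    """Minimum duplication+loss cost by exhaustive search (test oracle).

    Enumerates every valid mapping of gene-tree internal nodes to species
    nodes (each node maps to an ancestor-or-self of its children's LCA) and
    scores duplications and losses from first principles.  Limited to gene
    trees with at most 8 leaves.
    """
    if isinstance(species, dendropy.Tree):
        species = SpeciesTreeIndex(species)
    leaves = [lf for lf in gene_tree.leaf_node_iter()]
    if len(leaves) > 8:
        raise ValueError("brute-force oracle limited to gene trees with <= 8 leaves")
    _check_binary(gene_tree, "gene tree")
    M_leaf = {lf: species.leaf(parse_gene_leaf(lf.taxon.label)[0]) for lf in leaves}
    internal = [n for n in gene_tree.postorder_node_iter() if not n.is_leaf()]

    def subtree_lca(node) -> dendropy.Node:
        lca = None
        for lf in node.leaf_iter():
            lca = M_leaf[lf] if lca is None else species.lca(lca, M_leaf[lf])
        return lca

    choices = [species.ancestors_or_self(subtree_lca(n)) for n in internal]
    depth = species.depth
    best = None
    for combo in itertools.product(*choices):
        M = dict(M_leaf)
        M.update(zip(internal, combo))
        ok = all(
            species.is_ancestor_or_equal(M[n], M[c])
            for n in internal
            for c in n.child_nodes()
        )
        if not ok:
            continue
        cost = 0
        for n in internal:
            c1, c2 = n.child_nodes()
            lca = species.lca(M[c1], M[c2])
            in_distinct = (
                M[n] is lca
                and M[c1] is not M[n]
                and M[c2] is not M[n]
            )
            if in_distinct:  # speciation
                cost += (depth[M[c1]] - depth[M[n]] - 1) + (depth[M[c2]] - depth[M[n]] - 1)
            else:  # duplication
                cost += 1
                cost += (depth[M[c1]] - depth[M[n]]) + (depth[M[c2]] - depth[M[n]])
        if best is None or cost < best:
            best = cost
    return best


@dataclass(frozen=True)
class CostModel:
    """Per-copy gain/loss costs for copy-number parsimony."""

    gain_cost: float = 1.0
    loss_cost: float = 1.0
    max_copies: int = 8

    def __post_init__(self) -> None:
        if self.gain_cost <= 0 or self.loss_cost <= 0:
            raise ValueError("costs must be > 0")
        if self.max_copies < 0:
            raise ValueError("max_copies must be >= 0")

    def step(self, parent_state: int, child_state: int) -> float:
        d = child_state - parent_state
        return d * self.gain_cost if d >= 0 else -d * self.loss_cost


@dataclass
class AncestralCopyNumber:
    """Result of the Sankoff DP: one minimum assignment plus diagnostics."""

    states: dict          # branch_id -> int (one minimum-cost assignment)
    root_state: int       # canonical: smallest among minimum-cost root states
    min_root_states: tuple  # all minimum-cost root states
    cost: float


def ancestral_copy_number(
    matrix: dict,
    species: SpeciesTreeIndex | dendropy.Tree,
    cost_model: CostModel | None = None,
) -> AncestralCopyNumber:
    """Sankoff parsimony over integer copy numbers on the species tree.

    ``matrix`` maps species label -> count, or ``None`` for missing data;
    missing leaves contribute zero cost for every state.  Ties at the root
    are all reported; the canonical single answer is the smallest state.
    """
    if isinstance(species, dendropy.Tree):
        species = SpeciesTreeIndex(species)
    cm = cost_model or CostModel()
    observed = [c for c in matrix.values() if c is not None]
    if not observed:
        raise ValueError("copy-number matrix has no observed entries")
    if max(observed) > cm.max_copies:
        raise ValueError("observed count exceeds cost model max_copies")
    states = range(cm.max_copies + 1)
    INF = float("inf")
    down: dict = {}
    for node in species.tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            count = matrix.get(label)
            if count is None:
                down[node] = [0.0] * len(states)
            else:
                down[node] = [0.0 if s == count else INF for s in states]
        else:
            vec = []
            for s in states:
                total = 0.0
                for child in node.child_nodes():
                    total += min(cm.step(s, t) + down[child][t] for t in states)
                vec.append(total)
            down[node] = vec
    root = species.root
    cost = min(down[root])
    min_roots = tuple(s for s in states if down[root][s] == cost)
    assignment: dict = {}

    def backtrack(node, s) -> None:
        assignment[branch_id(node)] = s
        for child in node.child_nodes():
            best_t = min(
                states, key=lambda t: (cm.step(s, t) + down[child][t], t)
            )
            backtrack(child, best_t)

    backtrack(root, min_roots[0])
    return AncestralCopyNumber(assignment, min_roots[0], min_roots, cost)


@dataclass(frozen=True)
class BranchEvents:
    duplications: int = 0
    losses: int = 0
    provenance: str = "count-parsimony"

    def __post_init__(self) -> None:
        if self.duplications < 0 or self.losses < 0:
            raise ValueError("event counts must be >= 0")


@dataclass
class EventMap:
    """Per-branch duplication/loss counts over a species tree."""

    species: SpeciesTreeIndex
    branches: dict  # branch_id -> BranchEvents

    def __post_init__(self) -> None:
        want = set(self.species.branch_ids())
        have = set(self.branches)
        missing = want - have
        for bid in missing:
            self.branches[bid] = BranchEvents()
        extra = have - want
        if extra:
            raise ValueError(f"event map has unknown branches: {sorted(extra)}")

    def total(self) -> tuple[int, int]:
        d = sum(b.duplications for b in self.branches.values())
        l = sum(b.losses for b in self.branches.values())
        return d, l

    @classmethod
    def zero(cls, species: SpeciesTreeIndex) -> "EventMap":
        return cls(species, {bid: BranchEvents() for bid in species.branch_ids()})


def event_map_from_reconciliation(rec: Reconciliation, provenance: str = "gene-tree") -> EventMap:
    branches = {
        bid: BranchEvents(rec.duplications[bid], rec.losses[bid], provenance)
        for bid in rec.species.branch_ids()
    }
    return EventMap(rec.species, branches)


def event_map_from_copy_number(
    acn: AncestralCopyNumber, species: SpeciesTreeIndex
) -> EventMap:
    """Per-branch gains/losses implied by an ancestral-state assignment."""
    branches: dict = {}
    for node in species.tree.preorder_node_iter():
        bid = branch_id(node)
        if node.parent_node is None:
            branches[bid] = BranchEvents(0, 0, "count-parsimony")
            continue
        delta = acn.states[bid] - acn.states[branch_id(node.parent_node)]
        branches[bid] = BranchEvents(
            max(delta, 0), max(-delta, 0), "count-parsimony"
        )
    return EventMap(species, branches)


def ancestral_counts_from_event_map(
    event_map: EventMap, root_copies: int = 1
) -> dict:
    """Copy number at the bottom of every branch, replaying the event map
    from ``root_copies`` ancestral copies above the root."""
    counts: dict = {}
    sp = event_map.species
    for node in sp.tree.preorder_node_iter():
        bid = branch_id(node)
        ev = event_map.branches[bid]
        base = root_copies if node.parent_node is None else counts[branch_id(node.parent_node)]
        counts[bid] = base + ev.duplications - ev.losses
    return counts


@dataclass(frozen=True)
class OverrideDirective:
    """Replace count-based events inside a clade with gene-tree evidence.

    ``clade`` names a species-tree node (its branch_id); ``replacement``
    maps branch_id -> (duplications, losses) for branches within the clade
    (unlisted branches inside the clade become 0/0).
    """

    clade: str
    replacement: dict
    justification: str = ""


def combine_evidence(
    count_map: EventMap,
    gene_tree_maps: list | None = None,
    overrides: list | None = None,
) -> EventMap:
    """Combine count parsimony with gene-tree overrides.

    The output defaults to ``count_map``; every branch inside an override
    clade gets the directive's events (falling back to the corresponding
    gene-tree map branch when the directive lists none and a gene-tree map
    is supplied), provenance-tagged ``"override"``.  Overlapping overrides
    raise with the list of conflicting branches.
    """
    overrides = overrides or []
    gene_tree_maps = gene_tree_maps or []
    sp = count_map.species
    by_bid = {branch_id(n): n for n in sp.nodes}
    claimed: dict = {}
    for ov in overrides:
        if ov.clade not in by_bid:
            raise ValueError(f"override clade {ov.clade!r} not in species tree")
        node = by_bid[ov.clade]
        clade_bids = [branch_id(n) for n in node.preorder_iter()]
        for bid in clade_bids:
            if bid in claimed:
                raise ValueError(
                    f"conflicting overrides on branch {bid!r}: "
                    f"clades {claimed[bid]!r} and {ov.clade!r}"
                )
            claimed[bid] = ov.clade
        unknown = set(ov.replacement) - set(clade_bids)
        if unknown:
            raise ValueError(
                f"override for {ov.clade!r} lists branches outside the clade: {sorted(unknown)}"
            )
    out = {bid: ev for bid, ev in count_map.branches.items()}
    gtm_by_bid: dict = {}
    for gtm in gene_tree_maps:
        for bid, ev in gtm.branches.items():
            if ev.duplications or ev.losses:
                gtm_by_bid[bid] = ev
    for ov in overrides:
        node = by_bid[ov.clade]
        for n in node.preorder_iter():
            bid = branch_id(n)
            if bid in ov.replacement:
                d, l = ov.replacement[bid]
            elif bid in gtm_by_bid:
                d, l = gtm_by_bid[bid].duplications, gtm_by_bid[bid].losses
            else:
                d, l = 0, 0
            out[bid] = BranchEvents(d, l, "override")
    return EventMap(sp, out)


def read_species_tree(path: str) -> SpeciesTreeIndex:
    tree = dendropy.Tree.get(path=path, schema="newick", preserve_underscores=True)
    return SpeciesTreeIndex(tree)


def read_gene_tree(path: str) -> dendropy.Tree:
    return dendropy.Tree.get(path=path, schema="newick", preserve_underscores=True)


def species_tree_from_string(newick: str) -> SpeciesTreeIndex:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return SpeciesTreeIndex(tree)


def gene_tree_from_string(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
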