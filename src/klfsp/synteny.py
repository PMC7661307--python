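"""Gene architecture and synteny: introns, tandem clusters, retrocopies.

A gene duplicated through an mRNA intermediate (retroduplication) lands in
the genome without its introns.  Within a paralog family, an intronless
copy alongside an intron-bearing ("parental-like") copy in the same species
is therefore a retrocopy candidate; if every family member is intronless
the signal is uninformative and all calls are ambiguous.  Tandem clustering
of family members within a distance window (default 1.5 Mb between gene
starts) and conserved order/orientation across species provide the
complementary synteny evidence.

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive) is
converted at the I/O boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import gffutils

from . import reconcile as _rec

__all__ = [
    "GeneModel",
    "LocusCluster",
    "OrderSignature",
    "RetrocopyCall",
    "RetroEvent",
    "intron_count",
    "detect_clusters",
    "order_signature",
    "signatures_equal",
    "classify_retrocopies",
    "assign_retro_events",
    "read_gff3",
    "write_gff3",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exon structure on a scaffold (0-based, half-open)."""

    gene_id: str
    species: str
    scaffold: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    family: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must precede end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene model needs >= 1 exon")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: exon outside gene span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e


def intron_count(gene: GeneModel) -> int:
    """Number of introns = exons - 1."""
    return len(gene.exons) - 1


@dataclass(frozen=True)
class LocusCluster:
    """Tandem family members on one scaffold within a diameter window."""

    members: tuple[GeneModel, ...]  # ordered by start
    scaffold: str

    @property
    def span(self) -> tuple[int, int]:
        return self.members[0].start, max(g.end for g in self.members)

    @property
    def diameter(self) -> int:
        starts = [g.start for g in self.members]
        return max(starts) - min(starts)

    @property
    def all_same_strand(self) -> bool:
        return len({g.strand for g in self.members}) == 1


def detect_clusters(
    genes: list[GeneModel],
    window: int = 1_500_000,
    require_same_strand: bool = False,
) -> list[LocusCluster]:
    """Greedy left-to-right tandem clustering under a diameter constraint.

    Genes on one scaffold are sorted by start; a cluster grows while the
    maximum pairwise gap between member gene starts (its diameter) stays
    within ``window``.  Strand agreement is reported on each cluster and
    only enforced when ``require_same_strand`` is set.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    by_scaffold: dict = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    clusters: list[LocusCluster] = []
    for scaffold in sorted(by_scaffold):
        current: list[GeneModel] = []
        for g in sorted(by_scaffold[scaffold], key=lambda g: (g.start, g.gene_id)):
            if current and (
                g.start - current[0].start > window
                or (require_same_strand and g.strand != current[0].strand)
            ):
                clusters.append(LocusCluster(tuple(current), scaffold))
                current = []
            current.append(g)
        if current:
            clusters.append(LocusCluster(tuple(current), scaffold))
    return clusters


class OrderSignature(tuple):
    """Canonical (family label, orientation) sequence of a cluster.

    Reading a scaffold from the other strand reverses gene order and flips
    every orientation; the canonical form is the lexicographically smaller
    of the forward reading and its flip, so equality is flip-invariant.
    """


def _flip(sig: tuple) -> tuple:
    return tuple((lab, "-" if ori == "+" else "+") for lab, ori in reversed(sig))


def order_signature(cluster: LocusCluster, family_labels: dict | None = None) -> OrderSignature:
    """Canonicalised (label, orientation) signature of a cluster.

    ``family_labels`` maps gene_id -> family member label; omitted, the
    models' own ``family`` field is used.  Unlabelled members are an error.
    """
    raw = []
    for g in cluster.members:
        label = (family_labels or {}).get(g.gene_id, g.family)
        if not label:
            raise ValueError(f"{g.gene_id}: no family label")
        raw.append((label, g.strand))
    fwd = tuple(raw)
    return OrderSignature(min(fwd, _flip(fwd)))


def signatures_equal(s1, s2) -> bool:
    return OrderSignature(min(tuple(s1), _flip(tuple(s1)))) == OrderSignature(
        min(tuple(s2), _flip(tuple(s2)))
    )


@dataclass(frozen=True)
class RetrocopyCall:
    gene_id: str
    intronless: bool
    call: str  # "retrocopy-candidate" | "parental-like" | "ambiguous"


def classify_retrocopies(family_genes: list[GeneModel]) -> list[RetrocopyCall]:
    """Classify family members of ONE species by intron presence.

    An intronless gene is a retrocopy candidate only when the family also
    contains an intron-bearing member (the putative parental lineage); a
    family that is entirely intronless carries no directional signal and
    every member is called ambiguous.
    """
    if not family_genes:
        raise ValueError("empty family")
    any_introns = any(intron_count(g) > 0 for g in family_genes)
    calls = []
    for g in family_genes:
        il = intron_count(g) == 0
        if not il:
            call = "parental-like"
        elif any_introns:
            call = "retrocopy-candidate"
        else:
            call = "ambiguous"
        calls.append(RetrocopyCall(g.gene_id, il, call))
    return calls


@dataclass(frozen=True)
class RetroEvent:
    """A duplication node inferred to be a retroduplication."""

    node_branch: str        # species-tree branch of the duplication (branch_id)
    clade_leaves: tuple     # gene leaf labels of the all-retrocopy clade


def assign_retro_events(
    gene_tree,
    rec: "_rec.Reconciliation",
    calls: list[RetrocopyCall],
) -> list[RetroEvent]:
    """Place retroduplication events on the species tree.

    For each maximal gene-tree clade whose leaves are all retrocopy
    candidates and whose sister subtree contains at least one parental-like
    gene, one event is emitted at the clade's parent node — provided the
    reconciliation labels that parent a duplication (otherwise the clade is
    skipped with a warning) — on the species branch the parent maps to.
    """
    call_by_gene = {c.gene_id: c for c in calls}

    def leaf_call(leaf) -> RetrocopyCall:
        _, gene = _rec.parse_gene_leaf(leaf.taxon.label)
        if gene not in call_by_gene:
            raise ValueError(f"no retrocopy call for gene {gene!r}")
        return call_by_gene[gene]

    def all_retro(node) -> bool:
        return all(leaf_call(lf).call == "retrocopy-candidate" for lf in node.leaf_iter())

    def any_parental(node) -> bool:
        return any(leaf_call(lf).call == "parental-like" for lf in node.leaf_iter())

    events: list[RetroEvent] = []
    # preorder => a maximal all-retro clade is visited before its subclades
    claimed: set = set()
    for node in gene_tree.preorder_node_iter():
        if node.parent_node is None or id(node) in claimed or not all_retro(node):
            continue
        parent = node.parent_node
        sisters = [c for c in parent.child_nodes() if c is not node]
        if not any(any_parental(s) for s in sisters):
            continue
        for desc in node.preorder_iter():
            claimed.add(id(desc))
        if rec.events.get(parent) != "duplication":
            warnings.warn(
                "all-retrocopy clade whose parent is not a duplication; skipped",
                stacklevel=2,
            )
            continue
        events.append(
            RetroEvent(
                node_branch=_rec.branch_id(rec.node_map[parent]),
                clade_leaves=tuple(sorted(lf.taxon.label for lf in node.leaf_iter())),
            )
        )
    return events


def read_gff3(path: str, species: str = "", family_map: dict | None = None) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA/exon features, ID/Parent).

    Coordinates are converted from GFF3's 1-based inclusive convention to
    0-based half-open.  ``family_map`` (gene_id -> family label) fills the
    ``family`` field.
    """
    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in db.features_of_type("gene"):
        exons = []
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = sorted((e.start - 1, e.end) for e in db.children(mrna, featuretype="exon"))
            break
        if not exons:
            exons = sorted((e.start - 1, e.end) for e in db.children(gene, featuretype="exon"))
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        models.append(
            GeneModel(
                gene_id=gene.id,
                species=species or gene.attributes.get("species", [""])[0],
                scaffold=gene.seqid,
                start=gene.start - 1,
                end=gene.end,
                strand=gene.strand,
                exons=tuple(exons),
                family=(family_map or {}).get(gene.id, gene.attributes.get("family", [""])[0]),
            )
        )
    models.sort(key=lambda g: (g.scaffold, g.start, g.gene_id))
    return models


def write_gff3(models: list[GeneModel], path: str) -> None:
    """Write gene models as GFF3 (gene + mRNA + exon rows)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            attrs = f"ID={g.gene_id}"
            if g.species:
                attrs += f";species={g.species}"
            if g.family:
                attrs += f";family={g.family}"
            fh.write(
                f"{g.scaffold}\tklfsp\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.scaffold}\tklfsp\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.scaffold}\tklfsp\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
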