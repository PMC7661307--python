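"""Split frequencies, convergence diagnostics and support categories.

Bayesian tree inference yields posterior samples of topologies; two
independent MCMC runs have converged on the same posterior when each
non-trivial bipartition (split) appears at similar frequency in both.  The
standard summary is the average standard deviation of split frequencies
(ASDSF): for each split passing a minimum-frequency filter, take the
two-sample standard deviation of its frequencies in the two runs
(sample convention, divisor n-1, i.e. |f1 - f2| / sqrt(2)), and average.
Values near zero indicate convergence; community practice treats < 0.01 as
converged and < 0.05 as acceptable.

Posterior-probability support on consensus trees is categorised with strict
thresholds: above 0.5 (white), above 0.7 (grey), above 0.95 (black).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum

import dendropy

__all__ = [
    "Bipartition",
    "SplitTable",
    "SupportCategory",
    "bipartitions",
    "split_frequencies",
    "asdsf",
    "support_category",
    "read_tree_sample",
]


class Bipartition(frozenset):
    """A non-trivial leaf-set split, canonicalised as the side NOT
    containing the lexicographically smallest leaf label.

    Canonicalisation makes equal splits compare equal regardless of tree
    rotation or rooting; construct via :func:`make_bipartition`.
    """


def make_bipartition(side: frozenset, all_leaves: frozenset) -> Bipartition:
    ref = min(all_leaves)
    if ref in side:
        side = all_leaves - side
    return Bipartition(side)


def _leaf_labels(tree: dendropy.Tree) -> frozenset:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels in tree")
    return frozenset(labels)


def bipartitions(tree: dendropy.Tree) -> set:
    """Non-trivial splits induced by the internal edges of ``tree``.

    The tree is treated as unrooted: splits with a single leaf on either
    side are excluded, and the root edge induces no split of its own.
    """
    leaves = _leaf_labels(tree)
    n = len(leaves)
    out: set = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(side) < n - 1:
            out.add(make_bipartition(side, leaves))
    return out


@dataclass(frozen=True)
class SplitTable:
    """Split -> frequency over a tree sample, with the sample size."""

    frequencies: dict
    sample_size: int
    leaves: frozenset

    def __post_init__(self) -> None:
        for f in self.frequencies.values():
            if not 0.0 <= f <= 1.0:
                raise ValueError("split frequency outside [0, 1]")


def split_frequencies(sample: list) -> SplitTable:
    """Frequency of each non-trivial split across a sample of trees."""
    if not sample:
        raise ValueError("empty tree sample")
    leaves = _leaf_labels(sample[0])
    counts: dict = {}
    for tree in sample:
        if _leaf_labels(tree) != leaves:
            raise ValueError("inconsistent leaf sets across the sample")
        for split in bipartitions(tree):
            counts[split] = counts.get(split, 0) + 1
    n = len(sample)
    return SplitTable({s: c / n for s, c in counts.items()}, n, leaves)


def asdsf(run1: SplitTable, run2: SplitTable, min_freq: float = 0.10) -> float:
    """Average standard deviation of split frequencies between two runs.

    A split qualifies when its frequency reaches ``min_freq`` in at least
    one run; absent splits count as frequency 0 in the other run.  Returns
    0 (with a warning) when no split qualifies — the statistic is undefined
    on an empty split set.
    """
    if not 0.0 <= min_freq <= 1.0:
        raise ValueError("min_freq must be in [0, 1]")
    if run1.leaves != run2.leaves:
        raise ValueError("split tables are over different leaf sets")
    sds = []
    for split in set(run1.frequencies) | set(run2.frequencies):
        f1 = run1.frequencies.get(split, 0.0)
        f2 = run2.frequencies.get(split, 0.0)
        if max(f1, f2) >= min_freq:
            sds.append(abs(f1 - f2) / math.sqrt(2.0))
    if not sds:
        warnings.warn("no split reached min_freq; ASDSF undefined, returning 0",
                      stacklevel=2)
        return 0.0
    return sum(sds) / len(sds)


class SupportCategory(Enum):
    NONE = "none"
    WHITE = "white"   # pp above 0.5
    GREY = "grey"     # pp above 0.7
    BLACK = "black"   # pp above 0.95


def support_category(pp: float) -> SupportCategory:
    """Categorise a posterior probability; thresholds are strict ('above')."""
    if not 0.0 <= pp <= 1.0:
        raise ValueError("posterior probability must be in [0, 1]")
    if pp > 0.95:
        return SupportCategory.BLACK
    if pp > 0.7:
        return SupportCategory.GREY
    if pp > 0.5:
        return SupportCategory.WHITE
    return SupportCategory.NONE


def read_tree_sample(path: str, schema: str = "newick") -> list:
    """Read a tree sample: plain newick (one tree per line) or a NEXUS
    trees block (translate tables handled by the parser)."""
    tl = dendropy.TreeList.get(path=path, schema=schema)
    return list(tl)
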