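"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-implementations (sliding-window
matching, exhaustive enumeration) kept independent of the library code
paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from klfsp.motifs import AMINO_ACIDS, ArchitecturePattern
from klfsp.reconcile import (
    SpeciesTreeIndex,
    gene_tree_from_string,
    species_tree_from_string,
)


# ------------------------------------------------------------ naive oracles

def naive_scan(sequence: str, pattern: ArchitecturePattern) -> list[int]:
    """O(n*m) sliding-window matcher: all start offsets whose window
    satisfies every fixed residue of the pattern."""
    fixed = pattern.fixed_offsets()
    m = pattern.length
    starts = []
    for i in range(len(sequence) - m + 1):
        if all(sequence[i + off] == res for off, res in fixed):
            starts.append(i)
    return starts


def exhaustive_sankoff(matrix, species: SpeciesTreeIndex, cost_model):
    """Minimum total cost over ALL internal-state assignments (oracle)."""
    internal = [n for n in species.tree.preorder_node_iter() if not n.is_leaf()]
    states = range(cost_model.max_copies + 1)
    leaves = [n for n in species.tree.leaf_node_iter()]
    best = float("inf")
    for combo in itertools.product(states, repeat=len(internal)):
        assign = dict(zip(internal, combo))
        cost = 0.0
        for leaf in leaves:
            obs = matrix.get(leaf.taxon.label)
            if obs is None:
                continue
            cost += cost_model.step(assign[leaf.parent_node], obs)
        for node in internal:
            if node.parent_node is not None:
                cost += cost_model.step(assign[node.parent_node], assign[node])
        if cost < best:
            best = cost
    return best


# ------------------------------------------------------- random instances

def random_species_tree(rng: np.random.Generator, n_species: int) -> SpeciesTreeIndex:
    """Random rooted binary species tree over S1..Sn (random joins)."""
    parts = [f"S{i}" for i in range(1, n_species + 1)]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a},{b})")
    return species_tree_from_string(parts[0] + ";")


def random_gene_tree(rng: np.random.Generator, species_labels: list[str], n_genes: int):
    """Random rooted binary gene tree; each leaf gets a random species."""
    leaves = [
        f"{rng.choice(species_labels)}|q{i}" for i in range(1, n_genes + 1)
    ]
    parts = list(leaves)
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a},{b})")
    return gene_tree_from_string(parts[0] + ";")


def random_protein(rng: np.random.Generator, length: int, plant_window: bool = False) -> str:
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    if plant_window:
        pat = ArchitecturePattern()
        window = []
        for el in pat.elements:
            if isinstance(el, int):
                window.extend(rng.choice(list(AMINO_ACIDS), size=el))
            else:
                window.append(el)
        w = "".join(window)
        pos = int(rng.integers(0, max(1, length - len(w) + 1)))
        seq = seq[:pos] + w + seq[pos + len(w):]
    return seq


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
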