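"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from cognatree.data_io import DataTable
from cognatree.phylo import Node, PhyloTree
from cognatree.substitution import transition_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def make_table(languages, features, rows, source="memory"):
    """Build a DataTable from a list of row tuples ('?' = missing)."""
    cells = {}
    for lang, row in zip(languages, rows):
        for feat, val in zip(features, row):
            cells[(lang, feat)] = None if val == "?" else val
    return DataTable(list(languages), list(features), cells, source)


def balanced_tree(labels=("a", "b", "c", "d"), h1=0.5, h2=0.7, root=1.0):
    """((a,b),(c,d)) with fixed heights, for hand-computable checks."""
    x = Node(None, h1)
    x.add_child(Node(labels[0], 0.0))
    x.add_child(Node(labels[1], 0.0))
    y = Node(None, h2)
    y.add_child(Node(labels[2], 0.0))
    y.add_child(Node(labels[3], 0.0))
    r = Node(None, root)
    r.add_child(x)
    r.add_child(y)
    return PhyloTree(r)


def enumeration_loglik(tree, rate_matrix, pi, pattern, r_f=1.0):
    """Brute-force likelihood: sum over all internal-state assignments.

    Independent of the pruning recursion; feasible for <=4 leaves, k<=4.
    """
    nodes = tree.postorder
    internals = [n for n in nodes if not n.is_leaf]
    k = rate_matrix.k
    P = {n.index: transition_matrix(rate_matrix, tree.duration(n) * r_f)
         for n in nodes if n.parent is not None}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        amap = {n.index: s for n, s in zip(internals, assign)}
        p = pi[amap[tree.root.index]]
        for n in nodes:
            if n.parent is None:
                continue
            if n.is_leaf:
                s = pattern.get(n.label)
                if s is not None:
                    p *= P[n.index][amap[n.parent.index], s]
            else:
                p *= P[n.index][amap[n.parent.index], amap[n.index]]
        total += p
    return math.log(total) if total > 0 else -math.inf
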