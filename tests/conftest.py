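"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's own graph code paths: closure
is a naive fixpoint over pairs, reduction a pairwise implication sweep,
cut enumeration walks root-to-leaf paths.
"""

from __future__ import annotations

import pytest

from granopart import fixture
from granopart.core_model import ParthoodEdge


@pytest.fixture
def fig2():
    return fixture("fig2_organ")


@pytest.fixture
def fig5():
    return fixture("fig5_co")


@pytest.fixture
def fig11():
    return fixture("fig11_organ")


@pytest.fixture
def kumar_scheme():
    return fixture("kumar_human")


@pytest.fixture
def kumar_demo():
    return fixture("kumar_demo")


@pytest.fixture
def fma_scheme():
    return fixture("fma_scheme")


# -- oracles -------------------------------------------------------------------


def brute_closure_pairs(pairs):
    """Naive fixpoint transitive closure over ordered pairs."""
    closed = set(pairs)
    changed = True
    while changed:
        changed = False
        for (a, b) in list(closed):
            for (c, d) in list(closed):
                if b == c and (a, d) not in closed:
                    closed.add((a, d))
                    changed = True
    return closed


def brute_reduction_pairs(pairs):
    """Covering pairs of an acyclic closed pair set: pairs not implied by a
    two-step path through the closure."""
    closed = brute_closure_pairs(pairs)
    return {
        (a, b)
        for (a, b) in closed
        if not any((a, m) in closed and (m, b) in closed for m in
                   {x for pair in closed for x in pair} - {a, b})
    }


def brute_is_acyclic(pairs):
    closed = brute_closure_pairs(pairs)
    return not any(a == b for (a, b) in closed)


def brute_cuts(tree):
    """Cut enumeration via root-to-leaf paths: the cut at depth d picks, on
    every path, the node at depth d, or the leaf if the path is shorter."""
    paths = []

    def walk(node, path):
        path = path + [node]
        kids = tree.children.get(node, ())
        if not kids:
            paths.append(path)
        for kid in kids:
            walk(kid, path)

    walk(tree.root, [])
    cuts = []
    for d in range(tree.depth, 0, -1):
        cut = set()
        for path in paths:
            cut.add(path[d - 1] if len(path) >= d else path[-1])
        cuts.append(frozenset(cut))
    return cuts  # index 0 = finest


def edge_pairs(edges):
    return {(e.child, e.parent) for e in edges}


def make_edges(pairs):
    return {ParthoodEdge(a, b) for (a, b) in pairs}
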