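"""Independent oracles used by the phylogeny tests.

Tree topologies are enumerated exhaustively and scored by ordinary
least squares on path lengths; none of this code shares anything with
the package's neighbor-joining implementation.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_unrooted_trees(taxa: list[str]) -> list[list[tuple[str, str]]]:
    """All unrooted binary tree topologies as edge lists.

    Internal nodes are named ``i0, i1, ...``; built by sequentially
    attaching each taxon to every existing edge.
    """
    assert len(taxa) >= 3
    base = [("i0", taxa[0]), ("i0", taxa[1]), ("i0", taxa[2])]
    trees = [base]
    counter = 1
    for leaf in taxa[3:]:
        new_trees = []
        for tree in trees:
            for k, (u, v) in enumerate(tree):
                node = f"i{counter}"
                t2 = tree[:k] + tree[k + 1:]
                t2 += [(u, node), (node, v), (node, leaf)]
                new_trees.append(t2)
        counter += 1
        trees = new_trees
    return trees


def _paths(tree: list[tuple[str, str]], taxa: list[str]) -> dict:
    adj: dict[str, list[str]] = {}
    for u, v in tree:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def path(a: str, b: str) -> list[tuple[str, str]]:
        stack = [(a, [a])]
        seen = {a}
        while stack:
            node, p = stack.pop()
            if node == b:
                return list(zip(p, p[1:]))
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append((nb, p + [nb]))
        raise AssertionError("disconnected tree")

    return {(a, b): path(a, b) for a, b in itertools.combinations(taxa, 2)}


def ls_fit_residual(tree: list[tuple[str, str]], taxa: list[str],
                    d: np.ndarray) -> float:
    """Least-squares residual of fitting branch lengths to distances."""
    edges = sorted(tuple(sorted(e)) for e in tree)
    index = {e: k for k, e in enumerate(edges)}
    pairs = list(itertools.combinations(range(len(taxa)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    paths = _paths(tree, taxa)
    for r, (i, j) in enumerate(pairs):
        for e in paths[(taxa[i], taxa[j])]:
            A[r, index[tuple(sorted(e))]] = 1.0
        y[r] = d[i, j]
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.sum((A @ coef - y) ** 2))


def best_topology_by_ls(taxa: list[str], d: np.ndarray
                        ) -> frozenset[frozenset[str]]:
    """Splits of the topology with minimal least-squares residual."""
    best = min(enumerate_unrooted_trees(taxa),
               key=lambda t: ls_fit_residual(t, taxa, d))
    return tree_splits(best, taxa)


def tree_splits(tree: list[tuple[str, str]], taxa: list[str]
                ) -> frozenset[frozenset[str]]:
    """Non-trivial splits, each normalised to its lexicographic side."""
    adj: dict[str, list[str]] = {}
    for u, v in tree:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    out = set()
    for u, v in tree:
        # leaves on v's side when edge (u, v) is removed
        stack, seen = [v], {u, v}
        side = set()
        while stack:
            node = stack.pop()
            if node in taxa:
                side.add(node)
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if 1 < len(side) < len(taxa) - 1:
            comp = frozenset(set(taxa) - side)
            out.add(min(frozenset(side), comp, key=lambda s: sorted(s)))
    return frozenset(out)


def random_additive_tree(taxa: list[str], rng: np.random.Generator
                         ) -> tuple[list[tuple[str, str]], dict, np.ndarray]:
    """A random topology with random branch lengths and its distances."""
    trees = enumerate_unrooted_trees(taxa)
    tree = trees[rng.integers(len(trees))]
    lengths = {tuple(sorted(e)): float(rng.uniform(0.1, 1.0)) for e in tree}
    paths = _paths(tree, taxa)
    n = len(taxa)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        w = sum(lengths[tuple(sorted(e))] for e in paths[(taxa[i], taxa[j])])
        d[i, j] = d[j, i] = w
    return tree, lengths, d


def phylo_tree_splits(tree, taxa: list[str]) -> frozenset[frozenset[str]]:
    """Non-trivial splits of a package PhyloTree, same normalisation."""
    out = set()
    for side, _node in tree.bipartitions():
        side = frozenset(side)
        if 1 < len(side) < len(taxa) - 1:
            comp = frozenset(set(taxa) - side)
            out.add(min(side, comp, key=lambda s: sorted(s)))
    return frozenset(out)
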