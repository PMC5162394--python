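"""Shared fixtures and independent oracle helpers.

The oracles here deliberately avoid the package's own code paths: brute-force
Python loops for site classification, an exhaustive re-statement of the
identification rules, a graph-based (networkx) monophyly check, and random
additive distance matrices built from explicitly constructed trees.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest

from barcodegap.alignment import AlignedMatrix, SequenceRecord


def make_matrix(rows: list[tuple[str, str, str]], region: str = "other") -> AlignedMatrix:
    """Build a matrix from (id, species, residues) triples."""
    return AlignedMatrix(
        [SequenceRecord(rid, sp, seq, region) for rid, sp, seq in rows], region=region
    )


@pytest.fixture
def toy_matrix() -> AlignedMatrix:
    return make_matrix(
        [
            ("s1_a_1", "s1_a", "ACGTACGT"),
            ("s1_a_2", "s1_a", "ACGTACGA"),
            ("s2_b_1", "s2_b", "ACTTTCGA"),
        ]
    )


# -- brute-force K2P oracle ----------------------------------------------------

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def brute_force_site_classes(a: str, b: str) -> tuple[int, int, int]:
    """Column-by-column loop: compared / transition / transversion counts."""
    n = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x != y:
            if frozenset((x, y)) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    return n, ts, tv


def brute_force_k2p(a: str, b: str) -> float:
    n, ts, tv = brute_force_site_classes(a, b)
    if n == 0:
        return math.nan
    P, Q = ts / n, tv / n
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def random_seq(rng: np.random.Generator, length: int, gap_rate: float = 0.0) -> str:
    chars = rng.choice(list("ACGT"), size=length)
    if gap_rate:
        gaps = rng.random(length) < gap_rate
        chars[gaps] = "-"
    return "".join(chars)


# -- brute-force identification oracle ----------------------------------------


def oracle_bm(qi: int, d: np.ndarray, species: list[str], tol: float = 1e-10) -> str:
    """Nearest-neighbour rule, restated from first principles."""
    others = [j for j in range(len(species)) if j != qi and not math.isnan(d[qi, j])]
    best = min(d[qi, j] for j in others)
    tied = {species[j] for j in others if d[qi, j] <= best + tol}
    if tied == {species[qi]}:
        return "correct"
    if species[qi] in tied:
        return "ambiguous"
    return "incorrect"


def oracle_bcm(
    qi: int, d: np.ndarray, species: list[str], threshold: float, tol: float = 1e-10
) -> str:
    others = [
        j
        for j in range(len(species))
        if j != qi and not math.isnan(d[qi, j]) and d[qi, j] <= threshold + tol
    ]
    if not others:
        return "no_match"
    best = min(d[qi, j] for j in others)
    tied = {species[j] for j in others if d[qi, j] <= best + tol}
    if tied == {species[qi]}:
        return "correct"
    if species[qi] in tied:
        return "ambiguous"
    return "incorrect"


def oracle_asb(qi: int, d: np.ndarray, species: list[str], tol: float = 1e-10) -> str:
    cons = [j for j in range(len(species))
            if j != qi and species[j] == species[qi] and not math.isnan(d[qi, j])]
    allo = [j for j in range(len(species))
            if species[j] != species[qi] and not math.isnan(d[qi, j])]
    if not allo:
        return "correct" if cons else "incorrect"
    da = min(d[qi, j] for j in allo)
    if not cons:
        return "incorrect"
    dc = max(d[qi, j] for j in cons)
    if dc < da - tol:
        return "correct"
    if dc <= da + tol:
        return "ambiguous"
    return "incorrect"


# -- random additive trees -----------------------------------------------------


def random_additive_tree(
    n_tips: int, rng: np.random.Generator
) -> tuple[list[str], np.ndarray, set[frozenset[str]]]:
    """Random binary unrooted tree with positive branch lengths.

    Returns tip labels, the additive tip-tip distance matrix, and the set of
    non-trivial bipartitions (each normalised as the side excluding the
    lexicographically smallest tip).
    """
    labels = [f"t{i}" for i in range(n_tips)]
    g = nx.Graph()
    nodes = list(labels)
    nxt = 0
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]  # pop higher index first
        internal = f"i{nxt}"
        nxt += 1
        g.add_edge(a, internal, length=float(rng.uniform(0.05, 1.0)))
        g.add_edge(b, internal, length=float(rng.uniform(0.05, 1.0)))
        nodes.remove(a)
        nodes.remove(b)
        nodes.append(internal)
    center = f"i{nxt}"
    for node in nodes:
        g.add_edge(node, center, length=float(rng.uniform(0.05, 1.0)))

    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    d = np.zeros((n_tips, n_tips))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            d[i, j] = dist[a][b]

    tips = frozenset(labels)
    ref = min(tips)
    splits: set[frozenset[str]] = set()
    for u, v in g.edges:
        h = g.copy()
        h.remove_edge(u, v)
        comp = nx.node_connected_component(h, u)
        side = frozenset(t for t in comp if t in tips)
        if ref in side:
            side = tips - side
        if 2 <= len(side) <= n_tips - 2:
            splits.add(side)
    return labels, d, splits


def _spanning_edges(tree_graph: nx.Graph, tips: list[str]) -> set[frozenset[str]]:
    edges: set[frozenset[str]] = set()
    for i in range(len(tips)):
        for j in range(i + 1, len(tips)):
            path = nx.shortest_path(tree_graph, tips[i], tips[j])
            edges.update(frozenset(e) for e in zip(path, path[1:]))
    return edges


def spanning_subtree_is_exclusive(
    tree_graph: nx.Graph, tips: set[str], all_tips: set[str]
) -> bool:
    """Monophyly oracle: a tip set forms one side of an edge bipartition iff
    its minimal spanning subtree shares no edge with the spanning subtree of
    the remaining tips."""
    inside = _spanning_edges(tree_graph, sorted(tips))
    outside = _spanning_edges(tree_graph, sorted(all_tips - set(tips)))
    return not (inside & outside)
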