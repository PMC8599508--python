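"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the rerooting oracle uses
dendropy's own rerooting, the chi-square oracle recomputes heterogeneity from
raw strings with plain Python, and the parsimony oracle enumerates internal
state assignments exhaustively.
"""

import itertools
import random
from collections import Counter

import dendropy


def rerooting_sister_pairs(newick: str) -> set:
    """All sister pairs observable by rooting the tree on every edge.

    Returns a set of frozenset({side_a, side_b}) leaf-set pairs, excluding the
    root pair whose union is the full leaf set.
    """
    base = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    all_leaves = frozenset(l.taxon.label for l in base.leaf_node_iter())
    n_edges = len(base.edges())
    pairs = set()
    for i in range(n_edges):
        t = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        edge = list(t.preorder_edge_iter())[i]
        if edge.tail_node is not None:
            t.reroot_at_edge(edge, update_bipartitions=False)
        for node in t.preorder_node_iter():
            kids = node.child_nodes()
            for a, b in itertools.combinations(kids, 2):
                sa = frozenset(l.taxon.label for l in a.leaf_iter())
                sb = frozenset(l.taxon.label for l in b.leaf_iter())
                if sa | sb != all_leaves:
                    pairs.add(frozenset((sa, sb)))
    return pairs


def random_binary_newick(n_leaves: int, seed: int, prefix: str = "L") -> str:
    """Random binary tree over n labelled leaves, by random pairwise merging."""
    rng = random.Random(seed)
    units = [f"{prefix}{i}" for i in range(1, n_leaves + 1)]
    while len(units) > 1:
        i, j = sorted(rng.sample(range(len(units)), 2))
        b = units.pop(j)
        a = units.pop(i)
        units.append(f"({a},{b})")
    return units[0] + ";"


def chi2_total_oracle(rows: dict) -> float:
    """Total compositional chi-square from raw row strings, pure Python."""
    counts = {t: Counter(c for c in row if c not in "-X") for t, row in rows.items()}
    global_counts = Counter()
    for c in counts.values():
        global_counts.update(c)
    total = sum(global_counts.values())
    x2 = 0.0
    for t, c in counts.items():
        n_t = sum(c.values())
        for state, g in global_counts.items():
            expected = n_t * g / total
            if expected > 0:
                x2 += (c.get(state, 0) - expected) ** 2 / expected
    return x2


def chi2_scores_oracle(rows: dict) -> list:
    """score(i) = X2(full) - X2(without site i), by full recomputation."""
    L = len(next(iter(rows.values())))
    full = chi2_total_oracle(rows)
    scores = []
    for i in range(L):
        reduced = {t: row[:i] + row[i + 1:] for t, row in rows.items()}
        scores.append(full - chi2_total_oracle(reduced))
    return scores


def fitch_steps_oracle(tree, column: dict) -> int:
    """Minimum number of state changes on the tree explaining the column,
    by exhaustive enumeration of internal-node state assignments.

    ``tree`` is a GeneTree; ``column`` maps leaf label -> residue ('-'/'X'
    entries place no constraint and are dropped). Only observed states need
    be considered for the optimum.
    """
    observed = sorted({c for c in column.values() if c not in "-X"})
    if len(observed) <= 1:
        return 0
    internals = tree.internal_nodes()
    edges = set()
    for n in tree.nodes():
        for nb in tree.neighbors(n):
            edges.add((min(n, nb), max(n, nb)))
    best = None
    for assignment in itertools.product(observed, repeat=len(internals)):
        states = dict(zip(internals, assignment))
        for n in tree.nodes():
            lbl = tree.label(n)
            if lbl is not None:
                states[n] = column.get(lbl, "-")
        cost = 0
        for u, v in edges:
            su, sv = states[u], states[v]
            if su in "-X" or sv in "-X":
                continue
            if su != sv:
                cost += 1
        if best is None or cost < best:
            best = cost
    return best
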