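"""Independent oracles shared by the unit and acceptance suites.

These deliberately avoid the package's own recurrences: parsimony scores
come from exhaustive enumeration of ancestral assignments, and random
instances are built directly from the tree simulator.
"""

import itertools

from mtphylo.alignment import Alignment
from mtphylo.synthdata import simulate_tree

STATES = "ACGT-"


def exhaustive_parsimony(tree, leaf_sets):
    """Minimum changes over all ancestral assignments, one column.

    Enumerates every assignment of the five states to every internal
    node; a leaf edge costs nothing when the parent state belongs to the
    leaf's observed set.
    """
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    edges = [(n.parent_node, n) for n in tree.preorder_node_iter()
             if n.parent_node is not None]
    best = None
    for assign in itertools.product(STATES, repeat=len(internals)):
        states = {id(n): s for n, s in zip(internals, assign)}
        cost = 0
        for parent, child in edges:
            p = states[id(parent)]
            if child.is_leaf():
                cost += p not in leaf_sets[child.taxon.label]
            else:
                cost += p != states[id(child)]
        best = cost if best is None else min(best, cost)
    return best


def random_instance(rng, max_leaves=6, max_cols=8, alphabet="ACGT-RYN"):
    """A random rooted tree plus random leaf rows over a small alphabet."""
    n = int(rng.integers(3, max_leaves + 1))
    tree = simulate_tree(n, rng)
    ncols = int(rng.integers(1, max_cols + 1))
    rows = {lf.taxon.label: "".join(rng.choice(list(alphabet), ncols))
            for lf in tree.leaf_node_iter()}
    return tree, Alignment(list(rows), rows)
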