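"""Desk-scale tree inference: neighbor joining, bootstrap, consensus,
outgroup rooting, and an adapter for external maximum-likelihood engines.

Internal inference is neighbor joining - deterministic, fast, and exact
on additive distance matrices - while production-size maximum-likelihood
runs are delegated to an external engine through a subprocess adapter.
Consensus, rooting and all downstream annotation are engine-agnostic.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence as Seq

import dendropy
import numpy as np

from .alignment import Alignment
from .pairwise import DistanceMatrix

__all__ = [
    "neighbor_joining",
    "bootstrap_replicates",
    "majority_consensus",
    "root_by_outgroup",
    "ExternalMLConfig",
    "run_external_ml",
]


def _new_tree(taxa: Iterable[str]) -> tuple[dendropy.Tree, dict]:
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = {}
    for label in taxa:
        node = dendropy.Node()
        node.taxon = ns.new_taxon(label)
        nodes[label] = node
    return tree, nodes


def neighbor_joining(matrix: DistanceMatrix) -> dendropy.Tree:
    """Classic Saitou-Nei neighbor joining.

    Produces an unrooted binary tree; on an additive matrix the
    path-length distances between leaves reproduce the input exactly.
    Ties in the Q criterion break deterministically toward the
    lexicographically smallest label pair.  Negative branch lengths are
    clamped to zero.
    """
    n = len(matrix.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    d = matrix.values.astype(float).copy()
    tree, leaf_nodes = _new_tree(matrix.ids)
    active: list[str] = list(matrix.ids)
    nodes: dict[str, dendropy.Node] = dict(leaf_nodes)
    labels = {i: matrix.ids[i] for i in range(n)}
    idx = list(range(n))

    while len(idx) > 2:
        m = len(idx)
        sums = d[np.ix_(idx, idx)].sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * d[idx[a], idx[b]] - sums[a] - sums[b]
                key = (q, tuple(sorted((labels[idx[a]], labels[idx[b]]))))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        ia, ib = idx[a], idx[b]
        dij = d[ia, ib]
        la = 0.5 * dij + (sums[a] - sums[b]) / (2 * (m - 2))
        lb = dij - la
        parent = dendropy.Node()
        na, nb = nodes[labels[ia]], nodes[labels[ib]]
        parent.add_child(na)
        parent.add_child(nb)
        na.edge.length = max(la, 0.0)
        nb.edge.length = max(lb, 0.0)
        new_label = f"({labels[ia]},{labels[ib]})"
        nodes[new_label] = parent
        # distances from the new node to the remaining taxa
        rest = [x for x in idx if x not in (ia, ib)]
        newdist = 0.5 * (d[ia, rest] + d[ib, rest] - dij)
        d[ia, rest] = newdist
        d[rest, ia] = newdist
        labels[ia] = new_label
        idx = [x for x in idx if x != ib]

    # connect the last two by a single edge (standard unrooted form:
    # the internal survivor becomes the trifurcating seed)
    ia, ib = idx
    na, nb = nodes[labels[ia]], nodes[labels[ib]]
    seed, other = (na, nb) if not na.is_leaf() else (nb, na)
    seed.add_child(other)
    other.edge.length = max(d[ia, ib], 0.0)
    tree.seed_node = seed
    tree.is_rooted = False
    return tree


def bootstrap_replicates(alignment: Alignment, n: int,
                         seed: int) -> list[Alignment]:
    """``n`` column-resampled replicates of an alignment.

    Columns are drawn uniformly with replacement; a fixed seed
    reproduces the exact replicate set.
    """
    if n < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    m = alignment.ncols
    return [alignment.take_columns(rng.integers(0, m, size=m))
            for _ in range(n)]


def _clades(tree: dendropy.Tree, anchor: str) -> set[frozenset[str]]:
    """Leaf-set of each internal edge, normalized away from ``anchor``."""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = frozenset(leaves - side)
        if 0 < len(side) < len(leaves):
            out.add(side)
    return out


def majority_consensus(trees: Seq[dendropy.Tree],
                       threshold: float = 0.5) -> dendropy.Tree:
    """Majority-rule consensus with per-clade support.

    Retains every bipartition whose frequency across the input trees
    strictly exceeds ``threshold`` (0.5 <= threshold < 1 guarantees
    pairwise compatibility); support values are the exact frequencies.
    Unresolved regions collapse to polytomies.  Each node's support is
    stored in ``node.support`` and mirrored in its label.
    """
    if not 0.5 <= threshold < 1:
        raise ValueError("threshold must lie in [0.5, 1)")
    trees = list(trees)
    if not trees:
        raise ValueError("no input trees")
    leafsets = [frozenset(lf.taxon.label for lf in t.leaf_node_iter())
                for t in trees]
    if len(set(leafsets)) != 1:
        raise ValueError("input trees have mismatched leaf sets")
    leaves = sorted(leafsets[0])
    anchor = leaves[0]
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for clade in _clades(t, anchor):
            counts[clade] = counts.get(clade, 0) + 1
    total = len(trees)
    retained = {c: cnt / total for c, cnt in counts.items()
                if cnt / total > threshold and 1 < len(c) < len(leaves) - 1}

    # nest retained clades by containment (they are pairwise compatible)
    tree, leaf_nodes = _new_tree(leaves)
    root = dendropy.Node()
    tree.seed_node = root
    tree.is_rooted = False
    clade_nodes: list[tuple[frozenset[str], dendropy.Node]] = []
    for clade in sorted(retained, key=len):
        node = dendropy.Node()
        node.support = retained[clade]
        node.label = f"{retained[clade]:.2f}"
        clade_nodes.append((clade, node))

    def smallest_container(member_set: frozenset[str],
                           proper: bool) -> dendropy.Node:
        best = None
        for other, other_node in clade_nodes:
            contained = member_set < other if proper else member_set <= other
            if contained and member_set != other and (
                    best is None or len(other) < len(best[0])):
                best = (other, other_node)
        return best[1] if best else root

    for clade, node in sorted(clade_nodes, key=lambda p: -len(p[0])):
        smallest_container(clade, proper=True).add_child(node)
    for lf in leaves:
        smallest_container(frozenset([lf]), proper=False).add_child(
            leaf_nodes[lf])
    return tree


def root_by_outgroup(tree: dendropy.Tree,
                     outgroup_ids: Iterable[str]) -> dendropy.Tree:
    """Root a tree on the edge separating the outgroup from everything else.

    The outgroup must form one side of a bipartition of the unrooted
    tree; otherwise the offending (minimal conflicting) split is
    reported.
    """
    out = set(outgroup_ids)
    tree = tree.clone(depth=1)
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = out - leaves
    if missing:
        raise ValueError(f"outgroup ids not in tree: {sorted(missing)}")
    target = None
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if side == out or side == leaves - out:
            target = node
            break
    if target is None:
        best = None
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            side = {lf.taxon.label for lf in node.leaf_iter()}
            if side & out and side - out:
                if best is None or len(side) < len(best):
                    best = side
        raise ValueError(
            f"outgroup {sorted(out)} is not monophyletic; minimal conflicting "
            f"split: {sorted(best) if best else '?'}")
    length = target.edge.length or 0.0
    tree.reroot_at_edge(target.edge, length1=length / 2, length2=length / 2,
                        update_bipartitions=False)
    tree.is_rooted = True
    return tree


@dataclass(frozen=True)
class ExternalMLConfig:
    """How to invoke an external maximum-likelihood engine.

    ``command`` is a template list; ``{fasta}`` is replaced by the input
    alignment path.  The engine must print newick on stdout (the default
    works for fasttree-style tools) or write it to ``{tree}``.
    """

    command: tuple[str, ...] = ("fasttree", "-nt", "-quiet", "{fasta}")
    reads_stdout: bool = True


def run_external_ml(alignment: Alignment,
                    config: ExternalMLConfig = ExternalMLConfig()
                    ) -> dendropy.Tree:
    """Adapter: write FASTA, invoke the engine, parse its newick output."""
    exe = shutil.which(config.command[0])
    if exe is None:
        raise RuntimeError(
            f"external ML engine {config.command[0]!r} not found; use "
            "neighbor_joining() for a self-contained reconstruction")
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "aln.fasta"
        treefile = Path(tmp) / "out.nwk"
        alignment.write_fasta(fasta)
        cmd = [c.format(fasta=fasta, tree=treefile) for c in config.command]
        res = subprocess.run(cmd, capture_output=True, text=True, check=True)
        newick = res.stdout if config.reads_stdout else treefile.read_text()
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    got = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if got != set(alignment.ids):
        raise RuntimeError("external engine changed the leaf set")
    return tree
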