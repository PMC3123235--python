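"""Parsimony annotation of a phylogeny and tree-level statistics.

Ancestral states are inferred by generalized Fitch parsimony over the
five-state alphabet {A,C,G,T,-}: the gap is a first-class state, so each
alignment column is treated independently and indels are *not* unified
into single events.  IUPAC ambiguity codes at the leaves enter as state
subsets (N as all four bases), which resolves ambiguity implicitly: a
leaf whose set contains the parent state generates no event, so the
effects of ambiguity stay local and close to the leaves.  Gap padding of
unsequenced regions (flexible sequences) expands to the full state set
and therefore never generates events at all.

Branch events are classified against a conservation profile (dominant
fraction alpha per column) and the mutational history itself
(back-mutations restore a state an earlier event on the same
root-to-leaf path had replaced).  Cross-tabulated counts, per-branch
histograms, generation points and the perfect-phylogeny lower bound
quantify tree quality and localize suspect data.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import dendropy
import numpy as np

from .alignment import Alignment
from .sequences import iupac_set

__all__ = [
    "ConservationProfile",
    "conservation_profile",
    "AncestralLabeling",
    "fitch_label",
    "MutationEvent",
    "extract_events",
    "flag_events",
    "CrossTab",
    "crosstab",
    "BranchStats",
    "branch_stats",
    "generation_points",
    "perfect_phylogeny_bound",
    "Rates",
    "summary_rates",
    "ensure_node_names",
]

_STATE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8, "-": 16}
_BIT_STATE = {v: k for k, v in _STATE_BIT.items()}
FULL_SET = 31  # all five states; used for unsequenced padding


def _leaf_mask(symbol: str) -> int:
    return sum(_STATE_BIT[b] for b in iupac_set(symbol))


_MASK_LUT = np.zeros(128, dtype=np.uint8)
for _c in "ACGTRYSWKMBDHVN-":
    _MASK_LUT[ord(_c)] = _leaf_mask(_c)


def _lowest_bit(masks: np.ndarray) -> np.ndarray:
    """Lowest set bit per entry = deterministic pick in order A<C<G<T<'-'."""
    return masks & (~masks + 1)


# --------------------------------------------------------------------------
# conservation

@dataclass
class ConservationProfile:
    """Per-column dominant fraction alpha and its summary.

    alpha is the frequency of the most common unambiguous, non-gap
    residue among the rows that carry one (the "effective depth");
    columns with zero effective depth have undefined alpha (NaN).
    """

    alpha: np.ndarray
    dominant: np.ndarray
    effective_depth: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return self.effective_depth > 0

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.alpha))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.alpha))

    def fraction_below(self, threshold: float) -> float:
        d = self.defined
        return float((self.alpha[d] < threshold).sum() / max(d.sum(), 1))


def conservation_profile(alignment: Alignment,
                         count_all_rows: bool = False) -> ConservationProfile:
    """Column-wise conservation of an alignment.

    By default gaps and ambiguity codes are excluded from the
    denominator so that alpha reflects true polymorphic variation;
    ``count_all_rows`` switches to a raw row count denominator.
    """
    if alignment.nrows < 2:
        raise ValueError("conservation needs at least two rows")
    mat = alignment.matrix()
    ncols = mat.shape[1]
    counts = np.stack([(mat == b).sum(axis=0) for b in "ACGT"])
    depth = counts.sum(axis=0)
    top = counts.max(axis=0)
    denom = np.full(ncols, alignment.nrows) if count_all_rows else depth
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(denom > 0, top / np.where(denom > 0, denom, 1), np.nan)
    dominant = np.array(list("ACGT"))[counts.argmax(axis=0)]
    dominant[depth == 0] = "?"
    return ConservationProfile(alpha, dominant, depth)


# --------------------------------------------------------------------------
# Fitch labeling

def ensure_node_names(tree: dendropy.Tree) -> None:
    """Give every node a stable, unique name (leaves keep taxon labels)."""
    taken = {lf.taxon.label for lf in tree.leaf_node_iter()}
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.name = node.taxon.label
        else:
            label = getattr(node, "name", None) or node.label
            if not label or label in taken:
                while f"node{k}" in taken:
                    k += 1
                label = f"node{k}"
            node.name = label
            node.label = label  # serialized as the internal newick label
            taken.add(label)


@dataclass
class AncestralLabeling:
    """Fitch state sets and resolved states for every node.

    ``state_sets`` holds the bottom-up candidate masks; ``resolved``
    holds one symbol per node and column - a concrete state from
    {A,C,G,T,-} at internal nodes, the observed (possibly ambiguous)
    symbol at leaves.  ``score_per_column`` sums to the parsimony score.
    """

    state_sets: dict[str, np.ndarray]
    resolved: dict[str, np.ndarray]
    score_per_column: np.ndarray
    root_name: str
    leaf_names: frozenset[str]

    @property
    def score(self) -> int:
        return int(self.score_per_column.sum())


def fitch_label(tree: dendropy.Tree, alignment: Alignment) -> AncestralLabeling:
    """Generalized Fitch parsimony labeling of a rooted tree.

    Bottom-up, per column: a node's candidate set is the intersection of
    its children's sets when non-empty, else their union at the cost of
    one change (children folded pairwise in order, which is exact on
    binary trees).  Top-down: the root resolves to the first member of
    its set in the order A<C<G<T<'-'; every other internal node inherits
    its parent's state when possible, else takes the first member of its
    own set.  Leaves retain their observed symbols; IUPAC codes expand
    to state subsets, ``N`` to all four bases, and unsequenced padding
    to the full five-state set.
    """
    ensure_node_names(tree)
    leaf_names = {lf.name for lf in tree.leaf_node_iter()}
    missing = leaf_names - set(alignment.ids)
    if missing:
        raise ValueError(f"leaves missing from alignment: {sorted(missing)}")
    ncols = alignment.ncols

    masks: dict[str, np.ndarray] = {}
    score = np.zeros(ncols, dtype=int)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            row = alignment.rows[node.name]
            m = _MASK_LUT[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]
            if (m == 0).any():
                j = int(np.argmax(m == 0))
                raise ValueError(f"{node.name}: bad symbol {row[j]!r} "
                                 f"in column {j}")
            um = alignment.unsequenced.get(node.name)
            if um is not None:
                m = np.where(um, FULL_SET, m)
            masks[node.name] = m.astype(np.uint8)
        else:
            children = node.child_nodes()
            cur = masks[children[0].name].copy()
            for child in children[1:]:
                inter = cur & masks[child.name]
                disjoint = inter == 0
                score += disjoint
                cur = np.where(disjoint, cur | masks[child.name], inter)
            masks[node.name] = cur.astype(np.uint8)

    resolved: dict[str, np.ndarray] = {}
    bit_to_char = np.empty(32, dtype="U1")
    for b, c in _BIT_STATE.items():
        bit_to_char[b] = c
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            resolved[node.name] = np.array(list(alignment.rows[node.name]),
                                           dtype="U1")
            continue
        m = masks[node.name]
        if node.parent_node is None:
            bits = _lowest_bit(m)
        else:
            pbits = _parent_bits(resolved[node.parent_node.name])
            inherit = (m & pbits) != 0
            bits = np.where(inherit, pbits, _lowest_bit(m))
        resolved[node.name] = bit_to_char[bits]
    return AncestralLabeling(masks, resolved, score, tree.seed_node.name,
                             frozenset(leaf_names))


def _parent_bits(chars: np.ndarray) -> np.ndarray:
    codes = chars.astype("U1").view(np.uint32).astype(np.uint8)
    return _MASK_LUT[codes].astype(np.uint16)


# --------------------------------------------------------------------------
# events

@dataclass
class MutationEvent:
    """One state change hypothesized on one branch at one column."""

    parent: str
    child: str
    column: int
    ref_position: Optional[int]
    from_state: str
    to_state: str
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.from_state == self.to_state:
            raise ValueError("from_state and to_state must differ")

    @property
    def is_indel(self) -> bool:
        return "-" in (self.from_state, self.to_state)

    @property
    def is_ambiguous(self) -> bool:
        return any(s not in "ACGT-" for s in (self.from_state, self.to_state))

    def as_record(self) -> dict:
        return {"parent": self.parent, "child": self.child,
                "column": self.column, "ref_position": self.ref_position,
                "from_state": self.from_state, "to_state": self.to_state,
                "flags": sorted(self.flags)}


def extract_events(labeling: AncestralLabeling,
                   tree: dendropy.Tree) -> list[MutationEvent]:
    """One event per branch and column where resolved states differ.

    On a pendant branch the change criterion is set-based: the leaf
    generates an event only when the parent's state is incompatible with
    its observed symbol, so an ``N`` or a compatible ambiguity code never
    creates an event; when it does, the recorded ``to_state`` is the
    observed (possibly ambiguous) symbol itself.
    """
    events: list[MutationEvent] = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        pres = labeling.resolved[node.parent_node.name]
        if node.is_leaf():
            changed = (_parent_bits(pres) & labeling.state_sets[node.name]) == 0
        else:
            changed = pres != labeling.resolved[node.name]
        cres = labeling.resolved[node.name]
        for j in np.flatnonzero(changed):
            events.append(MutationEvent(
                node.parent_node.name, node.name, int(j), None,
                str(pres[j]), str(cres[j])))
    return events


def flag_events(events: Iterable[MutationEvent], tree: dendropy.Tree,
                profile: Optional[ConservationProfile],
                alpha_threshold: float = 0.95,
                back_mutation_scope: str = "path",
                colmap: Optional[list] = None) -> list[MutationEvent]:
    """Attach classification flags to extracted events.

    conserved: the column's alpha exceeds ``alpha_threshold``.
    back_mutation: an earlier event on the root path at the same column
    replaced exactly the state this event restores (``scope='path'``),
    or - stricter - the event restores the root state (``scope='root'``).
    ambiguous / indel follow directly from the event's states.  Events
    are flagged in place and returned as a list.
    """
    if back_mutation_scope not in ("path", "root"):
        raise ValueError("back_mutation_scope must be 'path' or 'root'")
    events = list(events)
    parents = {}
    for node in tree.preorder_node_iter():
        parents[node.name] = (node.parent_node.name if node.parent_node
                              else None)
    by_branch_col = {(e.child, e.column): e for e in events}
    root_name = tree.seed_node.name
    # resolved root states recovered from the event chain are not needed:
    # the first event's from_state on any path *is* the root state there.
    for e in events:
        if profile is not None and e.column < len(profile.alpha):
            a = profile.alpha[e.column]
            if np.isfinite(a) and a > alpha_threshold:
                e.flags.add("conserved")
        if e.is_indel:
            e.flags.add("indel")
        if e.is_ambiguous:
            e.flags.add("ambiguous")
        # walk ancestors of the event's branch
        chain: list[MutationEvent] = []
        node = e.parent
        while node is not None and node != root_name:
            prior = by_branch_col.get((node, e.column))
            if prior is not None:
                chain.append(prior)
            node = parents[node]
        if chain:
            if back_mutation_scope == "path":
                if any(prior.from_state == e.to_state for prior in chain):
                    e.flags.add("back_mutation")
            else:
                root_state = chain[-1].from_state
                if e.to_state == root_state:
                    e.flags.add("back_mutation")
        if colmap is not None and 0 <= e.column < len(colmap):
            e.ref_position = colmap[e.column]
    return events


# --------------------------------------------------------------------------
# statistics

_CT_COLS = ("conserved", "back_mutation", "conserved_and_back", "remaining",
            "total")


@dataclass
class CrossTab:
    """Mutation-type cross-tabulation.

    Rows: unambiguous events, their ungapped (indel-free) sub-row, and
    ambiguous events; ambiguous + unambiguous = total.  Columns:
    conserved, back-mutation, their intersection, and events that are
    neither; by inclusion-exclusion each row total equals conserved +
    back - both + remaining.
    """

    cells: dict[str, dict[str, int]]

    def row(self, name: str) -> dict[str, int]:
        return self.cells[name]

    def check_identities(self) -> None:
        for name, r in self.cells.items():
            lhs = (r["conserved"] + r["back_mutation"]
                   - r["conserved_and_back"] + r["remaining"])
            if lhs != r["total"]:
                raise AssertionError(f"inclusion-exclusion fails for {name}")
        t = self.cells
        for col in _CT_COLS:
            if t["unambiguous"][col] + t["ambiguous"][col] != t["total"][col]:
                raise AssertionError(f"row sums fail for column {col}")

    def to_dict(self) -> dict:
        return {r: dict(c) for r, c in self.cells.items()}


def _ct_row(evs: list[MutationEvent]) -> dict[str, int]:
    cons = sum(1 for e in evs if "conserved" in e.flags)
    back = sum(1 for e in evs if "back_mutation" in e.flags)
    both = sum(1 for e in evs
               if {"conserved", "back_mutation"} <= e.flags)
    rest = sum(1 for e in evs
               if not ({"conserved", "back_mutation"} & e.flags))
    return {"conserved": cons, "back_mutation": back,
            "conserved_and_back": both, "remaining": rest, "total": len(evs)}


def crosstab(events: Iterable[MutationEvent]) -> CrossTab:
    events = list(events)
    ambiguous = [e for e in events if "ambiguous" in e.flags]
    unambiguous = [e for e in events if "ambiguous" not in e.flags]
    ungapped = [e for e in unambiguous if "indel" not in e.flags]
    ct = CrossTab({
        "unambiguous": _ct_row(unambiguous),
        "ungapped": _ct_row(ungapped),
        "ambiguous": _ct_row(ambiguous),
        "total": _ct_row(events),
    })
    ct.check_identities()
    return ct


@dataclass
class BranchStats:
    """Per-branch event counts and tree-driven outlier flags."""

    counts: dict[tuple[str, str], int]
    outliers: set[tuple[str, str]]
    threshold: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def empty_fraction(self) -> float:
        return sum(1 for c in self.counts.values() if c == 0) / len(self.counts)

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.counts.values())))

    @property
    def sd(self) -> float:
        return float(np.std(list(self.counts.values())))

    def histogram(self) -> Counter:
        return Counter(self.counts.values())


def branch_stats(events: Iterable[MutationEvent], tree: dendropy.Tree,
                 threshold: int = 50) -> BranchStats:
    """Events per branch; branches exceeding ``threshold`` events are
    flagged for review (legitimate evolution stays well below it)."""
    counts: dict[tuple[str, str], int] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            counts[(node.parent_node.name, node.name)] = 0
    for e in events:
        counts[(e.parent, e.child)] = counts.get((e.parent, e.child), 0) + 1
    outliers = {b for b, c in counts.items() if c > threshold}
    return BranchStats(counts, outliers, threshold)


def generation_points(events: Iterable[MutationEvent],
                      grouping: str = "by_position_and_states"
                      ) -> tuple[dict, Counter]:
    """Number of branches on which each mutation independently arises.

    ``by_position`` unifies mutation variants by alignment column;
    ``by_position_and_states`` distinguishes the (from, to) pair.  More
    than one generation point indicates homoplasy.  Returns the
    per-mutation counts and the frequency histogram of those counts.
    """
    if grouping not in ("by_position", "by_position_and_states"):
        raise ValueError(f"unknown grouping {grouping!r}")
    branches: dict[tuple, set] = {}
    for e in events:
        key = (e.column,) if grouping == "by_position" else (
            e.column, e.from_state, e.to_state)
        branches.setdefault(key, set()).add((e.parent, e.child))
    counts = {k: len(v) for k, v in branches.items()}
    return counts, Counter(counts.values())


def perfect_phylogeny_bound(alignment: Alignment) -> int:
    """Minimum events any tree could need, ambiguities suppressed.

    Per column, every occurring unambiguous symbol (gap included) beyond
    the first needs at least one generation point; summing (k - 1) over
    columns gives the perfect-phylogeny lower bound on the parsimony
    score.
    """
    mat = alignment.matrix()
    for sid, mask in alignment.unsequenced.items():
        mat[alignment.ids.index(sid), mask] = "?"  # suppressed like ambiguity
    total = 0
    for j in range(mat.shape[1]):
        symbols = {c for c in mat[:, j] if c in "ACGT-"}
        if symbols:
            total += len(symbols) - 1
    return total


@dataclass
class Rates:
    """Normalized mutation loads of an annotated tree."""

    per_leaf: float
    per_character: float
    per_branch_mean: float
    per_branch_sd: float
    empty_branch_fraction: float

    def report(self) -> dict[str, float]:
        return {k: round(v, 2) for k, v in self.__dict__.items()}


def summary_rates(total_events: int, n_leaves: int, n_columns: int,
                  branch_counts: Optional[Mapping] = None) -> Rates:
    if n_leaves <= 0 or n_columns <= 0:
        raise ValueError("leaf and column counts must be positive")
    if branch_counts:
        vals = np.array(list(branch_counts.values()), dtype=float)
        mean, sd = float(vals.mean()), float(vals.std())
        empty = float((vals == 0).sum() / len(vals))
    else:
        mean = sd = empty = 0.0
    return Rates(per_leaf=total_events / n_leaves,
                 per_character=total_events / n_columns,
                 per_branch_mean=mean, per_branch_sd=sd,
                 empty_branch_fraction=empty)
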