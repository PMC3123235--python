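"""Seeded generator of mtDNA-like datasets with full ground truth.

The generator emulates the structure the pipeline is built for, at desk
scale: a small circular-style reference (default 2 kb) with a control
region split in two by the numbering origin, six protein-coding genes
and two non-coding spacers; a known Yule phylogeny; per-branch
substitutions and unit-aware indels (codon-level in genes, short in
non-coding units), optionally with forced recurrent/reverting events;
and injected curation defects - start-point rotations, control-region
truncations, N-runs, exact duplicates, divergent outliers, overlong
intrusions and ambiguity excess - each recorded in an exact registry so
every pipeline stage can be scored against known truth.

Everything is driven by one ``numpy`` generator: a fixed seed gives
bit-identical sequences, trees and registries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np

from .alignment import Alignment
from .annotation import ReferenceAnnotation, StructuralUnit
from .curation import QcConfig
from .pairwise import rotate
from .sequences import Dataset, Sequence

__all__ = [
    "SynthSpec",
    "TrueEvent",
    "Defect",
    "GroundTruth",
    "simulate_tree",
    "make_annotation",
    "evolve_sequences",
    "inject_defects",
    "generate",
    "qc_config_for",
]

_AMBIG_CODES = "RYSWKM"


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for one synthetic dataset."""

    n_leaves: int = 30
    reference_length: int = 2000
    substitution_rate: float = 1.5   # Poisson mean per unit branch length
    indel_rate: float = 0.15
    branch_length_mean: float = 1.0
    allow_recurrent: bool = True
    force_revert: bool = False
    ambiguity_rate: float = 0.0      # per-position, per-leaf
    # defect counts
    n_rotations: int = 0
    rotation_offset: Optional[int] = None
    n_truncations: int = 0
    n_n_runs: int = 0
    n_run_length: int = 25
    n_duplicates: int = 0
    n_outliers: int = 0
    outlier_extra_subs: int = 60
    n_overlong: int = 0
    n_ambiguous: int = 0
    ambiguity_excess_count: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.indel_rate, self.ambiguity_rate):
            if r < 0:
                raise ValueError("rates must be nonnegative")
        counts = (self.n_rotations, self.n_truncations, self.n_n_runs,
                  self.n_duplicates, self.n_outliers, self.n_overlong,
                  self.n_ambiguous)
        if any(c < 0 for c in counts):
            raise ValueError("defect counts must be nonnegative")


@dataclass(frozen=True)
class TrueEvent:
    """One applied point event, in master-column coordinates."""

    parent: str
    child: str
    column: tuple[int, int]   # (reference position, insertion index)
    from_state: str
    to_state: str
    kind: str                 # substitution | deletion | insertion


@dataclass(frozen=True)
class Defect:
    kind: str
    params: dict


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    tree: dendropy.Tree
    events: list[TrueEvent]
    alignment: Alignment          # true leaf alignment, gap state included
    registry: dict[str, Defect] = field(default_factory=dict)
    annotation: Optional[ReferenceAnnotation] = None

    @property
    def n_point_events(self) -> int:
        return len(self.events)


def simulate_tree(n: int, seed_or_rng) -> dendropy.Tree:
    """Random rooted binary tree under a Yule (uniform split) process.

    Branch lengths are exponential; leaf labels are ``t01, t02, ...`` in
    a deterministic traversal order.
    """
    if n < 3:
        raise ValueError("need at least three leaves")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = True
    root = tree.seed_node
    leaves = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        leaves.append(child)
    while len(leaves) < n:
        pick = int(rng.integers(0, len(leaves)))
        node = leaves.pop(pick)
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            leaves.append(child)
    width = max(2, len(str(n)))
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            k += 1
            node.taxon = ns.new_taxon(f"t{k:0{width}d}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.exponential(1.0))
    return tree


def make_annotation(spec: SynthSpec, rng: np.random.Generator
                    ) -> ReferenceAnnotation:
    """A structurally mtDNA-like reference annotation at reduced scale.

    For the default 2000 bp length: two control-region parts flanking the
    ends (the split of one region by the numbering origin), six coding
    genes and two non-coding spacers in between.  Other lengths scale the
    same layout proportionally, keeping gene lengths divisible by three.
    """
    L = spec.reference_length
    if L < 400:
        raise ValueError("reference too short for the standard layout")
    residues = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=L)])
    ref = Sequence(id="synthref", residues=residues, species="synthetic")

    def scale(x: int) -> int:
        return int(round(x * L / 2000))

    cr1_end = scale(100)
    cr2_start = L - scale(120) + 1
    span = (cr1_end + 1, cr2_start - 1)
    # six genes, two spacers after genes 2 and 4
    units: list[StructuralUnit] = [
        StructuralUnit("control_region_1", "control_region_part", 1, cr1_end),
        StructuralUnit("control_region_2", "control_region_part", cr2_start, L),
    ]
    gap_len = max(scale(20), 4)
    coding_len = span[1] - span[0] + 1 - 2 * gap_len
    gene_len = (coding_len // 6) // 3 * 3
    pos = span[0]
    for g in range(1, 7):
        end = pos + gene_len - 1
        if g == 6:
            end = span[1]  # absorb rounding; trailing part acts as 3' UTR
        units.append(StructuralUnit(f"gene{g}", "gene", pos, end,
                                    coding=True, reading_frame_offset=0))
        pos = end + 1
        if g in (2, 4):
            units.append(StructuralUnit(f"nc_{g}", "noncoding_gap",
                                        pos, pos + gap_len - 1))
            pos += gap_len
    return ReferenceAnnotation(ref, units, circular=True)


def _unit_of(annotation: ReferenceAnnotation, pos: int) -> StructuralUnit:
    for u in annotation.units:
        if u.start <= pos <= u.end:
            return u
    raise ValueError(f"position {pos} outside annotation")


def evolve_sequences(tree: dendropy.Tree, annotation: ReferenceAnnotation,
                     spec: SynthSpec, rng: Optional[np.random.Generator] = None
                     ) -> tuple[Dataset, GroundTruth]:
    """Evolve the reference down the tree, recording every event.

    Substitution and indel counts per branch are Poisson in the branch
    length.  Indels respect unit structure: in coding genes they are
    codon-sized with high probability (frameshifts are rare), in
    non-coding units short and unconstrained.  With ``allow_recurrent``
    off, no alignment column is ever touched twice anywhere in the tree,
    so the parsimony score of the truth equals the event count; with
    ``force_revert`` on, one x->y / y->x pair is planted on a single
    root-to-leaf path and recorded.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    from .annotate import ensure_node_names
    ensure_node_names(tree)
    L = annotation.length
    ref = annotation.reference.residues
    bases = np.array(list("ACGT"))

    columns: list[tuple[int, int]] = [(p, 0) for p in range(1, L + 1)]
    ins_counter: dict[int, int] = {}
    chars: dict[str, dict[tuple[int, int], str]] = {}
    root = tree.seed_node
    chars[root.name] = {(p, 0): ref[p - 1] for p in range(1, L + 1)}
    events: list[TrueEvent] = []
    touched: set[tuple[int, int]] = set()

    def pick_sub_column(present: list[tuple[int, int]]) -> Optional[tuple[int, int]]:
        pool = present if spec.allow_recurrent else \
            [c for c in present if c not in touched]
        if not pool:
            return None
        return pool[int(rng.integers(0, len(pool)))]

    forced: Optional[dict] = None
    if spec.allow_recurrent and spec.force_revert:
        # choose a leaf at depth >= 2 and a column for the planted pair
        leaf = next(lf for lf in tree.leaf_node_iter()
                    if lf.parent_node.parent_node is not None)
        path = []
        node = leaf
        while node.parent_node is not None:
            path.append(node)
            node = node.parent_node
        path.reverse()  # root's child ... leaf
        col = (int(rng.integers(L // 4, 3 * L // 4)), 0)
        forced = {"column": col, "first": path[0].name, "second": path[-1].name}

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_chars = chars[node.parent_node.name]
        my = dict(parent_chars)
        edge_len = node.edge.length or 0.0
        n_sub = int(rng.poisson(spec.substitution_rate * edge_len))
        n_indel = int(rng.poisson(spec.indel_rate * edge_len))

        for _ in range(n_sub):
            present = sorted(my)
            col = pick_sub_column(present)
            if col is None:
                continue
            if forced and col == forced["column"]:
                continue  # reserved for the planted pair
            old = my[col]
            new = str(rng.choice(bases[bases != old]))
            my[col] = new
            touched.add(col)
            events.append(TrueEvent(node.parent_node.name, node.name, col,
                                    old, new, "substitution"))

        for _ in range(n_indel):
            insertion = bool(rng.integers(0, 2))
            pos = int(rng.integers(1, L + 1))
            unit = _unit_of(annotation, pos)
            if unit.coding:
                length = 3 if rng.random() < 0.85 else int(rng.integers(1, 3))
                if length == 3:  # align to a codon boundary
                    pos = unit.start + ((pos - unit.start) // 3) * 3
                    if pos + 2 > unit.end:
                        pos = unit.end - 2
            else:
                length = int(rng.integers(1, 5))
                pos = min(pos, unit.end - length + 1) if unit.end - length + 1 \
                    >= unit.start else unit.start
            if insertion:
                anchor = min(pos, L)
                new_cols = []
                for _k in range(length):
                    ins_counter[anchor] = ins_counter.get(anchor, 0) + 1
                    new_cols.append((anchor, ins_counter[anchor]))
                columns.extend(new_cols)
                for c in new_cols:
                    ch = str(rng.choice(bases))
                    my[c] = ch
                    touched.add(c)
                    events.append(TrueEvent(node.parent_node.name, node.name,
                                            c, "-", ch, "insertion"))
            else:
                run = [(p, 0) for p in range(pos, min(pos + length, L + 1))]
                run = [c for c in run if c in my and
                       (spec.allow_recurrent or c not in touched)]
                if forced:
                    run = [c for c in run if c != forced["column"]]
                for c in run:
                    events.append(TrueEvent(node.parent_node.name, node.name,
                                            c, my[c], "-", "deletion"))
                    del my[c]
                    touched.add(c)

        if forced:
            col = forced["column"]
            if node.name == forced["first"] and col in my:
                old = my[col]
                new = str(rng.choice(bases[bases != old]))
                my[col] = new
                forced["states"] = (old, new)
                events.append(TrueEvent(node.parent_node.name, node.name, col,
                                        old, new, "substitution"))
            elif node.name == forced["second"] and "states" in forced:
                old, new = forced["states"]
                if my.get(col) == new:
                    my[col] = old
                    events.append(TrueEvent(node.parent_node.name, node.name,
                                            col, new, old, "substitution"))

        chars[node.name] = my

    # guarantee leaf uniqueness: identical leaves (possible under very short
    # branches) would be indistinguishable from injected duplicates
    leaf_nodes = {lf.name: lf for lf in tree.leaf_node_iter()}
    while True:
        seen: dict[str, str] = {}
        collision = None
        for name in sorted(leaf_nodes):
            key = "".join(chars[name].get(c, "-") for c in sorted(columns))
            if key in seen:
                collision = name
                break
            seen[key] = name
        if collision is None:
            break
        my = chars[collision]
        pool = [c for c in sorted(my) if c not in touched]
        col = pool[int(rng.integers(0, len(pool)))] if pool else \
            sorted(my)[int(rng.integers(0, len(my)))]
        old = my[col]
        new = str(rng.choice(bases[bases != old]))
        my[col] = new
        touched.add(col)
        parent = leaf_nodes[collision].parent_node.name
        events.append(TrueEvent(parent, collision, col, old, new,
                                "substitution"))

    # leaf ambiguity injection (recorded as events of kind 'ambiguity')
    if spec.ambiguity_rate > 0:
        for lf in tree.leaf_node_iter():
            my = chars[lf.name]
            for col in sorted(my):
                if rng.random() < spec.ambiguity_rate:
                    old = my[col]
                    code = str(rng.choice(list(_AMBIG_CODES)))
                    my[col] = code
                    events.append(TrueEvent(lf.name, lf.name, col, old, code,
                                            "ambiguity"))

    order = sorted(columns)
    leaf_names = [lf.name for lf in tree.leaf_node_iter()]
    rows = {}
    for name in leaf_names:
        my = chars[name]
        rows[name] = "".join(my.get(c, "-") for c in order)
    colmap = [p if k == 0 else None for p, k in order]
    true_aln = Alignment(leaf_names, rows, colmap=colmap)

    sequences = [Sequence(id=name, residues=rows[name].replace("-", ""),
                          species="synthetic", source="synthdata")
                 for name in leaf_names]
    truth = GroundTruth(tree=tree, events=events, alignment=true_aln,
                        annotation=annotation)
    return Dataset(sequences), truth


def inject_defects(dataset: Dataset, spec: SynthSpec,
                   annotation: ReferenceAnnotation,
                   rng: Optional[np.random.Generator] = None
                   ) -> tuple[Dataset, dict[str, Defect]]:
    """Apply the requested defect battery to randomly chosen sequences.

    Each modifying defect hits a distinct sequence; duplicates add new
    sequences copied from untouched ones.  The registry maps sequence id
    to the defect applied, exactly.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    n_modify = (spec.n_rotations + spec.n_truncations + spec.n_n_runs
                + spec.n_outliers + spec.n_overlong + spec.n_ambiguous)
    if n_modify + spec.n_duplicates > len(dataset):
        raise ValueError("more defects requested than sequences available")
    ids = list(dataset.ids)
    victims = [str(v) for v in rng.choice(ids, size=n_modify, replace=False)]
    registry: dict[str, Defect] = {}
    out = [dataset.get(i) for i in ids]
    index = {s.id: k for k, s in enumerate(out)}
    L = annotation.length
    cr1 = annotation.unit("control_region_1")
    cr2 = annotation.unit("control_region_2")

    def take(n: int) -> list[str]:
        chosen, rest = victims[:n], victims[n:]
        victims[:] = rest
        return chosen

    for vid in take(spec.n_rotations):
        s = out[index[vid]]
        offset = spec.rotation_offset or int(rng.integers(50, len(s) - 50))
        out[index[vid]] = s.with_residues(rotate(s.residues, offset))
        registry[vid] = Defect("rotation", {"offset": offset})

    for vid in take(spec.n_truncations):
        s = out[index[vid]]
        head = cr1.length
        tail = cr2.length
        out[index[vid]] = s.with_residues(s.residues[head:len(s) - tail])
        registry[vid] = Defect("truncation", {"removed": head + tail})

    for vid in take(spec.n_n_runs):
        s = out[index[vid]]
        start = int(rng.integers(len(s) // 4, len(s) // 2))
        run = spec.n_run_length
        res = s.residues[:start] + "N" * run + s.residues[start + run:]
        out[index[vid]] = s.with_residues(res)
        registry[vid] = Defect("n_run", {"start": start + 1, "length": run})

    for vid in take(spec.n_outliers):
        s = out[index[vid]]
        res = list(s.residues)
        positions = rng.choice(len(res), size=spec.outlier_extra_subs,
                               replace=False)
        bases = np.array(list("ACGT"))
        for p in positions:
            res[p] = str(rng.choice(bases[bases != res[p]]))
        out[index[vid]] = s.with_residues("".join(res))
        registry[vid] = Defect("outlier",
                               {"extra_substitutions": spec.outlier_extra_subs})

    for vid in take(spec.n_overlong):
        s = out[index[vid]]
        extra = (L + 150) - len(s)
        pad = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=extra)])
        out[index[vid]] = s.with_residues(s.residues + pad)
        registry[vid] = Defect("overlong", {"padded_to": len(s) + extra})

    for vid in take(spec.n_ambiguous):
        s = out[index[vid]]
        res = list(s.residues)
        positions = rng.choice(len(res), size=spec.ambiguity_excess_count,
                               replace=False)
        for p in positions:
            res[p] = str(rng.choice(list(_AMBIG_CODES)))
        out[index[vid]] = s.with_residues("".join(res))
        registry[vid] = Defect("ambiguity_excess",
                               {"count": spec.ambiguity_excess_count})

    clean_ids = [i for i in ids if i not in registry]
    for _d in range(spec.n_duplicates):
        src = str(rng.choice(clean_ids))
        dup_id = f"{src}_dup{_d + 1}"
        out.append(Sequence(id=dup_id, residues=out[index[src]].residues,
                            species="synthetic", source="synthdata"))
        registry[dup_id] = Defect("duplicate", {"of": src})

    return Dataset(out), registry


def qc_config_for(annotation: ReferenceAnnotation, **overrides) -> QcConfig:
    """QC thresholds consistent with a synthetic reference's geometry."""
    cr_len = sum(u.length for u in annotation.units
                 if u.kind == "control_region_part")
    return QcConfig.scaled(annotation.length, cr_len, **overrides)


@dataclass
class SynthResult:
    """One generated study: annotation, truth, datasets and config."""

    spec: SynthSpec
    annotation: ReferenceAnnotation
    tree: dendropy.Tree
    clean_dataset: Dataset
    dataset: Dataset
    truth: GroundTruth
    qc_config: QcConfig


def generate(spec: SynthSpec) -> SynthResult:
    """Full deterministic generation: tree, sequences, defects, registry."""
    rng = np.random.default_rng(spec.seed)
    annotation = make_annotation(spec, rng)
    tree = simulate_tree(spec.n_leaves, rng)
    clean, truth = evolve_sequences(tree, annotation, spec, rng)
    defected, registry = inject_defects(clean, spec, annotation, rng)
    truth.registry = registry
    return SynthResult(spec, annotation, tree, clean, defected, truth,
                       qc_config_for(annotation))
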