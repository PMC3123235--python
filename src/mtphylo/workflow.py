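"""End-to-end pipeline: storage stages interleaved with algorithmic and
restrictive stages.

The flow is qc -> rotation correction -> duplicate compression ->
reference alignment (cached) -> partitioned alignment and merge ->
distances and group outliers -> tree -> parsimony annotation -> stats.
Restrictive stages do not silently drop data: review-range lengths and
distance outliers are flagged and routed back to the curation log, and
only ``auto_exclude`` removes them from tree building.  Every stage
writes its artifact under the output directory, so a rerun can reuse
cached intermediates (notably the per-sequence pairwise alignments with
the reference, which dominate the cost and never change for a given
sequence).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import io as mio
from .alignment import Alignment
from .annotation import ReferenceAnnotation
from .annotate import (branch_stats, conservation_profile, crosstab,
                       ensure_node_names, extract_events, fitch_label,
                       flag_events, generation_points,
                       perfect_phylogeny_bound, summary_rates)
from .curation import QcConfig, run_qc
from .pairwise import (AFFINE_SINGLE_EVENT, correct_rotation, detect_rotation,
                       distance_matrix, global_align, group_outliers,
                       PairwiseAlignment)
from .partition import align_unit, merge_units, split_by_units
from .sequences import Dataset
from .trees import (bootstrap_replicates, majority_consensus,
                    neighbor_joining, root_by_outgroup)

__all__ = ["WorkflowConfig", "PipelineResult", "run_pipeline"]


@dataclass
class WorkflowConfig:
    """All pipeline thresholds and toggles in one place.

    The stored database query string documents how a user would assemble
    the real input set from GenBank; the tool itself never downloads.
    """

    qc: QcConfig = field(default_factory=QcConfig)
    engine: str = "internal"          # unit aligner: internal | mafft | ...
    indel_mode: str = "per_column"
    skip_ambiguous_distances: bool = True
    outlier_k: float = 5.0
    alpha_threshold: float = 0.95
    branch_outlier_threshold: int = 50
    bootstrap_n: int = 0
    consensus_threshold: float = 0.5
    seed: int = 42
    auto_exclude: bool = False
    back_mutation_scope: str = "path"
    #: Entrez query used to assemble the real mtDNA input set by hand.
    database_query: str = ("Homo[Organism] AND gene in mitochondrion[PROP] "
                           "AND 14000:19000[SLEN] NOT pseudogene[All Fields]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "qc" in payload:
            def tuplify(v):
                return tuple(tuplify(x) for x in v) if isinstance(v, list) else v
            payload["qc"] = QcConfig(**{k: tuplify(v)
                                        for k, v in payload["qc"].items()})
        return cls(**payload)


@dataclass
class PipelineResult:
    dataset: Dataset
    qc_report: object
    alignment: Alignment
    matrix: object
    outliers: object
    tree: object
    consensus: object
    events: list
    stats: dict
    flags: dict[str, list[str]]


def _cache_ref_alignment(cache_dir: Path, seq, reference) -> PairwiseAlignment:
    """Pairwise alignment with the reference, cached on disk by content."""
    digest = hashlib.sha1(seq.residues.encode()).hexdigest()[:16]
    path = cache_dir / f"refaln_{seq.id}_{digest}.fasta"
    if path.exists():
        aln = mio.read_alignment_fasta(path)
        a, b = aln.rows[aln.ids[0]], aln.rows[aln.ids[1]]
        if a.replace("-", "") == seq.residues:
            return PairwiseAlignment(a, b, float("nan"))
    pa = global_align(seq.residues, reference.residues, AFFINE_SINGLE_EVENT)
    with open(path, "w") as fh:
        fh.write(f">{seq.id}\n{pa.aligned_a}\n>{reference.id}\n{pa.aligned_b}\n")
    return pa


def run_pipeline(dataset: Dataset, annotation: ReferenceAnnotation,
                 config: WorkflowConfig, outdir: str | Path) -> PipelineResult:
    """Run every stage on an in-memory dataset, writing artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cache = outdir / "cache"
    cache.mkdir(exist_ok=True)
    flags: dict[str, list[str]] = {}

    def flag(sid: str, rule: str) -> None:
        flags.setdefault(sid, []).append(rule)

    # ---- stage 1: qc -----------------------------------------------------
    report, ds = run_qc(dataset, config.qc)
    report.to_json(outdir / "qc_report.json")
    for sid, rec in report.per_sequence.items():
        for f in rec["flags"]:
            flag(sid, f)
    retained = [s for s in ds if s.tier != "excluded"]

    # ---- stage 2: rotation detection and correction ----------------------
    reference = annotation.reference
    corrected = []
    for s in retained:
        # rotation only makes sense for complete genomes: a missing
        # control region mimics a rotation under naive identity scoring
        if s.tier == "strict" and 0.8 <= len(s) / len(reference) <= 1.2:
            offset = detect_rotation(s, reference)
        else:
            offset = None
        if offset:
            s = correct_rotation(s, offset)
            ds.record("rotation_corrected", s.id, f"offset {offset}")
            ds.replace_sequence(s)
            flag(s.id, "rotation_corrected")
        corrected.append(s)

    # ---- stage 3: duplicate compression ----------------------------------
    from .curation import deduplicate
    dups = deduplicate(Dataset(corrected))
    reps = [s for s in corrected if s.id in dups.groups]

    # ---- stage 4+5: partitioned alignment --------------------------------
    ref_alignments = {s.id: _cache_ref_alignment(cache, s, reference)
                      for s in reps}
    unit_slices: dict[str, list] = {u.name: [] for u in annotation.units}
    from .partition import UnitSlice
    for u in annotation.units:  # reference slices lead every unit
        unit_slices[u.name].append(UnitSlice(
            reference.id, u.name, reference.residues[u.start - 1:u.end]))
    for s in reps:
        for sl in split_by_units(s, annotation, ref_alignments[s.id]):
            if sl.empty:
                flag(s.id, f"missing_unit:{sl.unit_name}")
            else:
                unit_slices[sl.unit_name].append(sl)
    unit_alignments = {}
    for u in annotation.units:
        slices = unit_slices[u.name]
        nonempty = [sl for sl in slices if not sl.empty]
        if len(nonempty) >= 2:
            unit_alignments[u.name] = align_unit(
                nonempty, engine=config.engine, center_id=reference.id)
        else:
            unit_alignments[u.name] = Alignment.from_rows(
                [(sl.sequence_id, sl.residues) for sl in nonempty])
    full = merge_units(unit_alignments, annotation, reference.id)
    full.write_fasta(outdir / "alignment.fasta")
    full.write_colmap(outdir / "colmap.tsv")

    # ---- stage 6: distances and outliers ---------------------------------
    has_flexible = any(s.tier == "flexible" for s in reps)
    column_mask = None
    if has_flexible and full.colmap is not None:
        cr = [u for u in annotation.units if u.kind == "control_region_part"]
        in_cr = np.zeros(annotation.length + 1, dtype=bool)
        for u in cr:
            in_cr[u.start:u.end + 1] = True
        cr_cols = np.array([p is not None and in_cr[p] for p in full.colmap])
        column_mask = np.array([p is not None for p in full.colmap]) & ~cr_cols
        # control-region gaps of flexible rows are unsequenced, not
        # deletions: mask them so they never generate mutation events
        for s in reps:
            if s.tier != "flexible":
                continue
            row_gap = np.frombuffer(full.rows[s.id].encode("ascii"),
                                    dtype=np.uint8) == ord("-")
            prior = full.unsequenced.get(
                s.id, np.zeros(full.ncols, dtype=bool))
            full.unsequenced[s.id] = prior | (cr_cols & row_gap)
    matrix = distance_matrix(full, indel_mode=config.indel_mode,
                             skip_ambiguous=config.skip_ambiguous_distances,
                             column_mask=column_mask)
    matrix.to_tsv(outdir / "distances.tsv")
    labels = {s.id: (s.species or "default") for s in reps}
    labels[reference.id] = "reference"
    outliers = group_outliers(matrix, labels, k=config.outlier_k)
    for sid in outliers.flagged:
        flag(sid, "distance_outlier")
        ds.record("distance_outlier", sid, "flagged")

    # ---- stage 7: tree ---------------------------------------------------
    tree_ids = [i for i in full.ids
                if not (config.auto_exclude and i in outliers.flagged)]
    if config.auto_exclude:
        for sid in outliers.flagged:
            if sid in ds:
                ds.replace_sequence(ds.get(sid).with_tier("excluded"))
    tree_aln = full.subset(tree_ids)
    tree_matrix = distance_matrix(tree_aln, indel_mode=config.indel_mode,
                                  skip_ambiguous=config.skip_ambiguous_distances,
                                  column_mask=column_mask)
    nj = neighbor_joining(tree_matrix)
    consensus = None
    if config.bootstrap_n > 0:
        reps_alns = bootstrap_replicates(tree_aln, config.bootstrap_n,
                                         config.seed)
        boot_trees = [neighbor_joining(distance_matrix(a)) for a in reps_alns]
        consensus = majority_consensus(boot_trees, config.consensus_threshold)
    rooted = root_by_outgroup(nj, [reference.id])
    mio.write_newick(rooted, outdir / "tree.nwk")
    if consensus is not None:
        mio.write_newick(consensus, outdir / "consensus.nwk")

    # ---- stage 8: annotation and statistics ------------------------------
    ensure_node_names(rooted)
    profile = conservation_profile(tree_aln)
    labeling = fitch_label(rooted, tree_aln)
    events = extract_events(labeling, rooted)
    events = flag_events(events, rooted, profile,
                         alpha_threshold=config.alpha_threshold,
                         back_mutation_scope=config.back_mutation_scope,
                         colmap=full.colmap)
    ct = crosstab(events)
    bstats = branch_stats(events, rooted,
                          threshold=config.branch_outlier_threshold)
    leaf_ids = set(tree_aln.ids)
    for parent, child in bstats.outliers:
        if child in leaf_ids:  # internal-branch outliers live in stats only
            flag(child, "branch_outlier")
            ds.record("branch_outlier", child, "flagged")
    gp_counts, gp_hist = generation_points(events)
    n_leaves = sum(1 for _ in rooted.leaf_node_iter())
    rates = summary_rates(len(events), n_leaves, tree_aln.ncols,
                          bstats.counts)
    stats = {
        "n_sequences": len(dataset),
        "n_representatives": len(reps),
        "n_tree_leaves": n_leaves,
        "n_columns": tree_aln.ncols,
        "fitch_score": labeling.score,
        "n_events": len(events),
        "crosstab": ct.to_dict(),
        "perfect_phylogeny_bound": perfect_phylogeny_bound(tree_aln),
        "conservation_mean": profile.mean,
        "conservation_sd": profile.sd,
        "rates": rates.report(),
        "branch_outliers": sorted(c for _, c in bstats.outliers),
        "generation_point_histogram": {str(k): v
                                       for k, v in sorted(gp_hist.items())},
        "flags": {k: sorted(set(v)) for k, v in sorted(flags.items())},
    }
    (outdir / "stats.json").write_text(json.dumps(stats, indent=1))
    with open(outdir / "events.tsv", "w") as fh:
        fh.write("parent\tchild\tcolumn\tref_position\tfrom\tto\tflags\n")
        for e in events:
            fh.write(f"{e.parent}\t{e.child}\t{e.column}\t"
                     f"{e.ref_position if e.ref_position is not None else 'ins'}"
                     f"\t{e.from_state}\t{e.to_state}\t"
                     f"{','.join(sorted(e.flags))}\n")
    annotations: dict[str, list[dict]] = {}
    for e in events:
        annotations.setdefault(e.child, []).append({
            "column": e.column, "ref_position": e.ref_position,
            "from_state": e.from_state, "to_state": e.to_state,
            "flags": e.flags})
    mio.write_phyloxml(rooted, annotations, outdir / "tree.phyloxml")
    with open(outdir / "provenance.tsv", "w") as fh:
        fh.write("rule\tsequence\tdecision\n")
        for a in ds.log:
            fh.write(f"{a.rule}\t{a.sequence_id}\t{a.decision}\n")

    return PipelineResult(ds, report, full, matrix, outliers, rooted,
                          consensus, events, stats,
                          {k: sorted(set(v)) for k, v in flags.items()})
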