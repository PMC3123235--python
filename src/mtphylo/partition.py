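"""Reference-guided partitioned alignment.

Aligning thousands of ~16.6 kb genomes at once is impractical, but the
mitochondrial genome has a fixed gene order, so each sequence can be
split at the structural boundaries defined by the reference annotation,
each unit aligned separately, and the unit alignments concatenated back
(reconciling the declared overlaps between adjacent units such as
ATP8/ATP6).  Unit boundaries are located in each sequence through its
cached pairwise alignment with the reference, which is computed once.

Indels inside protein-coding units are classified as codon-level (length
divisible by three, placed on a codon boundary) or frameshift; indels in
non-coding units are left unclassified biologically.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np

from .alignment import Alignment
from .annotation import ReferenceAnnotation, StructuralUnit
from .pairwise import (AFFINE_SINGLE_EVENT, PairwiseAlignment, ScoringScheme,
                       global_align)
from .sequences import Sequence

__all__ = [
    "UnitSlice",
    "IndelCall",
    "split_by_units",
    "align_unit",
    "classify_indels",
    "merge_units",
]


@dataclass(frozen=True)
class UnitSlice:
    """The residues of one sequence homologous to one structural unit."""

    sequence_id: str
    unit_name: str
    residues: str
    left_overlap: int = 0
    right_overlap: int = 0

    @property
    def empty(self) -> bool:
        return not self.residues


def _push_query_gaps_right(aligned_a: str, aligned_b: str) -> tuple[str, str]:
    """Canonicalize co-optimal gap placement: pull residues leftward.

    A residue sitting just right of a query gap run is moved to the run's
    start whenever it matches the reference there - cost-neutral under
    any of the schemes used here - so that truncated regions become clean
    terminal gap blocks and residues attach to the leftmost homologous
    position.
    """
    a = list(aligned_a)
    b = aligned_b
    n = len(a)
    i = 0
    while i < n:
        if a[i] != "-":
            i += 1
            continue
        j = i
        while j < n and a[j] == "-":
            j += 1
        while j < n and a[j] != "-" and b[j] != "-" and a[j] == b[i]:
            a[i], a[j] = a[j], "-"
            i += 1
            j += 1
        i = j
    return "".join(a), b


def _reference_positions(ref_alignment: PairwiseAlignment) -> list[int]:
    """Reference position owning each residue of the query sequence.

    Insertions attach to the reference position on their left; residues
    inserted before reference position 1 attach to position 1.
    """
    owners: list[int] = []
    p = 0
    for qa, ra in zip(ref_alignment.aligned_a, ref_alignment.aligned_b):
        if ra != "-":
            p += 1
        if qa != "-":
            owners.append(max(p, 1))
    return owners


def split_by_units(seq: Sequence, annotation: ReferenceAnnotation,
                   ref_alignment: Optional[PairwiseAlignment] = None,
                   margin: int = 0) -> list[UnitSlice]:
    """Split one sequence into per-unit slices via its reference alignment.

    ``ref_alignment`` must align ``seq`` (row a) against the annotation's
    reference (row b); it is computed on the fly when not supplied, but
    callers should cache it.  Affine gap costs are used so that missing
    regions stay contiguous gap blocks instead of being scattered among
    co-optimal mismatches.  ``margin`` extends every unit interval by
    the given number of reference positions on both sides, in addition to
    any overlap the annotation declares between adjacent units.  A unit
    with no homologous residues yields an empty, flagged slice.
    """
    if ref_alignment is None:
        ref_alignment = global_align(seq.residues, annotation.reference.residues,
                                     AFFINE_SINGLE_EVENT)
    if ref_alignment.aligned_a.replace("-", "") != seq.residues:
        raise ValueError(f"reference alignment does not match sequence {seq.id}")
    norm_a, norm_b = _push_query_gaps_right(ref_alignment.aligned_a,
                                            ref_alignment.aligned_b)
    ref_alignment = PairwiseAlignment(norm_a, norm_b, ref_alignment.score)
    owners = np.array(_reference_positions(ref_alignment))
    residues = np.array(list(seq.residues))
    units = annotation.units
    slices: list[UnitSlice] = []
    for idx, unit in enumerate(units):
        left = right = 0
        if idx > 0:
            left = annotation.adjacent_overlap(units[idx - 1], unit)
        if idx + 1 < len(units):
            right = annotation.adjacent_overlap(unit, units[idx + 1])
        lo = max(unit.start - margin, 1)
        hi = min(unit.end + margin, annotation.length)
        sel = (owners >= lo) & (owners <= hi)
        slices.append(UnitSlice(seq.id, unit.name, "".join(residues[sel]),
                                left_overlap=left, right_overlap=right))
    return slices


# --------------------------------------------------------------------------
# per-unit multiple alignment

def _center_star(rows: list[tuple[str, str]], center_id: str,
                 scoring: ScoringScheme) -> Alignment:
    """Progressive center-star alignment around ``center_id``'s row."""
    center = dict(rows)[center_id]
    others = [(i, s) for i, s in rows if i != center_id]
    pairs = {i: global_align(s, center, scoring) for i, s in others}
    # inserted-character counts before each center position (index 0..len)
    ins = np.zeros(len(center) + 1, dtype=int)
    chunks: dict[str, tuple[list[str], list[str]]] = {}
    for i, pa in pairs.items():
        before: list[str] = [""] * (len(center) + 1)
        at: list[str] = [""] * len(center)
        cpos = 0
        for qa, ca in zip(pa.aligned_a, pa.aligned_b):
            if ca == "-":
                before[cpos] += qa
            else:
                at[cpos] = qa
                cpos += 1
        chunks[i] = (before, at)
        ins = np.maximum(ins, [len(b) for b in before])
    out_rows: list[tuple[str, str]] = []
    center_row = "".join("-" * ins[j] + center[j] for j in range(len(center)))
    center_row += "-" * ins[len(center)]
    for i, _ in rows:
        if i == center_id:
            out_rows.append((i, center_row))
            continue
        before, at = chunks[i]
        parts = []
        for j in range(len(center)):
            parts.append(before[j] + "-" * (ins[j] - len(before[j])) + at[j])
        parts.append(before[len(center)] + "-" * (ins[len(center)]
                                                  - len(before[len(center)])))
        out_rows.append((i, "".join(parts)))
    return Alignment.from_rows(out_rows)


def align_unit(slices: Iterable[UnitSlice], engine: str = "internal",
               scoring: ScoringScheme = ScoringScheme(),
               center_id: Optional[str] = None) -> Alignment:
    """Multiple alignment of the non-empty slices of one unit.

    The internal engine is a deterministic center-star progressive
    aligner seeded on ``center_id`` (normally the reference's slice).
    ``engine='mafft'`` (or any executable name) delegates to an external
    aligner invoked on FASTA in / FASTA out.
    """
    slices = list(slices)
    nonempty = [s for s in slices if not s.empty]
    if len(nonempty) < 2:
        raise ValueError("need at least two non-empty slices to align")
    names = {s.unit_name for s in slices}
    if len(names) != 1:
        raise ValueError(f"slices from different units: {sorted(names)}")
    rows = [(s.sequence_id, s.residues) for s in nonempty]
    if center_id is None or center_id not in {i for i, _ in rows}:
        center_id = rows[0][0]
    if engine == "internal":
        if len({r for _, r in rows}) == 1:
            return Alignment.from_rows(rows)  # identical: gap-free by definition
        return _center_star(rows, center_id, scoring)
    return _external_align(rows, engine)


def _external_align(rows: list[tuple[str, str]], engine: str) -> Alignment:
    exe = shutil.which(engine)
    if exe is None:
        raise RuntimeError(
            f"external aligner {engine!r} not found on PATH; "
            "fall back to engine='internal'")
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "unit.fasta"
        with open(fasta, "w") as fh:
            for i, s in rows:
                fh.write(f">{i}\n{s}\n")
        res = subprocess.run([exe, "--auto", "--quiet", str(fasta)]
                             if "mafft" in engine else [exe, str(fasta)],
                             capture_output=True, text=True, check=True)
    aligned: list[tuple[str, str]] = []
    cur_id, cur = None, []
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            if cur_id is not None:
                aligned.append((cur_id, "".join(cur).upper()))
            cur_id, cur = line[1:].split()[0], []
        else:
            cur.append(line.strip())
    if cur_id is not None:
        aligned.append((cur_id, "".join(cur).upper()))
    order = {i: k for k, (i, _) in enumerate(rows)}
    aligned.sort(key=lambda p: order[p[0]])
    return Alignment.from_rows(aligned)


# --------------------------------------------------------------------------
# indel classification

@dataclass(frozen=True)
class IndelCall:
    """One maximal gap run, localized and classified.

    ``ref_position`` is the first deleted reference position for a
    deletion, or the reference position immediately left of the inserted
    material for an insertion.
    """

    unit_name: str
    sequence_id: str
    ref_position: int
    length: int
    kind: str
    insertion: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("codon_full", "frameshift", "noncoding"):
            raise ValueError(f"unknown indel kind {self.kind!r}")


def _unit_colmap(aln: Alignment, unit: StructuralUnit,
                 reference_id: str) -> list[Optional[int]]:
    """Reference position per column, from the unit's reference row."""
    ref_row = aln.rows[reference_id]
    colmap: list[Optional[int]] = []
    p = unit.start - 1
    for ch in ref_row:
        if ch == "-":
            colmap.append(None)
        else:
            p += 1
            colmap.append(p)
    if p != unit.end:
        raise ValueError(
            f"reference row of unit {unit.name} spans {unit.start}..{p}, "
            f"expected ..{unit.end}")
    return colmap


def _codon_aligned(unit: StructuralUnit, first_ref_pos: int, length: int,
                   insertion: bool) -> bool:
    if length % 3 != 0:
        return False
    if insertion:
        # material inserted after first_ref_pos: between-codon iff the
        # position closes a codon
        return (first_ref_pos - unit.start + 1 - unit.reading_frame_offset) % 3 == 0
    return (first_ref_pos - unit.start - unit.reading_frame_offset) % 3 == 0


def classify_indels(unit_alignment: Alignment, unit: StructuralUnit,
                    reference_id: str) -> list[IndelCall]:
    """Classify every maximal gap run in a unit alignment.

    Deletions are gap runs in a sequence row; insertions are runs of
    residues a row holds where the reference row is gapped.  In coding
    units an event is ``codon_full`` when its length is a multiple of
    three *and* it starts on a codon boundary, else ``frameshift``; in
    non-coding units every event is ``noncoding``.
    """
    if reference_id not in unit_alignment.rows:
        raise ValueError(f"reference row {reference_id!r} missing from unit "
                         f"{unit.name}")
    colmap = _unit_colmap(unit_alignment, unit, reference_id)
    calls: list[IndelCall] = []
    for sid in unit_alignment.ids:
        if sid == reference_id:
            continue
        row = unit_alignment.rows[sid]
        j = 0
        n = len(row)
        while j < n:
            if row[j] == "-" and colmap[j] is not None:
                # deletion relative to the reference
                j0 = j
                while j < n and row[j] == "-":
                    j += 1
                positions = [colmap[x] for x in range(j0, j)
                             if colmap[x] is not None]
                length = len(positions)
                if length:
                    kind = "noncoding"
                    if unit.coding:
                        kind = ("codon_full" if _codon_aligned(
                            unit, positions[0], length, False) else "frameshift")
                    calls.append(IndelCall(unit.name, sid, positions[0],
                                           length, kind, insertion=False))
            elif row[j] != "-" and colmap[j] is None:
                # insertion relative to the reference
                j0 = j
                while j < n and colmap[j] is None:
                    j += 1
                length = sum(1 for x in range(j0, j) if row[x] != "-")
                anchor = max((colmap[x] for x in range(j0) if colmap[x] is not None),
                             default=unit.start - 1)
                if length:
                    kind = "noncoding"
                    if unit.coding:
                        kind = ("codon_full" if _codon_aligned(
                            unit, anchor, length, True) else "frameshift")
                    calls.append(IndelCall(unit.name, sid, anchor, length,
                                           kind, insertion=True))
            else:
                j += 1
    return calls


# --------------------------------------------------------------------------
# merge

def merge_units(unit_alignments: Mapping[str, Alignment],
                annotation: ReferenceAnnotation,
                reference_id: str) -> Alignment:
    """Concatenate unit alignments into the full alignment.

    Adjacent-unit overlaps keep the left unit's columns; the right unit's
    copy must agree residue-for-residue per sequence, otherwise a
    reconciliation error names the sequence and the unit pair.  Rows
    absent from a unit are gap-filled there and marked unsequenced.
    """
    units = [u for u in annotation.units if u.name in unit_alignments]
    if not units:
        raise ValueError("no unit alignments supplied")
    all_ids: list[str] = []
    for u in units:
        for i in unit_alignments[u.name].ids:
            if i not in all_ids:
                all_ids.append(i)
    if reference_id in all_ids:  # reference leads
        all_ids.remove(reference_id)
        all_ids.insert(0, reference_id)

    merged: dict[str, list[str]] = {i: [] for i in all_ids}
    unseq: dict[str, list[bool]] = {i: [] for i in all_ids}
    colmap: list[Optional[int]] = []
    # per row: residue string contributed at each reference position
    # (position's residue plus any insertions attached to its right)
    contrib: dict[str, dict[int, str]] = {i: {} for i in all_ids}
    last_ref = 0
    prev_unit: Optional[StructuralUnit] = None

    for unit in units:
        aln = unit_alignments[unit.name]
        ucolmap = _unit_colmap(aln, unit, reference_id)
        keep: list[int] = []
        dropped: list[int] = []
        anchor = unit.start - 1
        for j, p in enumerate(ucolmap):
            if p is not None:
                anchor = p
            # a column is overlap-dropped only when a previous unit already
            # contributed its anchor position (insertions before position 1
            # can only belong to the first unit and are always kept)
            (keep if anchor > last_ref or last_ref == 0 else dropped).append(j)
        if dropped:
            # overlap region: verify the right unit agrees with what the
            # left unit already contributed
            ref_dropped = [ucolmap[j] for j in dropped if ucolmap[j] is not None]
            lo = min(ref_dropped) if ref_dropped else last_ref + 1
            for sid in aln.ids:
                row = aln.rows[sid]
                right_str = "".join(row[j] for j in dropped).replace("-", "")
                left_str = "".join(contrib[sid].get(p, "")
                                   for p in range(lo, last_ref + 1))
                seen_left = any(p in contrib[sid] for p in range(lo, last_ref + 1))
                if (seen_left and right_str != left_str) or (
                        not seen_left and right_str):
                    raise ValueError(
                        f"overlap disagreement for sequence {sid!r} between "
                        f"units {prev_unit.name if prev_unit else '?'!r} "
                        f"and {unit.name!r}: {left_str!r} vs {right_str!r}")
        width = len(keep)
        anchor = last_ref
        for j in keep:
            p = ucolmap[j]
            colmap.append(p)
            if p is not None:
                anchor = p
            for sid in all_ids:
                if sid in aln.rows:
                    ch = aln.rows[sid][j]
                    merged[sid].append(ch)
                    unseq[sid].append(False)
                    if ch != "-":
                        key = p if p is not None else anchor
                        contrib[sid][key] = contrib[sid].get(key, "") + ch
                else:
                    merged[sid].append("-")
                    unseq[sid].append(True)
        if keep:
            last_kept = [ucolmap[j] for j in keep if ucolmap[j] is not None]
            if last_kept:
                last_ref = last_kept[-1]
        prev_unit = unit

    rows = {i: "".join(merged[i]) for i in all_ids}
    unsequenced = {i: np.array(unseq[i], dtype=bool) for i in all_ids
                   if any(unseq[i])}
    return Alignment(all_ids, rows, colmap=colmap, unsequenced=unsequenced)
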