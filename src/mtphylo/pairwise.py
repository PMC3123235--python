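"""Pairwise alignment, parsimony edit distances and rotation correction.

Distances are unweighted parsimony counts in "distance orientation":
match 0, mismatch 1, each gapped column 1 (or each maximal gap run 1 when
indels are treated as single events).  A column contributes nothing when
the IUPAC sets of the two symbols intersect, so ambiguity never inflates
a distance.  Rotation handling corrects circular genomes linearized at a
non-canonical start point, after which everything downstream can treat
sequences as plain linear strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
from Bio import Align
from scipy.stats import median_abs_deviation

from .alignment import Alignment
from .sequences import Sequence, iupac_set

__all__ = [
    "ScoringScheme",
    "AFFINE_SINGLE_EVENT",
    "PairwiseAlignment",
    "global_align",
    "edit_distance",
    "DistanceMatrix",
    "distance_matrix",
    "GroupOutlierReport",
    "group_outliers",
    "detect_rotation",
    "correct_rotation",
    "rotate",
]

# Bitmask encoding of IUPAC symbols over states {A,C,G,T,-}; two symbols
# are compatible iff their masks intersect.
_BITS = {"A": 1, "C": 2, "G": 4, "T": 8, "-": 16}
_MASK = np.zeros(128, dtype=np.uint8)
for _sym in "ACGTRYSWKMBDHVN":
    _MASK[ord(_sym)] = sum(_BITS[b] for b in iupac_set(_sym))
_MASK[ord("-")] = _BITS["-"]

def _encode(row: str) -> np.ndarray:
    codes = np.frombuffer(row.encode("ascii"), dtype=np.uint8)
    masks = _MASK[codes]
    if (masks == 0).any():
        bad = chr(codes[int(np.argmax(masks == 0))])
        raise ValueError(f"symbol {bad!r} is not IUPAC DNA")
    return masks


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment costs (all nonnegative, distance orientation).

    ``gap_open`` is charged for the first column of a gap run and
    ``gap_extend`` for each further column, so the default (0/1/1/1)
    makes the optimal-alignment cost equal the per-column parsimony
    distance.  ``indel_mode`` records how downstream distance
    computations should count gap runs.
    """

    match: float = 0.0
    mismatch: float = 1.0
    gap_open: float = 1.0
    gap_extend: float = 1.0
    indel_mode: str = "per_column"

    def __post_init__(self) -> None:
        if min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("costs must be nonnegative in distance orientation")
        if self.indel_mode not in ("per_column", "single_event"):
            raise ValueError(f"unknown indel mode {self.indel_mode!r}")


#: Affine preset approximating single-event treatment of indels.
AFFINE_SINGLE_EVENT = ScoringScheme(gap_open=3.0, gap_extend=1.0,
                                    indel_mode="single_event")


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of two sequences with its cost."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")
        if any(x == y == "-" for x, y in zip(self.aligned_a, self.aligned_b)):
            raise ValueError("column with gap in both rows")


def global_align(a: str | Sequence, b: str | Sequence,
                 scoring: ScoringScheme = ScoringScheme()) -> PairwiseAlignment:
    """Optimal global (Needleman-Wunsch, affine-gap) alignment.

    Runs on Biopython's pairwise aligner with negated costs; the returned
    ``score`` is the minimal total cost.  Of the co-optimal alignments the
    aligner's canonical first enumeration is returned, which is
    deterministic for fixed inputs.
    """
    sa = a.residues if isinstance(a, Sequence) else a
    sb = b.residues if isinstance(b, Sequence) else b
    if not sa or not sb:
        raise ValueError("cannot align empty sequences")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = -scoring.match
    aligner.mismatch_score = -scoring.mismatch
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    aln = aligner.align(sa, sb)[0]
    return PairwiseAlignment(str(aln[0]), str(aln[1]), -aln.score)


def edit_distance(row_a: str, row_b: str, indel_mode: str = "per_column") -> int:
    """Parsimony edit distance between two aligned (gapped) rows.

    per_column: one event per column whose IUPAC sets are disjoint
    (columns gapped in both rows never count).  single_event: one event
    per substitution column plus one per maximal gap run in either row.
    """
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows must have equal length")
    if not row_a:
        return 0
    ma, mb = _encode(row_a), _encode(row_b)
    disjoint = (ma & mb) == 0
    if indel_mode == "per_column":
        return int(disjoint.sum())
    if indel_mode != "single_event":
        raise ValueError(f"unknown indel mode {indel_mode!r}")
    gap_a = ma == _BITS["-"]
    gap_b = mb == _BITS["-"]
    subs = int((disjoint & ~gap_a & ~gap_b).sum())
    return subs + _count_runs(gap_a & ~gap_b) + _count_runs(gap_b & ~gap_a)


def _count_runs(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    m = mask.astype(np.int8)
    return int(m[0] + (np.diff(m) == 1).sum())


@dataclass
class DistanceMatrix:
    """Labeled symmetric nonnegative distance matrix."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("matrix not symmetric")
        if np.diag(v).any():
            raise ValueError("diagonal must be zero")
        if (v < 0).any():
            raise ValueError("distances must be nonnegative")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.ids) + "\n")
            for i, row_id in enumerate(self.ids):
                fh.write(row_id + "\t"
                         + "\t".join(f"{x:g}" for x in self.values[i]) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = [line.rstrip("\n").split("\t")[1:] for line in fh if line.strip()]
        return cls(header, np.array(rows, dtype=float))


def distance_matrix(alignment: Alignment, indel_mode: str = "per_column",
                    skip_ambiguous: bool = False,
                    column_mask: Optional[np.ndarray] = None) -> DistanceMatrix:
    """All-pairs parsimony edit distances over an alignment.

    ``skip_ambiguous`` drops, per pair, every column where either row
    carries an ambiguity code.  ``column_mask`` (boolean, length ncols)
    restricts all pairs to a fixed set of columns - e.g. coding-region
    columns when control-region-less sequences are being compared.
    """
    if alignment.nrows < 2:
        raise ValueError("need at least two rows for a distance matrix")
    ids = list(alignment.ids)
    masks = np.stack([_encode(alignment.rows[i]) for i in ids])
    plain = np.isin(masks, [1, 2, 4, 8, 16])
    if column_mask is not None:
        keep = np.asarray(column_mask, dtype=bool)
        masks = masks[:, keep]
        plain = plain[:, keep]
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mi, mj = masks[i], masks[j]
            usable = (plain[i] & plain[j]) if skip_ambiguous else np.ones(
                mi.shape, dtype=bool)
            disjoint = ((mi & mj) == 0) & usable
            if indel_mode == "per_column":
                d = int(disjoint.sum())
            else:
                gi = (mi == 16) & usable
                gj = (mj == 16) & usable
                subs = int((disjoint & ~gi & ~gj).sum())
                d = subs + _count_runs(gi & ~gj) + _count_runs(gj & ~gi)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids, values)


@dataclass
class GroupOutlierReport:
    """Within-group outliers and between-group separation."""

    flagged: set[str]
    member_medians: dict[str, float]
    group_stats: dict[str, dict]
    separation: dict[tuple[str, str], dict]
    small_groups: list[str]


def group_outliers(matrix: DistanceMatrix, group_labels: Mapping[str, str],
                   k: float = 5.0, rel_factor: float = 4.0) -> GroupOutlierReport:
    """Flag sequences unusually distant from their own group.

    Within each group of >= 3 members, a member is flagged when the
    median of its intra-group distances exceeds the group's median of
    those medians by more than ``k`` times their median absolute
    deviation, *and* exceeds ``rel_factor`` times that center.  The relative guard
    separates defective data - whose distances are inflated several-fold
    - from legitimately divergent lineages: real intraspecies mtDNA
    distance distributions spread to roughly three times their median,
    so only a larger multiple signals an intrusion.
    Groups of fewer than three members are reported, not scored.  The
    separation report compares, for each group pair, the minimum
    inter-group distance with the maximum intra-group distances.
    """
    unlabeled = [i for i in matrix.ids if i not in group_labels]
    if unlabeled:
        raise ValueError(f"unlabeled sequences: {unlabeled}")
    groups: dict[str, list[int]] = {}
    for idx, sid in enumerate(matrix.ids):
        groups.setdefault(group_labels[sid], []).append(idx)

    flagged: set[str] = set()
    member_medians: dict[str, float] = {}
    group_stats: dict[str, dict] = {}
    small = [g for g, idxs in groups.items() if len(idxs) < 3]
    for g, idxs in groups.items():
        sub = matrix.values[np.ix_(idxs, idxs)]
        if len(idxs) >= 2:
            intra = sub[np.triu_indices(len(idxs), k=1)]
            max_intra = float(intra.max()) if intra.size else 0.0
        else:
            max_intra = 0.0
        group_stats[g] = {"size": len(idxs), "max_intra": max_intra}
        if len(idxs) < 3:
            continue
        meds = np.array([np.median(np.delete(sub[r], r)) for r in range(len(idxs))])
        center = float(np.median(meds))
        mad = float(median_abs_deviation(meds))
        group_stats[g].update(median_of_medians=center, mad=mad)
        for r, idx in enumerate(idxs):
            member_medians[matrix.ids[idx]] = float(meds[r])
            if (meds[r] > center + k * mad and meds[r] > center
                    and (center == 0 or meds[r] > rel_factor * center)):
                flagged.add(matrix.ids[idx])

    separation: dict[tuple[str, str], dict] = {}
    names = sorted(groups)
    for a_i, ga in enumerate(names):
        for gb in names[a_i + 1:]:
            inter = matrix.values[np.ix_(groups[ga], groups[gb])]
            min_inter = float(inter.min())
            worst_intra = max(group_stats[ga]["max_intra"],
                              group_stats[gb]["max_intra"])
            separation[(ga, gb)] = {
                "min_inter": min_inter,
                "max_intra": worst_intra,
                "separated": min_inter > worst_intra,
            }
    return GroupOutlierReport(flagged, member_medians, group_stats,
                              separation, small)


# --------------------------------------------------------------------------
# circular rotation

def rotate(residues: str, offset: int) -> str:
    """Cut a circular sequence at ``offset`` (0-based) and relinearize."""
    offset %= len(residues)
    return residues[offset:] + residues[:offset]


def _identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(1 for x, y in zip(a[:n], b[:n]) if x == y) / n


def detect_rotation(seq: Sequence | str, reference: Sequence | str,
                    k: int = 12, margin: float = 0.05, stride: int = 16,
                    drift_window: int = 32,
                    min_support: float = 0.3) -> Optional[int]:
    """Detect a displaced start point of a circular genome.

    Candidate offsets are collected by k-mer seeding against the
    reference.  Small apparent offsets (within ``drift_window``) are the
    signature of ordinary indels, not rotations, and are never reported.
    A candidate must dominate the k-mer vote (at least ``min_support`` of
    the sampled k-mers, and more supporting votes than the zero-offset
    neighbourhood) and must improve ungapped identity over the as-is
    sequence by at least ``margin``.  Returns the offset such that
    :func:`correct_rotation` restores canonical numbering, or ``None``.
    """
    s = seq.residues if isinstance(seq, Sequence) else seq
    r = reference.residues if isinstance(reference, Sequence) else reference
    if not 0.8 <= len(s) / len(r) <= 1.2:
        raise ValueError("sequence and reference lengths differ by more than 20%")
    L = len(r)
    if L <= k:
        return None
    index: dict[str, list[int]] = {}
    for p in range(L - k + 1):
        index.setdefault(r[p:p + k], []).append(p)
    votes: dict[int, int] = {}
    sampled = 0
    for i in range(0, len(s) - k + 1, stride):
        sampled += 1
        for p in index.get(s[i:i + k], [])[:4]:
            o = (p - i) % L
            votes[o] = votes.get(o, 0) + 1

    def circ_near(o: int, c: int) -> bool:
        d = (o - c) % L
        return min(d, L - d) <= drift_window

    def mass(c: int) -> int:
        return sum(v for o, v in votes.items() if circ_near(o, c))

    zero_mass = mass(0)
    candidates = [o for o in sorted(votes, key=votes.get, reverse=True)
                  if not circ_near(o, 0)][:3]
    base = _identity(s, r)
    for o in candidates:
        if mass(o) < max(min_support * sampled, 1) or mass(o) <= zero_mass:
            continue
        gain = _identity(rotate(s, len(s) - (o % len(s))), r) - base
        if gain >= margin:
            return o
    return None


def correct_rotation(seq: Sequence, offset: int) -> Sequence:
    """Undo a start-point displacement so canonical position 1 leads."""
    if not 0 <= offset < len(seq):
        raise ValueError("offset out of range")
    if offset == 0:
        return seq
    return seq.with_residues(rotate(seq.residues, len(seq) - offset))
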