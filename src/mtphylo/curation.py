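"""Single-sequence quality tests and dataset tiering.

The tests mirror the empirical structure of public human-mtDNA
collections: complete genomes cluster tightly in length (16550-16600 bp
for the rCRS numbering, with nothing beyond 16600), genomes lacking the
control region sit below a characteristic length vacuum, and the space in
between holds rare but legitimate deletions that deserve review rather
than silent exclusion.  Composition tests count IUPAC ambiguity and long
N-runs; identity tests compress exact duplicates behind representatives.

All thresholds live in :class:`QcConfig` so the same rules scale to the
synthetic mini-genomes used in testing.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .sequences import Dataset, Sequence, UNAMBIGUOUS

__all__ = [
    "QcConfig",
    "QcReport",
    "LENGTH_CLASSES",
    "classify_length",
    "count_ambiguities",
    "ambiguity_covering",
    "find_n_runs",
    "deduplicate",
    "DuplicateGroups",
    "run_qc",
]

LENGTH_CLASSES = (
    "strict_ok",
    "flexible_no_control_region",
    "review_outlier",
    "reject_overlong",
)


@dataclass(frozen=True)
class QcConfig:
    """Curation thresholds.

    ``strict_length_range`` is closed on both ends; the review ranges and
    the control-region vacuum are half-open ``[lo, hi)``.  Defaults are
    the human-mtDNA values; :meth:`scaled` derives a consistent set for a
    synthetic reference of different length.
    """

    strict_length_range: tuple[int, int] = (16550, 16600)
    max_length: int = 16600
    control_region_vacuum: tuple[int, int] = (15600, 16300)
    review_ranges: tuple[tuple[int, int], ...] = ((16300, 16550),)
    ambiguity_threshold: int = 5
    ambiguity_fraction: Optional[float] = None
    n_run_min: int = 10
    strict_exclude: bool = False

    def __post_init__(self) -> None:
        for lo, hi in (self.strict_length_range, self.control_region_vacuum,
                       *self.review_ranges):
            if lo > hi:
                raise ValueError(f"ill-formed interval [{lo}, {hi})")
        if self.ambiguity_threshold < 0:
            raise ValueError("ambiguity_threshold must be >= 0")
        if self.n_run_min < 1:
            raise ValueError("n_run_min must be >= 1")

    @classmethod
    def scaled(cls, reference_length: int, control_region_length: int,
               **overrides) -> "QcConfig":
        """Thresholds for a reference of arbitrary size.

        The strict band brackets the reference length; the vacuum sits
        between the truncated (control-region-less) length and the review
        band, preserving the ordering of the human-scale defaults.
        """
        L = reference_length
        strict = (L - 50, L + 100)
        review = (L - 100, L - 50)
        vacuum = (min(L - control_region_length + 20, L - 130), L - 100)
        defaults = dict(strict_length_range=strict, max_length=strict[1],
                        control_region_vacuum=vacuum, review_ranges=(review,))
        defaults.update(overrides)
        return cls(**defaults)


def classify_length(seq: Sequence, cfg: QcConfig) -> str:
    """Length class of a raw sequence under the configured bands."""
    L = len(seq)
    lo, hi = cfg.strict_length_range
    vlo, vhi = cfg.control_region_vacuum
    if L > cfg.max_length:
        return "reject_overlong"
    if lo <= L <= hi:
        return "strict_ok"
    if any(rlo <= L < rhi for rlo, rhi in cfg.review_ranges):
        return "review_outlier"
    if vlo <= L < vhi:
        # inside the vacuum: no legitimate genome has this length
        return "review_outlier"
    if L < vlo:
        return "flexible_no_control_region"
    return "review_outlier"


def count_ambiguities(seq: Sequence | str) -> int:
    """Number of residues outside {A,C,G,T} (gaps, absent from raw
    sequences, are not counted)."""
    residues = seq if isinstance(seq, str) else seq.residues
    return sum(1 for c in residues if c not in UNAMBIGUOUS and c != "-")


def ambiguity_covering(dataset: Dataset, t: int) -> float:
    """Fraction of sequences with at most ``t`` ambiguous positions."""
    if len(dataset) == 0:
        raise ValueError("ambiguity covering undefined on an empty dataset")
    return sum(1 for s in dataset if count_ambiguities(s) <= t) / len(dataset)


_N_RUN = re.compile(r"N+")


def find_n_runs(seq: Sequence | str, n_run_min: int) -> list[tuple[int, int]]:
    """Maximal runs of 'N' of length >= n_run_min as (1-based start, length)."""
    if n_run_min < 1:
        raise ValueError("n_run_min must be >= 1")
    residues = seq if isinstance(seq, str) else seq.residues
    return [(m.start() + 1, m.end() - m.start())
            for m in _N_RUN.finditer(residues)
            if m.end() - m.start() >= n_run_min]


@dataclass
class DuplicateGroups:
    """Partition of a dataset by exact residue equality.

    ``groups`` maps each representative id (lexicographically smallest in
    its group) to the sorted list of member ids, singletons included, so
    final outputs can re-expand compressed members.
    """

    groups: dict[str, list[str]]

    @property
    def representatives(self) -> list[str]:
        return sorted(self.groups)

    @property
    def expansion_map(self) -> dict[str, str]:
        return {m: rep for rep, members in self.groups.items() for m in members}

    @property
    def n_compressed(self) -> int:
        return sum(len(m) - 1 for m in self.groups.values())


def deduplicate(dataset: Dataset) -> DuplicateGroups:
    """Group sequences by exact (plain, not ambiguity-aware) string equality."""
    by_residues: dict[str, list[str]] = {}
    for s in dataset:
        by_residues.setdefault(s.residues, []).append(s.id)
    groups = {min(ids): sorted(ids) for ids in by_residues.values()}
    return DuplicateGroups(groups)


@dataclass
class QcReport:
    """Per-sequence QC results and dataset-level summaries."""

    per_sequence: dict[str, dict]
    length_histogram: dict[int, int]
    covering_curve: list[float]
    duplicate_groups: DuplicateGroups

    def flagged_ids(self, flag: Optional[str] = None) -> set[str]:
        return {i for i, rec in self.per_sequence.items()
                if rec["flags"] and (flag is None or flag in rec["flags"])}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "per_sequence": {i: {**rec, "flags": sorted(rec["flags"])}
                             for i, rec in self.per_sequence.items()},
            "length_histogram": {str(k): v
                                 for k, v in sorted(self.length_histogram.items())},
            "covering_curve": self.covering_curve,
            "duplicate_groups": self.duplicate_groups.groups,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def run_qc(dataset: Dataset, cfg: QcConfig) -> tuple[QcReport, Dataset]:
    """Apply all single-sequence tests and assign curation tiers.

    Tier assignment: ``strict_ok`` -> strict; missing control region ->
    flexible; overlong -> excluded; review outliers stay in the strict
    tier but flagged (they are retained for completeness unless
    ``cfg.strict_exclude`` drops them).  Excess ambiguity and long N-runs
    flag a sequence without excluding it.  The returned dataset carries
    one provenance entry per rule application; re-running on the output
    is a no-op.
    """
    out = dataset.copy()
    per_seq: dict[str, dict] = {}
    max_ambig = 0
    for s in dataset:
        length_class = classify_length(s, cfg)
        ambig = count_ambiguities(s)
        runs = find_n_runs(s, cfg.n_run_min)
        max_ambig = max(max_ambig, ambig)
        flags: set[str] = set()

        tier = {"strict_ok": "strict",
                "flexible_no_control_region": "flexible",
                "reject_overlong": "excluded",
                "review_outlier": "excluded" if cfg.strict_exclude else "strict",
                }[length_class]
        if length_class != "strict_ok":
            flags.add(length_class)
            _record_once(out, length_class, s.id,
                         "excluded" if tier == "excluded" else "flagged")
        threshold = cfg.ambiguity_threshold
        if cfg.ambiguity_fraction is not None:
            threshold = max(threshold, int(cfg.ambiguity_fraction * len(s)))
        if ambig > threshold:
            flags.add("ambiguity_excess")
            _record_once(out, "ambiguity_excess", s.id,
                         f"flagged ({ambig} > {threshold})")
        if runs:
            flags.add("n_run")
            _record_once(out, "n_run", s.id, f"flagged (runs at {runs})")
        if s.tier != tier:
            out.replace_sequence(s.with_tier(tier))
        per_seq[s.id] = {
            "length": len(s), "length_class": length_class,
            "ambiguity_count": ambig,
            "max_n_run": max((l for _, l in runs), default=0),
            "tier": tier, "flags": flags,
        }

    dups = deduplicate(dataset)
    for rep, members in dups.groups.items():
        for m in members:
            if m != rep:
                per_seq[m]["flags"].add("duplicate")
                _record_once(out, "duplicate", m, f"represented by {rep}")

    histogram = Counter(len(s) for s in dataset)
    curve = [ambiguity_covering(dataset, t) for t in range(max_ambig + 1)] \
        if len(dataset) else []
    report = QcReport(per_seq, dict(histogram), curve, dups)
    out.validate()
    return report, out


def _record_once(out: Dataset, rule: str, seq_id: str, decision: str) -> None:
    """Append a provenance entry unless this rule already logged this
    sequence (keeps :func:`run_qc` idempotent)."""
    if not any(a.rule == rule and a.sequence_id == seq_id for a in out.log):
        out.record(rule, seq_id, decision)
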