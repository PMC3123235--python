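"""Core sequence and dataset containers.

Raw sequences are uppercase IUPAC DNA strings with ``U`` normalized to
``T``.  Gap characters are only legal in aligned material, never in raw
sequences.  A :class:`Dataset` couples a list of sequences with an
append-only provenance log so that every curation decision remains
auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

__all__ = [
    "IUPAC_CODES",
    "AMBIGUITY_SETS",
    "UNAMBIGUOUS",
    "Sequence",
    "CurationAction",
    "Dataset",
    "iupac_set",
]

#: IUPAC nucleotide one-letter codes (DNA), gap included for aligned rows.
AMBIGUITY_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "-": frozenset("-"),
}

IUPAC_CODES: frozenset[str] = frozenset(AMBIGUITY_SETS)
UNAMBIGUOUS: frozenset[str] = frozenset("ACGT")

#: Tier labels used throughout curation.
TIERS = ("strict", "flexible", "excluded", "unclassified")


def iupac_set(symbol: str) -> frozenset[str]:
    """Base set denoted by an IUPAC symbol ('-' denotes the gap state)."""
    try:
        return AMBIGUITY_SETS[symbol]
    except KeyError:
        raise ValueError(f"not an IUPAC DNA symbol: {symbol!r}") from None


def normalize_residues(raw: str) -> str:
    """Uppercase and map U->T; validation is left to the caller."""
    return raw.upper().replace("U", "T")


@dataclass(frozen=True)
class Sequence:
    """A single (usually mitochondrial) genome sequence.

    Parameters
    ----------
    id
        Unique identifier (e.g. an accession).
    residues
        Uppercase residue string over the IUPAC DNA alphabet.  Raw
        sequences must not contain ``'-'``: gaps neither have meaning nor
        are expected before alignment.
    species
        Species label used for group-wise analyses.
    source
        Free-text provenance (study, submitter, file of origin).
    tier
        Curation tier; new sequences start ``unclassified``.
    """

    id: str
    residues: str
    species: str = ""
    source: str = ""
    tier: str = "unclassified"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"{self.id}: residues must be non-empty")
        if self.tier not in TIERS:
            raise ValueError(f"{self.id}: unknown tier {self.tier!r}")
        bad = set(self.residues) - IUPAC_CODES
        if bad:
            pos = next(i for i, c in enumerate(self.residues) if c in bad)
            raise ValueError(
                f"{self.id}: invalid symbol {self.residues[pos]!r} at position {pos + 1}"
            )
        if "-" in self.residues:
            raise ValueError(f"{self.id}: raw sequences must not contain gaps")

    @classmethod
    def from_raw(cls, id: str, raw: str, **kwargs) -> "Sequence":
        """Build a sequence from arbitrary-case input, normalizing U->T."""
        return cls(id=id, residues=normalize_residues(raw), **kwargs)

    def __len__(self) -> int:
        return len(self.residues)

    def with_residues(self, residues: str) -> "Sequence":
        return replace(self, residues=residues)

    def with_tier(self, tier: str) -> "Sequence":
        return replace(self, tier=tier)


@dataclass(frozen=True)
class CurationAction:
    """One provenance-log entry: which rule touched which sequence, and how."""

    rule: str
    sequence_id: str
    decision: str


class Dataset:
    """An ordered collection of sequences plus its curation log.

    Sequence ids are unique; every *excluded* sequence must be justified by
    at least one log entry, which :meth:`validate` enforces.
    """

    def __init__(self, sequences: Iterable[Sequence] = (),
                 log: Iterable[CurationAction] = ()) -> None:
        self.sequences: list[Sequence] = list(sequences)
        self.log: list[CurationAction] = list(log)
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dup}")
        self._index = {s.id: i for i, s in enumerate(self.sequences)}

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[Sequence]:
        return iter(self.sequences)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def get(self, seq_id: str) -> Sequence:
        return self.sequences[self._index[seq_id]]

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def record(self, rule: str, seq_id: str, decision: str) -> None:
        self.log.append(CurationAction(rule, seq_id, decision))

    def replace_sequence(self, seq: Sequence) -> None:
        self.sequences[self._index[seq.id]] = seq

    def copy(self) -> "Dataset":
        return Dataset(self.sequences, self.log)

    def validate(self) -> None:
        logged = {a.sequence_id for a in self.log}
        for s in self.sequences:
            if s.tier == "excluded" and s.id not in logged:
                raise ValueError(f"excluded sequence {s.id} has no log entry")
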