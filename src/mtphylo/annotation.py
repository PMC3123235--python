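"""Reference structural annotation: genes, non-coding gaps, control region.

The reference genome (the rCRS for human mtDNA) defines "canonical"
coordinates, 1-based and inclusive.  Its feature table is decomposed into
an ordered list of structural units that jointly cover every reference
position: annotated genes, one non-coding gap per maximal unannotated
interval, and the control region split into the two parts created by the
circular numbering origin.  Units drive partitioned alignment downstream.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .sequences import Sequence, normalize_residues

__all__ = [
    "StructuralUnit",
    "ReferenceAnnotation",
    "read_reference_annotation",
    "rcrs_annotation",
]

UNIT_KINDS = ("gene", "noncoding_gap", "control_region_part")

#: Canonical position of the historical 'N' placeholder in the rCRS: an
#: artificial pseudodeletion kept to preserve the original numbering.
RCRS_FALSE_GAP_POSITIONS = (3107,)


@dataclass(frozen=True)
class StructuralUnit:
    """One structural unit in reference coordinates (1-based, inclusive)."""

    name: str
    kind: str
    start: int
    end: int
    coding: bool = False
    reading_frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.kind not in UNIT_KINDS:
            raise ValueError(f"unknown unit kind {self.kind!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"{self.name}: bad interval {self.start}..{self.end}")
        if self.coding and self.kind != "gene":
            raise ValueError(f"{self.name}: only genes may be coding")
        if not 0 <= self.reading_frame_offset <= 2:
            raise ValueError(f"{self.name}: reading frame offset out of range")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "StructuralUnit") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class ReferenceAnnotation:
    """A reference sequence plus its ordered structural units.

    The unit intervals must cover every reference position, and only units
    adjacent in start order may overlap (overlapping genes such as ATP8 /
    ATP6 are carried in both units and reconciled at merge time).
    """

    reference: Sequence
    units: list[StructuralUnit]
    circular: bool = True
    false_gap_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.units = sorted(self.units, key=lambda u: (u.start, u.end))
        self.validate()

    @property
    def length(self) -> int:
        return len(self.reference)

    def unit(self, name: str) -> StructuralUnit:
        for u in self.units:
            if u.name == name:
                return u
        raise KeyError(name)

    def validate(self) -> None:
        n = self.length
        covered = [False] * (n + 1)
        for u in self.units:
            if u.end > n:
                raise ValueError(f"{u.name} extends past reference end ({u.end} > {n})")
            for p in range(u.start, u.end + 1):
                covered[p] = True
        missing = [p for p in range(1, n + 1) if not covered[p]]
        if missing:
            raise ValueError(
                f"reference positions not covered by any unit (first: {missing[0]})"
            )
        for i, u in enumerate(self.units):
            for v in self.units[i + 2:]:
                if u.overlaps(v):
                    raise ValueError(
                        f"non-adjacent units overlap: {u.name} and {v.name}"
                    )

    def adjacent_overlap(self, left: StructuralUnit, right: StructuralUnit) -> int:
        """Width of the shared interval between two start-ordered neighbours."""
        if left.end >= right.start:
            return left.end - right.start + 1
        return 0


def _feature_gene_name(feature) -> str:
    q = feature.qualifiers
    for key in ("gene", "product", "locus_tag"):
        if key in q:
            return str(q[key][0]).replace(" ", "_")
    return f"{feature.type}_{int(feature.location.start) + 1}"


def read_reference_annotation(path: str | Path,
                              reference_fasta: str | Path | None = None,
                              ) -> ReferenceAnnotation:
    """Parse a GenBank flat file into a :class:`ReferenceAnnotation`.

    Gene-level features (CDS, tRNA, rRNA; plain ``gene`` features only when
    no finer-grained feature covers the same interval) become ``gene``
    units.  A D-loop / control-region feature is split into one unit per
    contiguous span, so a feature wrapping the numbering origin yields the
    two canonical control-region parts.  Every maximal interval covered by
    no feature becomes a ``noncoding_gap`` unit.

    The sequence block is optional; pass ``reference_fasta`` to supply the
    residues separately when the GenBank file carries only the feature
    table.
    """
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        record = SeqIO.read(str(path), "genbank")
    if not record.features:
        raise ValueError(f"{path}: GenBank record has no feature table")

    ref_len = len(record)
    residues = None
    try:
        residues = normalize_residues(str(record.seq))
    except Exception:
        residues = None
    if not residues:
        if reference_fasta is not None:
            rec = SeqIO.read(str(reference_fasta), "fasta")
            residues = normalize_residues(str(rec.seq))
            if len(residues) != ref_len:
                raise ValueError(
                    f"reference FASTA length {len(residues)} != record length {ref_len}"
                )
        else:
            # Feature-table-only record: placeholder residues; fine for
            # partition geometry, not for alignment.
            residues = "N" * ref_len

    units: list[StructuralUnit] = []
    gene_like = {"CDS", "tRNA", "rRNA"}
    fine_intervals: list[tuple[int, int]] = []
    for f in record.features:
        if f.type in gene_like:
            fine_intervals.append((int(f.location.start) + 1, int(f.location.end)))
    for f in record.features:
        if f.type in gene_like:
            start, end = int(f.location.start) + 1, int(f.location.end)
            frame = 0
            coding = f.type == "CDS"
            if coding and "codon_start" in f.qualifiers:
                frame = int(f.qualifiers["codon_start"][0]) - 1
            units.append(StructuralUnit(_feature_gene_name(f), "gene",
                                        start, end, coding, frame))
        elif f.type == "gene":
            start, end = int(f.location.start) + 1, int(f.location.end)
            if not any(s <= start and end <= e for s, e in fine_intervals):
                units.append(StructuralUnit(_feature_gene_name(f), "gene", start, end))
        elif f.type in ("D-loop", "misc_feature") and (
                f.type == "D-loop"
                or "control region" in str(f.qualifiers.get("note", "")).lower()):
            parts = sorted(f.location.parts, key=lambda p: int(p.start))
            for k, part in enumerate(parts, 1):
                units.append(StructuralUnit(
                    f"control_region_{k}" if len(parts) > 1 else "control_region_1",
                    "control_region_part", int(part.start) + 1, int(part.end)))

    if not units:
        raise ValueError(f"{path}: no gene or control-region features found")

    # Derive non-coding gaps: maximal intervals covered by no unit so far.
    covered = [False] * (ref_len + 2)
    for u in units:
        for p in range(u.start, u.end + 1):
            covered[p] = True
    gaps: list[StructuralUnit] = []
    p = 1
    while p <= ref_len:
        if not covered[p]:
            q = p
            while q + 1 <= ref_len and not covered[q + 1]:
                q += 1
            gaps.append(StructuralUnit(f"nc_{p}_{q}", "noncoding_gap", p, q))
            p = q + 1
        else:
            p += 1
    units.extend(gaps)

    circular = record.annotations.get("topology", "") == "circular"
    false_gaps = RCRS_FALSE_GAP_POSITIONS if record.id.startswith("NC_012920") else ()
    ref = Sequence(id=record.id or path.stem, residues=residues,
                   species=str(record.annotations.get("organism", "")),
                   source=str(path))
    return ReferenceAnnotation(ref, units, circular=circular,
                               false_gap_positions=false_gaps)


def write_genbank_features(annotation: ReferenceAnnotation,
                           path: str | Path) -> None:
    """Write the annotation as a minimal GenBank flat file (features only).

    Genes become CDS/tRNA-style entries, the two control-region parts are
    re-joined into one origin-spanning D-loop feature; non-coding gaps are
    omitted because :func:`read_reference_annotation` re-derives them.
    The sequence block is omitted; ship the residues as FASTA alongside.
    """
    L = annotation.length
    lines = [
        f"LOCUS       {annotation.reference.id:<18} {L:>7} bp    DNA     "
        f"{'circular' if annotation.circular else 'linear  '} SYN 01-JAN-2000",
        f"DEFINITION  {annotation.reference.id} structural annotation "
        "(feature table only).",
        f"ACCESSION   {annotation.reference.id}",
        "FEATURES             Location/Qualifiers",
        f"     source          1..{L}",
    ]
    cr = sorted((u for u in annotation.units
                 if u.kind == "control_region_part"), key=lambda u: u.start)
    if len(cr) == 2 and cr[0].start == 1 and cr[1].end == L:
        lines.append(f"     D-loop          join({cr[1].start}..{cr[1].end},"
                     f"1..{cr[0].end})")
    else:
        for u in cr:
            lines.append(f"     D-loop          {u.start}..{u.end}")
    for u in annotation.units:
        if u.kind != "gene":
            continue
        ftype = "CDS" if u.coding else "misc_RNA"
        lines.append(f"     {ftype:<15} {u.start}..{u.end}")
        lines.append(f'                     /gene="{u.name}"')
        if u.coding:
            lines.append(f"                     /codon_start="
                         f"{u.reading_frame_offset + 1}")
    lines += ["ORIGIN", "//", ""]
    Path(path).write_text("\n".join(lines))


def rcrs_annotation(reference_fasta: str | Path | None = None) -> ReferenceAnnotation:
    """The bundled rCRS structural annotation (feature table only).

    Residues are ``N`` placeholders unless a FASTA with the real sequence
    is supplied; the partition geometry (50 units) does not depend on them.
    """
    data = importlib.resources.files("mtphylo.data") / "rcrs_features_reconstructed.gb"
    with importlib.resources.as_file(data) as p:
        return read_reference_annotation(p, reference_fasta)
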