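"""Multiple-alignment container with an explicit column -> reference map.

Columns are 0-based internally; ``colmap[j]`` holds the 1-based canonical
reference position homologous to column ``j``, or ``None`` for an
insertion column.  Reference positions must be strictly increasing along
the alignment where present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence as Seq

import numpy as np

__all__ = ["Alignment"]


@dataclass
class Alignment:
    """Equal-length aligned rows keyed by sequence id.

    Parameters
    ----------
    ids
        Row order.
    rows
        Mapping id -> aligned residue string (may include ``'-'``).
    colmap
        Per-column 1-based reference position, or ``None`` for insertion
        columns.  ``None`` for the whole attribute means "unmapped"
        (e.g. bootstrap replicates, where column identity is resampled).
    unsequenced
        Optional id -> boolean array marking columns that are gap-padded
        because the region was never sequenced (as opposed to a
        biological deletion).
    """

    ids: list[str]
    rows: dict[str, str]
    colmap: Optional[list[Optional[int]]] = None
    unsequenced: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError("alignment has no rows")
        if set(self.ids) != set(self.rows):
            raise ValueError("ids and rows disagree")
        lengths = {len(self.rows[i]) for i in self.ids}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        n = lengths.pop()
        if self.colmap is not None:
            if len(self.colmap) != n:
                raise ValueError("colmap length != number of columns")
            ref = [p for p in self.colmap if p is not None]
            if any(b <= a for a, b in zip(ref, ref[1:])):
                raise ValueError("reference positions in colmap must increase")
        for i, mask in self.unsequenced.items():
            if len(mask) != n:
                raise ValueError(f"unsequenced mask for {i} has wrong length")

    @property
    def ncols(self) -> int:
        return len(self.rows[self.ids[0]])

    @property
    def nrows(self) -> int:
        return len(self.ids)

    def row(self, seq_id: str) -> str:
        return self.rows[seq_id]

    def column(self, j: int) -> str:
        return "".join(self.rows[i][j] for i in self.ids)

    def degapped(self, seq_id: str) -> str:
        return self.rows[seq_id].replace("-", "")

    def matrix(self) -> np.ndarray:
        """Rows as a (nrows, ncols) array of single-byte strings."""
        return np.array([list(self.rows[i]) for i in self.ids], dtype="U1")

    def take_columns(self, indices: Seq[int]) -> "Alignment":
        """New alignment restricted to (possibly repeated) column indices.

        Column identity is not preserved under resampling, so the result
        carries no colmap.
        """
        rows = {i: "".join(self.rows[i][j] for j in indices) for i in self.ids}
        unseq = {i: m[list(indices)] for i, m in self.unsequenced.items()}
        return Alignment(list(self.ids), rows, colmap=None, unsequenced=unseq)

    def subset(self, ids: Iterable[str]) -> "Alignment":
        keep = [i for i in self.ids if i in set(ids)]
        return Alignment(keep, {i: self.rows[i] for i in keep},
                         colmap=list(self.colmap) if self.colmap else None,
                         unsequenced={i: m for i, m in self.unsequenced.items()
                                      if i in set(keep)})

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for i in self.ids:
                fh.write(f">{i}\n")
                row = self.rows[i]
                for k in range(0, len(row), width):
                    fh.write(row[k:k + width] + "\n")

    def write_colmap(self, path: str | Path) -> None:
        """Column map as TSV: column index, reference position or 'ins'."""
        if self.colmap is None:
            raise ValueError("alignment has no column map")
        with open(path, "w") as fh:
            fh.write("column\treference_position\n")
            for j, p in enumerate(self.colmap):
                fh.write(f"{j}\t{'ins' if p is None else p}\n")

    @classmethod
    def from_rows(cls, pairs: Iterable[tuple[str, str]],
                  colmap: Optional[list[Optional[int]]] = None) -> "Alignment":
        pairs = list(pairs)
        return cls([i for i, _ in pairs], dict(pairs), colmap=colmap)
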