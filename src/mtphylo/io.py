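"""Readers and writers: FASTA datasets, newick trees, phyloXML documents.

Standard formats go through established parsers (Biopython for FASTA and
GenBank, dendropy for newick, Biopython's phyloXML support for annotated
trees); this module only adapts them to the package's domain types.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping, Optional

import dendropy
from Bio import Phylo, SeqIO
from Bio.Phylo import PhyloXML

from .alignment import Alignment
from .sequences import Dataset, IUPAC_CODES, Sequence, normalize_residues

__all__ = [
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "read_alignment_fasta",
    "read_newick",
    "write_newick",
    "write_phyloxml",
    "read_phyloxml",
    "leaf_bipartitions",
]


class FastaParseError(ValueError):
    pass


def _line_of_record(path: Path, record_id: str) -> int:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">") and line[1:].split()[0] == record_id:
                return lineno
    return 0


def read_fasta(path: str | Path, species: str = "",
               tier: str = "unclassified") -> Dataset:
    """Read a multi-FASTA file into a :class:`Dataset` of raw sequences.

    Residues are uppercased and U is normalized to T.  Any symbol outside
    the IUPAC DNA alphabet, or a gap character, is a parse error naming
    the offending record's line.  An empty file yields an empty dataset
    with a warning entry in the log.
    """
    path = Path(path)
    sequences = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = normalize_residues(str(rec.seq))
        bad = set(residues) - IUPAC_CODES | (set(residues) & {"-"})
        if bad or not residues:
            line = _line_of_record(path, rec.id)
            what = f"invalid symbol(s) {sorted(bad)}" if bad else "empty record"
            raise FastaParseError(
                f"{path}:{line}: record {rec.id!r}: {what} (IUPAC DNA expected)")
        sequences.append(Sequence(id=rec.id, residues=residues,
                                  species=species, source=str(path), tier=tier))
    ds = Dataset(sequences)
    if not sequences:
        ds.record("read_fasta", "-", f"warning: empty FASTA file {path}")
    return ds


def write_fasta(dataset_or_seqs: Dataset | Iterable[Sequence],
                path: str | Path, width: int = 70) -> None:
    seqs = list(dataset_or_seqs)
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for k in range(0, len(s.residues), width):
                fh.write(s.residues[k:k + width] + "\n")


def read_alignment_fasta(path: str | Path) -> Alignment:
    """Read equal-length gapped FASTA rows into an :class:`Alignment`."""
    pairs = [(rec.id, normalize_residues(str(rec.seq)))
             for rec in SeqIO.parse(str(path), "fasta")]
    if not pairs:
        raise FastaParseError(f"{path}: no records")
    return Alignment.from_rows(pairs)


# --------------------------------------------------------------------------
# newick

def read_newick(path_or_string: str | Path) -> dendropy.Tree:
    p = Path(str(path_or_string))
    kwargs = dict(schema="newick", preserve_underscores=True,
                  suppress_internal_node_taxa=True)
    if p.exists():
        return dendropy.Tree.get(path=str(p), **kwargs)
    return dendropy.Tree.get(data=str(path_or_string), **kwargs)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write a tree as newick with branch lengths and internal-node labels.

    Internal labels carry support values when present; labels containing
    newick-reserved characters are quoted by the writer.
    """
    tree.write(path=str(path), schema="newick", unquoted_underscores=True,
               suppress_rooting=True)


# --------------------------------------------------------------------------
# phyloXML

def _as_phyloxml(tree: dendropy.Tree) -> PhyloXML.Phylogeny:
    newick = tree.as_string(schema="newick", unquoted_underscores=True,
                            suppress_rooting=True)
    bp = Phylo.read(_io.StringIO(newick), "newick")
    return PhyloXML.Phylogeny.from_tree(bp)


def write_phyloxml(tree: dendropy.Tree,
                   annotations: Optional[Mapping[str, Iterable[Mapping]]],
                   path: str | Path) -> None:
    """Write a tree as phyloXML, with per-branch mutation annotations.

    ``annotations`` maps a node name (the child end of a branch) to an
    iterable of mutation records; each record is serialized as one
    ``<property>`` element applying to the parent branch, in the compact
    form ``position|ref_position|from>to|flags``.
    """
    phy = _as_phyloxml(tree)
    by_name = {}
    for clade in phy.find_clades():
        if clade.name:
            by_name[clade.name] = clade
        # newick readers may park internal labels in .confidence
        if clade.confidence is not None and not clade.name:
            by_name.setdefault(str(clade.confidence), clade)
    for name, events in (annotations or {}).items():
        if name not in by_name:
            raise ValueError(f"annotated branch {name!r} not found in tree")
        clade = by_name[name]
        for ev in events:
            try:
                value = "{column}|{ref}|{frm}>{to}|{flags}".format(
                    column=ev["column"],
                    ref=ev.get("ref_position", "ins"),
                    frm=ev["from_state"], to=ev["to_state"],
                    flags=",".join(sorted(ev.get("flags", ()))))
            except (KeyError, TypeError) as exc:
                raise ValueError(
                    f"unserializable annotation on branch {name!r}: {exc}") from exc
            clade.properties.append(PhyloXML.Property(
                value, ref="mtphylo:mutation", applies_to="parent_branch",
                datatype="xsd:string"))
    phyloxml = PhyloXML.Phyloxml({}, phylogenies=[phy])
    Phylo.PhyloXMLIO.write(phyloxml, str(path))


def read_phyloxml(path: str | Path) -> PhyloXML.Phylogeny:
    return Phylo.read(str(path), "phyloxml")


# --------------------------------------------------------------------------
# topology helpers

def leaf_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as leaf-label sets on the smaller side.

    Each internal edge contributes the frozenset of leaf labels on one
    side, normalized to the side *not* containing the alphabetically
    first leaf, so that sets from differently rooted copies compare equal.
    """
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    anchor = min(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if anchor in side:
            side = leaves - side
        if 1 < len(side) < len(leaves) - 1:
            out.add(frozenset(side))
    return out
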