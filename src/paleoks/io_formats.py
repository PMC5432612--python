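"""Readers and writers for every external representation the pipeline touches.

All gene identifiers are species-prefixed as ``"<species>|<gene>"`` so that
within- vs between-species classification never needs an external map.
Coding sequences may carry a single terminal stop codon (common in
transcriptome-derived ORFs); it is stripped on validation. Internal stop
codons are fatal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import dendropy
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "HitRecord",
    "AnnotationTable",
    "FormatError",
    "species_of",
    "read_fasta",
    "write_fasta",
    "validate_cds",
    "read_hit_table",
    "write_hit_table",
    "convert_blast_tabular",
    "read_annotations",
    "read_gene_list",
    "write_gene_list",
    "read_newick",
    "write_newick",
]

_NUCLEOTIDES = set("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class FormatError(ValueError):
    """Raised when an input file violates its dialect or an invariant."""


@dataclass
class SequenceRecord:
    """A nucleotide sequence with a unique, species-prefixed identifier."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.residues:
            raise FormatError(f"sequence {self.id!r} is empty")
        bad = [
            (i, c) for i, c in enumerate(self.residues) if c not in _NUCLEOTIDES
        ]
        if bad:
            pos, char = bad[0]
            raise FormatError(
                f"sequence {self.id!r}: non-nucleotide character {char!r} "
                f"at position {pos + 1}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def species_of(gene_id: str) -> str:
    """Species prefix of a ``"<species>|<gene>"`` identifier."""
    sp, sep, _ = gene_id.partition("|")
    if not sep or not sp:
        raise FormatError(f"gene id {gene_id!r} lacks a '<species>|' prefix")
    return sp


def validate_cds(record: SequenceRecord, strip_terminal_stop: bool = True) -> SequenceRecord:
    """Check frame and stop-codon invariants; strip a single terminal stop.

    A CDS must have length divisible by 3 and no in-frame stop codon except,
    optionally, at the terminus (stripped before analysis).
    """
    seq = record.residues
    if len(seq) % 3 != 0:
        raise FormatError(f"CDS {record.id!r}: length {len(seq)} not divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if strip_terminal_stop and codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
        if not codons:
            raise FormatError(f"CDS {record.id!r}: nothing left after stripping stop")
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise FormatError(
                f"CDS {record.id!r}: internal stop codon {codon} at codon {i + 1}"
            )
    return SequenceRecord(record.id, "".join(codons), record.description)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a nucleotide FASTA file into validated records.

    Residues are uppercased, record order is preserved, and duplicate
    identifiers are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id) :].strip()
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with bodies wrapped at ``width`` columns."""
    if width < 1:
        raise ValueError("width must be positive")
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


@dataclass(frozen=True)
class HitRecord:
    """One row of an all-vs-all protein similarity search."""

    query: str
    subject: str
    identity: float
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise FormatError(
                f"hit {self.query}~{self.subject}: identity {self.identity} not in [0,100]"
            )
        if self.evalue < 0 or not math.isfinite(self.evalue):
            raise FormatError(
                f"hit {self.query}~{self.subject}: E-value {self.evalue} invalid"
            )


_HIT_COLUMNS = ["query", "subject", "identity", "evalue", "bitscore"]


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Read the named-header 5-column hit table.

    Self-hits are retained here; the graph builder drops them. Malformed rows
    are reported with their line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_HIT_COLUMNS)] != _HIT_COLUMNS:
            raise FormatError(
                f"{path}: expected header columns {_HIT_COLUMNS}, got {header}"
            )
        hits: list[HitRecord] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            try:
                hits.append(
                    HitRecord(parts[0], parts[1], float(parts[2]), float(parts[3]), float(parts[4]))
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(f"{h.query}\t{h.subject}\t{h.identity:g}\t{h.evalue:g}\t{h.bitscore:g}\n")


def convert_blast_tabular(path: str | Path, out_path: str | Path) -> int:
    """Convert standard 12-column tabular alignment output to the 5-column dialect.

    Returns the number of rows converted. Columns used: 1 query, 2 subject,
    3 percent identity, 11 E-value, 12 bit score.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 12:
        raise FormatError(f"{path}: expected ≥12 tab-separated columns, got {df.shape[1]}")
    out = df.iloc[:, [0, 1, 2, 10, 11]]
    out.columns = _HIT_COLUMNS
    out.to_csv(out_path, sep="\t", index=False)
    return len(out)


@dataclass
class AnnotationTable:
    """Gene → categories mapping for one ontology (GO/COG/KEGG/TF/...)."""

    ontology: str
    entries: dict[str, set[str]] = field(default_factory=dict)

    def categories(self) -> set[str]:
        out: set[str] = set()
        for cats in self.entries.values():
            out |= cats
        return out

    def restrict(self, genes: Iterable[str]) -> "AnnotationTable":
        genes = set(genes)
        return AnnotationTable(
            self.ontology,
            {g: set(c) for g, c in self.entries.items() if g in genes},
        )


def read_annotations(path: str | Path, ontology: str = "GO") -> AnnotationTable:
    """Read a two-column TSV of (gene id, category id) pairs into sets."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = AnnotationTable(ontology)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise FormatError(f"{path}:{lineno}: blank gene or category field")
            table.entries.setdefault(parts[0], set()).add(parts[1])
    return table


def read_gene_list(path: str | Path) -> set[str]:
    """Read a plain-text list of gene ids, one per line (e.g. TE flags)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.add(line)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def _check_tree(tree: dendropy.Tree) -> dendropy.Tree:
    names = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise FormatError(f"duplicate leaf names in tree: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise FormatError(f"negative branch length {edge.length} in tree")
    return tree


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree with branch lengths (dendropy representation)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"{path}: malformed Newick ({exc})") from exc
    return _check_tree(tree)


def parse_newick(text: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:
        raise FormatError(f"malformed Newick ({exc})") from exc
    return _check_tree(tree)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
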