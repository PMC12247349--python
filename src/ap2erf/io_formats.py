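"""Readers and writers for the external formats the pipeline touches.

Coordinates are 1-based, fully closed intervals (NCBI feature-table
convention). The coordinate contract is a flat tab-separated table distilled
from a genome annotation, not GFF3 itself. Strand is carried through but
never used by downstream arithmetic; all distance and overlap criteria are
strand-agnostic.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "DomainHit",
    "GeneCoordinate",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_domain_table",
    "write_domain_table",
    "read_coordinates",
    "write_coordinates",
    "write_newick",
]

AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZJUO*")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record: identifier, free-text description, residues."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty identifier")
        if not self.residues:
            raise FormatError(f"sequence record {self.id!r} has no residues")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DomainHit:
    """One profile-domain match on a protein (1-based inclusive coords)."""

    protein_id: str
    profile: str
    evalue: float
    ali_start: int
    ali_end: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.evalue) or self.evalue < 0:
            raise FormatError(
                f"domain hit on {self.protein_id!r}: E-value must be finite and >= 0"
            )
        if self.ali_start < 1 or self.ali_end < self.ali_start:
            raise FormatError(
                f"domain hit on {self.protein_id!r}: bad alignment coordinates "
                f"({self.ali_start}, {self.ali_end})"
            )


@dataclass(frozen=True)
class GeneCoordinate:
    """Gene placement for one transcript/protein of one gene.

    ``chromosome`` is kept verbatim so allopolyploid subgenome suffixes
    ('1c', '1e', ...) and unplaced contig names survive parsing.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exon_count: int
    protein_id: str
    transcript_id: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise FormatError(f"gene {self.gene_id!r}: start must be >= 1")
        if self.end < self.start:
            raise FormatError(
                f"gene {self.gene_id!r}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if self.exon_count < 1:
            raise FormatError(f"gene {self.gene_id!r}: exon_count must be >= 1")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Residues are uppercased and whitespace-stripped; record order is
    preserved. Raises :class:`FormatError` on an empty file or a duplicate
    identifier.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate identifier {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = re.sub(r"\s+", "", str(rec.seq)).upper()
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, residues=residues, description=desc))
    if not records:
        raise FormatError(f"no records in FASTA file {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# --- domain-hit tables ----------------------------------------------------

# hmmscan/hmmsearch --domtblout column indices (whitespace-separated):
# 0 target name, 3 query name, 6 full-seq E-value, 12 i-Evalue (independent),
# 17 ali from, 18 ali to.  For hmmsearch the *protein* is the target and the
# profile is the query; that orientation is assumed here.
_DOMTBL_MIN_COLS = 23


def read_domain_table(path: str | Path, dialect: str = "tsv") -> list[DomainHit]:
    """Parse per-domain hits from a table.

    ``dialect='hmmer_domtblout'`` reads HMMER3 ``--domtblout`` output
    (protein as target, profile as query; independent E-value, alignment
    coordinates). ``dialect='tsv'`` reads a five-column table:
    protein_id, profile, evalue, ali_start, ali_end.
    """
    if dialect not in ("tsv", "hmmer_domtblout"):
        raise ValueError(f"unknown domain-table dialect {dialect!r}")
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                if dialect == "tsv":
                    if len(fields) < 5:
                        raise ValueError("expected 5 columns")
                    hit = DomainHit(
                        protein_id=fields[0],
                        profile=fields[1],
                        evalue=float(fields[2]),
                        ali_start=int(fields[3]),
                        ali_end=int(fields[4]),
                    )
                else:
                    if len(fields) < _DOMTBL_MIN_COLS:
                        raise ValueError("truncated domtblout row")
                    hit = DomainHit(
                        protein_id=fields[0],
                        profile=fields[3],
                        evalue=float(fields[12]),
                        ali_start=int(fields[17]),
                        ali_end=int(fields[18]),
                    )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}: malformed row at line {lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_domain_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in the five-column TSV dialect."""
    with open(path, "w") as fh:
        fh.write("# protein_id\tprofile\tevalue\tali_start\tali_end\n")
        for h in hits:
            fh.write(f"{h.protein_id}\t{h.profile}\t{h.evalue:g}\t{h.ali_start}\t{h.ali_end}\n")


# --- coordinate tables ----------------------------------------------------

_COORD_COLUMNS = [
    "gene_id",
    "chromosome",
    "start",
    "end",
    "strand",
    "exon_count",
    "protein_id",
    "transcript_id",
]


def read_coordinates(path: str | Path) -> list[GeneCoordinate]:
    """Read the gene-coordinate TSV (header row naming the eight fields)."""
    records: list[GeneCoordinate] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").lstrip("#").strip().split("\t")
        header = [h.strip() for h in header]
        if set(_COORD_COLUMNS) - set(header):
            missing = sorted(set(_COORD_COLUMNS) - set(header))
            raise FormatError(f"{path}: coordinate header missing columns {missing}")
        idx = {name: header.index(name) for name in _COORD_COLUMNS}
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                rec = GeneCoordinate(
                    gene_id=f[idx["gene_id"]],
                    chromosome=f[idx["chromosome"]],
                    start=int(f[idx["start"]]),
                    end=int(f[idx["end"]]),
                    strand=f[idx["strand"]],
                    exon_count=int(f[idx["exon_count"]]),
                    protein_id=f[idx["protein_id"]],
                    transcript_id=f[idx["transcript_id"]],
                )
            except (IndexError, ValueError, FormatError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            key = (rec.gene_id, rec.transcript_id)
            if key in seen:
                raise FormatError(
                    f"{path}: duplicate (gene_id, transcript_id) {key} at line {lineno}"
                )
            seen.add(key)
            records.append(rec)
    return records


def write_coordinates(records: Iterable[GeneCoordinate], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_COORD_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.chromosome}\t{r.start}\t{r.end}\t{r.strand}\t"
                f"{r.exon_count}\t{r.protein_id}\t{r.transcript_id}\n"
            )


# --- Newick ---------------------------------------------------------------

_NEWICK_UNSAFE = re.compile(r"[\s()\[\]:;,']")


def _newick_label(label: str) -> str:
    # whitespace is underscored; any remaining metacharacter forces quoting
    label = re.sub(r"\s", "_", label)
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree, path: str | Path) -> None:
    """Serialize a phylogeny-module tree to standard Newick with lengths."""
    with open(path, "w") as fh:
        fh.write(newick_string(tree))
        fh.write("\n")


def newick_string(tree) -> str:
    def render(node) -> str:
        if node.is_leaf:
            return f"{_newick_label(node.label)}:{node.length:.10g}"
        inner = ",".join(render(c) for c in node.children)
        if node.parent is None:
            return f"({inner})"
        return f"({inner}):{node.length:.10g}"

    return render(tree.root) + ";"
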