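"""Sequence, alignment and feature-table I/O.

All coordinates handled by this package are 1-based and inclusive, both for
GFF3 gene records (the GFF3 convention) and for positions inside protein
sequences. Gap characters '.' and '-' are both accepted on input and
normalized to '-'; output always uses '-'.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS = set("XBZUO")
_VALID_RESIDUES = set(AMINO_ACIDS) | AMBIGUOUS


class FormatError(ValueError):
    """Raised for malformed or contract-violating input files."""


@dataclass
class Sequence:
    """A protein sequence with a unique identifier."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence id must be non-empty")
        self.residues = self.residues.upper()
        if not self.residues:
            raise FormatError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains invalid residues: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """A multiple protein alignment; all rows have equal aligned length."""

    rows: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rows:
            n = len(self.rows[0].residues)
            for r in self.rows:
                if len(r.residues) != n:
                    lengths = {s.id: len(s.residues) for s in self.rows}
                    raise FormatError(
                        f"ragged alignment: row {r.id!r} has length "
                        f"{len(r.residues)}, expected {n} (all lengths: {lengths})"
                    )

    @property
    def n_columns(self) -> int:
        return len(self.rows[0].residues) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def ids(self) -> list:
        return [r.id for r in self.rows]

    def column(self, j: int) -> str:
        """Residues of 1-based alignment column ``j``."""
        return "".join(r.residues[j - 1] for r in self.rows)


@dataclass
class GeneRecord:
    """A gene feature from a GFF3 file (1-based inclusive coordinates)."""

    contig: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )


class _AlnRow(Sequence):
    """Alignment row: like Sequence but allows gap characters."""

    def __post_init__(self) -> None:  # noqa: D105
        if not self.id:
            raise FormatError("sequence id must be non-empty")
        self.residues = self.residues.upper().replace(".", "-")
        bad = set(self.residues) - _VALID_RESIDUES - {"-"}
        if bad:
            raise FormatError(
                f"alignment row {self.id!r} contains invalid characters: {sorted(bad)}"
            )


def aligned_row(seq_id: str, residues: str, description: str = "") -> Sequence:
    """Build an alignment row (gaps allowed, '.' normalized to '-')."""
    return _AlnRow(seq_id, residues, description)


def read_fasta(path) -> list:
    """Read a protein FASTA file into a list of :class:`Sequence`.

    A single terminal ``*`` (stop) is stripped; an internal ``*`` is an
    error, as are duplicate ids and empty files.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    out, seen = [], set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if residues.endswith("*"):
            residues = residues[:-1]
        if "*" in residues:
            raise FormatError(
                f"{path}: sequence {rec.id!r} contains an internal stop '*'"
            )
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        out.append(Sequence(rec.id, residues, desc))
    return out


def write_fasta(seqs, path, width: int = 60) -> None:
    """Write sequences to FASTA with fixed line width."""
    with open(path, "w") as fh:
        for s in seqs:
            header = f">{s.id} {s.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i:i + width] + "\n")


_FORMATS = {"clustal": "clustal", "stockholm": "stockholm"}


def read_alignment(path, format: str) -> Alignment:
    """Read a Clustal or Stockholm alignment file.

    Multi-block Clustal rows are concatenated per id; Stockholm markup
    (``#=GC``/``#=GS``) is ignored. '.' gaps are normalized to '-'.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown alignment format {format!r}")
    try:
        msa = AlignIO.read(str(path), _FORMATS[format])
    except ValueError as exc:
        # AlignIO rejects ragged input with its own message; surface per-id
        # lengths so the offending row can be identified.
        lengths = _row_lengths(path, format)
        if lengths and len(set(lengths.values())) > 1:
            raise FormatError(
                f"{path}: ragged alignment, row lengths {lengths}"
            ) from exc
        raise FormatError(f"{path}: {exc}") from exc
    rows = [aligned_row(rec.id, str(rec.seq)) for rec in msa]
    return Alignment(rows)


def _row_lengths(path, format: str) -> dict:
    """Diagnostic scan: aligned length per row id (no validation)."""
    lengths: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if (not line or line.startswith(("#", "//", "CLUSTAL"))
                    or line[0].isspace()):
                continue
            parts = line.split()
            if len(parts) >= 2 and not parts[1].isdigit():
                lengths[parts[0]] = lengths.get(parts[0], 0) + len(parts[1])
    return lengths


def write_alignment(aln: Alignment, path, format: str) -> None:
    """Write an Alignment as Clustal or Stockholm; round-trips losslessly."""
    if format not in _FORMATS:
        raise ValueError(f"unknown alignment format {format!r}")
    msa = MultipleSeqAlignment(
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in aln.rows
    )
    AlignIO.write(msa, str(path), _FORMATS[format])


def alignment_to_string(aln: Alignment, format: str = "stockholm") -> str:
    """Serialize an alignment to an in-memory string."""
    msa = MultipleSeqAlignment(
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in aln.rows
    )
    buf = io.StringIO()
    AlignIO.write(msa, buf, _FORMATS[format])
    return buf.getvalue()


def read_gff_genes(path) -> list:
    """Read ``gene`` features from a GFF3 file, sorted by (contig, start)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        id_spec=["ID"], merge_strategy="create_unique",
    )
    genes = []
    seen = set()
    for f in db.features_of_type("gene"):
        if "ID" not in f.attributes:
            raise FormatError(f"{path}: gene feature at {f.seqid}:{f.start} "
                              "is missing an ID attribute")
        gid = f.attributes["ID"][0]
        if gid in seen:
            raise FormatError(f"{path}: duplicate gene id {gid!r}")
        seen.add(gid)
        genes.append(GeneRecord(f.seqid, f.start, f.end, f.strand or ".", gid))
    genes.sort(key=lambda g: (g.contig, g.start))
    return genes


def write_tsv(df, path) -> None:
    """Write a report DataFrame as TSV (no index column)."""
    df.to_csv(path, sep="\t", index=False)
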