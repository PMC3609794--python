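"""FASTA input and TSV output.

Sequences are sanitized on read: upper-cased (soft-masked lower-case
repeats are plain sequence for entropy purposes), RNA U mapped to T, and
ambiguity codes (N, R, Y, ...) preserved.  A multi-record file represents
one pooled target sequence set; downstream counting never forms windows
across record boundaries.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .errors import FastaFormatError

_GZIP_MAGIC = b"\x1f\x8b"


@dataclass(frozen=True)
class SequenceRecord:
    """One named nucleotide sequence.

    Attributes
    ----------
    identifier:
        Header token before the first whitespace.
    residues:
        Upper-case nucleotide string over {A, C, G, T} plus IUPAC
        ambiguity codes.
    """

    identifier: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)


def _sanitize(raw: str) -> str:
    return raw.upper().replace("U", "T")


def read_fasta(path: str | Path, allow_gzip: bool = True) -> list[SequenceRecord]:
    """Parse a FASTA (optionally gzip-compressed) file into records.

    Parameters
    ----------
    path:
        FASTA file; gzip is auto-detected from the magic bytes when
        ``allow_gzip`` is true.
    allow_gzip:
        Refuse compressed input when false.

    Raises
    ------
    FileNotFoundError
        Missing input file.
    FastaFormatError
        Empty file, a record with zero residues, or non-FASTA content.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")

    with open(path, "rb") as raw:
        magic = raw.read(2)
    if magic == _GZIP_MAGIC:
        if not allow_gzip:
            raise FastaFormatError(f"{path}: gzip input not allowed here")
        opener = gzip.open(path, "rt")
    else:
        opener = open(path, "rt")

    records: list[SequenceRecord] = []
    with opener as handle:
        text = handle.read()
    if not text.strip():
        raise FastaFormatError(f"{path}: empty file")
    if not text.lstrip().startswith(">"):
        raise FastaFormatError(f"{path}: not FASTA (no '>' header)")
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        residues = _sanitize(str(rec.seq))
        if not residues:
            raise FastaFormatError(f"{path}: record '{rec.id}' has no residues")
        records.append(SequenceRecord(identifier=rec.id, residues=residues))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as plain FASTA with fixed line width."""
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.identifier}\n")
            for i in range(0, len(rec.residues), width):
                out.write(rec.residues[i : i + width] + "\n")


def _render(value: object, percent: bool, float_decimals: int, percent_decimals: int) -> str:
    if percent:
        return f"{float(value) * 100.0:.{percent_decimals}f}%"
    if isinstance(value, float):
        return f"{value:.{float_decimals}f}"
    return str(value)


def write_tsv(
    rows: Sequence[Mapping[str, object]],
    path: str | Path,
    column_order: Sequence[str],
    percent_columns: Iterable[str] = (),
    percent_decimals: int = 2,
    float_decimals: int = 6,
) -> None:
    """Write rows of labelled values as a tab-separated table.

    Floats are rendered with ``float_decimals`` places; columns named in
    ``percent_columns`` hold fractions and are rendered as percentages
    with ``percent_decimals`` places and a trailing ``%`` (0.0649 ->
    "6.49%").  An empty row collection produces a header-only file.
    """
    percent_set = set(percent_columns)
    for row in rows:
        if set(row.keys()) != set(column_order):
            raise ValueError(
                f"row columns {sorted(row)} do not match column_order {sorted(column_order)}"
            )
    with open(path, "w", encoding="utf-8", newline="\n") as out:
        out.write("\t".join(column_order) + "\n")
        for row in rows:
            cells = [
                _render(row[col], col in percent_set, float_decimals, percent_decimals)
                for col in column_order
            ]
            out.write("\t".join(cells) + "\n")
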