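"""FASTA/FASTQ and TSV input/output.

Thin wrappers over Biopython's SeqIO and pandas so that every module reads and
writes the standard formats the same way.  All tables are written as
tab-delimited UTF-8 with a header row; coordinates in any output are 0-based,
half-open.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import Read


class FastaParseError(ValueError):
    pass


def read_fasta(path: str | os.PathLike, library_id: str = "") -> list[Read]:
    """Parse a FASTA (or FASTQ) file into :class:`Read` records.

    An empty file yields an empty list.  Duplicate record ids within one file
    raise :class:`FastaParseError`.
    """
    path = os.fspath(path)
    fmt = "fastq" if path.endswith((".fastq", ".fq")) else "fasta"
    reads: list[Read] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(path, fmt):
            if rec.id in seen:
                raise FastaParseError(f"duplicate record id {rec.id!r} in {path}")
            seen.add(rec.id)
            qual = rec.letter_annotations.get("phred_quality")
            reads.append(
                Read(
                    id=rec.id,
                    sequence=str(rec.seq).upper(),
                    library_id=library_id,
                    quality=list(qual) if qual is not None else None,
                )
            )
    except ValueError as exc:  # malformed record
        if isinstance(exc, FastaParseError):
            raise
        raise FastaParseError(f"malformed {fmt} in {path}: {exc}") from exc
    return reads


def write_fasta(records: Iterable, path: str | os.PathLike) -> int:
    """Write records (anything with ``id`` and ``sequence``/``consensus``) as
    FASTA.  Returns the number of records written."""
    seqrecs = []
    for r in records:
        seq = getattr(r, "sequence", None)
        if seq is None:
            seq = r.consensus
        seqrecs.append(SeqRecord(Seq(seq), id=r.id, description=""))
    return SeqIO.write(seqrecs, os.fspath(path), "fasta")


def write_tsv_report(table: pd.DataFrame | Sequence[Sequence], path, header=None) -> None:
    """Write a rectangular table as tab-delimited UTF-8 with a header row.

    ``table`` may be a DataFrame or a sequence of rows (in which case
    ``header`` names the columns).  An empty table produces a header-only file.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(list(table), columns=header)
    table.to_csv(os.fspath(path), sep="\t", index=False, encoding="utf-8",
                 lineterminator="\n", float_format="%.6g")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(os.fspath(path), sep="\t")
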