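"""FASTA reading and writing.

Reading is delegated to :mod:`Bio.SeqIO`; identifiers are the first
whitespace-delimited header token, with the remaining description retained.
Duplicate identifiers are disambiguated with ``.dup1``, ``.dup2`` suffixes
and logged.  Writing wraps sequence lines at a fixed width (default 60) so
output files are byte-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from os import PathLike
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO

from .core import ChimeraProtError

logger = logging.getLogger(__name__)


class FastaError(ChimeraProtError):
    """Empty, duplicate-riddled beyond repair, or non-FASTA content."""


@dataclass(frozen=True)
class FastaRecord:
    id: str
    seq: str
    description: str = ""


RecordLike = Union[FastaRecord, Sequence[str]]


def read_fasta(path: Union[str, PathLike]) -> list[FastaRecord]:
    """Read all records from a FASTA file, in file order."""
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
        if not first:
            raise FastaError(f"{path}: empty file")
        if not first.startswith(">"):
            raise FastaError(f"{path}: not FASTA (no '>' header)")
    records: list[FastaRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if not rid:
            raise FastaError(f"{path}: record with empty identifier")
        if rid in seen:
            seen[rid] += 1
            new_id = f"{rid}.dup{seen[rid]}"
            logger.warning(
                "%s: duplicate identifier %r renamed to %r", path, rid, new_id
            )
            rid = new_id
        else:
            seen[rid] = 0
        desc = rec.description[len(rec.id) :].strip()
        records.append(FastaRecord(rid, str(rec.seq), desc))
    if not records:
        raise FastaError(f"{path}: no FASTA records")
    return records


def _coerce(rec: RecordLike) -> FastaRecord:
    if isinstance(rec, FastaRecord):
        return rec
    if len(rec) == 2:
        return FastaRecord(rec[0], rec[1])
    if len(rec) == 3:
        return FastaRecord(rec[0], rec[2], rec[1])
    raise TypeError(f"cannot interpret {rec!r} as a FASTA record")


def write_fasta(
    records: Iterable[RecordLike], path: Union[str, PathLike], wrap: int = 60
) -> int:
    """Write records in the given order; returns the number written."""
    if wrap < 1:
        raise ValueError("wrap must be >= 1")
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            rec = _coerce(rec)
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i : i + wrap] + "\n")
            n += 1
    return n
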