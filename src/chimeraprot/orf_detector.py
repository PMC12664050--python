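"""Module 1: enumerate and translate all stop-free ORFs of a transcriptome.

ORFs are maximal runs of non-stop codons in each of the three forward
frames, bounded by in-frame stop codons or by the transcript ends, with no
AUG requirement.  Runs of at least ``min_len_aa`` residues are reported with
1-based inclusive coordinates and canonical tags; reference and alternative
products are emitted combined (their separation is Module 2's job).
"""

from __future__ import annotations

import logging
import re
from os import PathLike
from typing import Union

from .core import Transcript, OrfRecord, VALID_FRAMES, translate_frame
from .fasta import FastaError, FastaRecord, read_fasta, write_fasta

logger = logging.getLogger(__name__)

_RUN_RE = re.compile(r"[^*]+")


def detect_orfs(t: Transcript, min_len_aa: int = 30) -> list[OrfRecord]:
    """All stop-free ORFs of ``t`` with at least ``min_len_aa`` residues.

    Returned in (frame, start) order.  Stop codons are never part of an ORF;
    trailing partial codons are excluded from coordinates.  A transcript with
    no qualifying ORF yields an empty list.
    """
    if min_len_aa < 1:
        raise ValueError("min_len_aa must be >= 1")
    orfs: list[OrfRecord] = []
    for frame in VALID_FRAMES:
        aa = translate_frame(t.seq, frame)
        for m in _RUN_RE.finditer(aa):
            if m.end() - m.start() < min_len_aa:
                continue
            start_nt = frame + 3 * m.start()
            end_nt = frame + 3 * m.end() - 1
            orfs.append(
                OrfRecord(
                    transcript_id=t.id,
                    frame=frame,
                    start_nt=start_nt,
                    end_nt=end_nt,
                    aa_seq=m.group(0),
                )
            )
    return orfs


def detect_transcriptome(
    transcriptome: Union[str, PathLike],
    min_len_aa: int = 30,
    out: Union[str, PathLike, None] = None,
) -> list[OrfRecord]:
    """Run :func:`detect_orfs` over a transcriptome FASTA.

    ORFs are concatenated in input transcript order; when ``out`` is given a
    single amino-acid FASTA is written whose headers are the ORF tags.
    """
    try:
        records = read_fasta(transcriptome)
    except FastaError as err:
        if "no FASTA records" in str(err) or "empty file" in str(err):
            logger.warning("%s: empty transcriptome, emitting no ORFs", transcriptome)
            records = []
        else:
            raise
    orfs: list[OrfRecord] = []
    per_frame = {f: 0 for f in VALID_FRAMES}
    for rec in records:
        t = Transcript(rec.id, rec.seq)
        for orf in detect_orfs(t, min_len_aa):
            per_frame[orf.frame] += 1
            orfs.append(orf)
    logger.info(
        "read %d transcripts; emitted %d ORFs >= %d aa (frame 1/2/3: %d/%d/%d)",
        len(records), len(orfs), min_len_aa,
        per_frame[1], per_frame[2], per_frame[3],
    )
    if out is not None:
        write_fasta((FastaRecord(o.tag, o.aa_seq) for o in orfs), out)
    return orfs
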