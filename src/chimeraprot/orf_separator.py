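"""Module 2: partition detected ORFs into refProt and altProt files.

A user-supplied canonical proteome defines what counts as a reference
product.  Because stop-to-stop ORFs extend beyond annotated start codons,
an annotated protein is properly contained in its host ORF's translation;
the default matching rule is therefore canonical-protein-as-substring of the
ORF translation (canonical entries shorter than 7 aa are ignored to avoid
trivial matches).  ``exact`` mode, which requires sequence equality, is
available as an alternative interpretation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Union

from .core import ChimeraProtError, OrfRecord
from .fasta import FastaRecord, read_fasta, write_fasta
from .tags import parse_orf_tag

logger = logging.getLogger(__name__)

#: Canonical entries shorter than this never define a refProt.
MIN_CANONICAL_LEN = 7

_MATCH_MODES = ("substring", "exact")


def _normalize_protein(seq: str) -> str:
    return seq.upper().rstrip("*")


class CanonicalIndex:
    """Multi-pattern containment scan over a canonical proteome.

    Canonical sequences are indexed by their first ``MIN_CANONICAL_LEN``-mer;
    a query ORF translation slides a window of that width, looks up candidate
    canonicals, and verifies full containment.  This keeps classification
    near-linear in the query length for realistic proteome sizes.
    """

    def __init__(
        self,
        canonical: Iterable[str],
        min_len: int = MIN_CANONICAL_LEN,
        mode: str = "substring",
    ) -> None:
        if mode not in _MATCH_MODES:
            raise ValueError(f"match mode must be one of {_MATCH_MODES}")
        self.mode = mode
        self.min_len = min_len
        seqs = {_normalize_protein(s) for s in canonical}
        self.n_input = len(seqs)
        self.seqs = {s for s in seqs if len(s) >= min_len}
        self._by_seed: dict[str, list[str]] = {}
        for s in self.seqs:
            self._by_seed.setdefault(s[:min_len], []).append(s)
        self.matched: set[str] = set()

    def match(self, aa_seq: str) -> bool:
        """True iff some canonical sequence matches ``aa_seq``."""
        aa_seq = aa_seq.upper()
        if self.mode == "exact":
            hit = aa_seq in self.seqs
            if hit:
                self.matched.add(aa_seq)
            return hit
        w = self.min_len
        found = False
        for i in range(len(aa_seq) - w + 1):
            for cand in self._by_seed.get(aa_seq[i : i + w], ()):
                if aa_seq.startswith(cand, i):
                    self.matched.add(cand)
                    found = True
        return found

    @property
    def unmatched(self) -> set[str]:
        return self.seqs - self.matched


def classify_orf(
    orf: OrfRecord,
    canonical: Union[CanonicalIndex, Iterable[str]],
    mode: str = "substring",
) -> str:
    """Classify one ORF as ``"refProt"`` or ``"altProt"``."""
    index = (
        canonical
        if isinstance(canonical, CanonicalIndex)
        else CanonicalIndex(canonical, mode=mode)
    )
    return "refProt" if index.match(orf.aa_seq) else "altProt"


@dataclass
class OrfCatalog:
    """Partitioned Module-2 output: altProt and refProt records by tag."""

    alt_records: list[OrfRecord]
    ref_records: list[OrfRecord]
    provenance: dict = field(default_factory=dict)

    @property
    def alt_tags(self) -> set[str]:
        return {r.tag for r in self.alt_records}

    @property
    def ref_tags(self) -> set[str]:
        return {r.tag for r in self.ref_records}


def orf_record_from_fasta(rec: FastaRecord) -> OrfRecord:
    """Rebuild an :class:`OrfRecord` from a tagged amino-acid FASTA record."""
    fields = parse_orf_tag(rec.id)
    return OrfRecord(
        transcript_id=fields.transcript_id,
        frame=fields.frame,
        start_nt=fields.start_nt,
        end_nt=fields.end_nt,
        aa_seq=rec.seq.upper(),
    )


def separate(
    orfs: Union[str, PathLike],
    proteome: Union[str, PathLike],
    out_alt: Union[str, PathLike, None] = None,
    out_ref: Union[str, PathLike, None] = None,
    match_mode: str = "substring",
) -> OrfCatalog:
    """Partition a Module-1 FASTA against a canonical proteome.

    Both output files preserve input order with unchanged tag headers.  ORF
    headers that do not parse as tags are a hard error: downstream modeling
    depends on tag coordinates.
    """
    orf_records = read_fasta(orfs)
    proteome_records = read_fasta(proteome)
    index = CanonicalIndex((r.seq for r in proteome_records), mode=match_mode)
    alt: list[OrfRecord] = []
    ref: list[OrfRecord] = []
    for rec in orf_records:
        orf = orf_record_from_fasta(rec)  # TagError propagates: hard error
        (ref if index.match(orf.aa_seq) else alt).append(orf)
    catalog = OrfCatalog(
        alt_records=alt,
        ref_records=ref,
        provenance={
            "orfs_file": str(orfs),
            "proteome_file": str(proteome),
            "n_orfs": len(orf_records),
            "n_canonical": index.n_input,
            "n_alt": len(alt),
            "n_ref": len(ref),
            "match_mode": match_mode,
        },
    )
    logger.info(
        "separated %d ORFs: %d altProts, %d refProts; %d of %d usable "
        "canonical entries unmatched by any ORF",
        len(orf_records), len(alt), len(ref),
        len(index.unmatched), len(index.seqs),
    )
    if out_alt is not None:
        write_fasta((FastaRecord(o.tag, o.aa_seq) for o in alt), out_alt)
    if out_ref is not None:
        write_fasta((FastaRecord(o.tag, o.aa_seq) for o in ref), out_ref)
    return catalog
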