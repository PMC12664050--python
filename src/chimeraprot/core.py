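"""Domain types and nucleotide-level primitives shared by every pipeline stage.

The pipeline models products of programmed ribosomal frameshifting (PRF): a
ribosome slips backward or forward by a few nucleotides mid-translation and
continues in a different reading frame, yielding a chimeric protein whose two
"arms" come from two overlapping (or nearly adjacent) open reading frames of
the same transcript.  Everything downstream works on three kinds of objects:

* :class:`Transcript` -- one spliced, sense-strand nucleotide sequence.
* :class:`OrfRecord` -- one stop-free reading span in one forward frame,
  with 1-based inclusive transcript coordinates and its translation.
* :class:`ChimericModel` -- one modeled PRF product: a left arm from one
  frame and a right arm from another, joined at a putative PRF site.

Coordinates are 1-based and inclusive throughout; frame ``f`` starts
translation at nucleotide offset ``f - 1``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional


class ChimeraProtError(Exception):
    """Base class for all errors raised by this package."""


class ConsistencyError(ChimeraProtError):
    """Internal geometry that should be impossible for stop-to-stop ORFs."""


# --- genetic code -----------------------------------------------------------

#: Stop codons of the standard genetic code; no alternative codes in v1.
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# Standard genetic code (NCBI transl_table=1), second/third base cycling TCAG.
_BASES = "TCAG"
_AA_BY_CODON_ORDER = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
CODON_TABLE: dict[str, str] = {
    "".join(codon): aa
    for codon, aa in zip(itertools.product(_BASES, repeat=3), _AA_BY_CODON_ORDER)
}

VALID_FRAMES = (1, 2, 3)

# IUPAC nucleotide ambiguity alphabet accepted on ingest (after U->T mapping).
IUPAC_NT = frozenset("ACGTNRYSWKMBDHV")


def normalize_nt(seq: str) -> str:
    """Uppercase a nucleotide string and map RNA ``U`` to ``T``."""
    return seq.upper().replace("U", "T")


def translate_frame(seq: str, frame: int) -> str:
    """Translate consecutive full codons of ``seq`` starting at frame offset.

    Frame ``f`` in {1, 2, 3} starts at nucleotide offset ``f - 1``.  Stop
    codons are rendered as ``*``.  Any codon containing a letter outside
    ``ACGT`` (``N`` or another IUPAC ambiguity letter) is rendered as ``X``,
    never resolved and never treated as a stop.  A trailing partial codon is
    dropped.
    """
    if frame not in VALID_FRAMES:
        raise ValueError(f"frame must be one of {VALID_FRAMES}, got {frame!r}")
    s = normalize_nt(seq)
    n_codons = (len(s) - frame + 1) // 3
    start = frame - 1
    return "".join(
        CODON_TABLE.get(s[i : i + 3], "X")
        for i in range(start, start + 3 * n_codons, 3)
    )


# --- domain types -----------------------------------------------------------


@dataclass
class Transcript:
    """One spliced transcript: identifier plus sense-strand nucleotide sequence.

    The sequence is uppercased and ``U`` is mapped to ``T`` on construction,
    so RNA-alphabet FASTA inputs are accepted transparently.
    """

    id: str
    seq: str
    biotype: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        self.seq = normalize_nt(self.seq)
        if len(self.seq) < 1:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        bad = set(self.seq) - IUPAC_NT
        if bad:
            raise ValueError(
                f"transcript {self.id!r}: non-IUPAC letters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class OrfRecord:
    """One stop-free reading span in one forward frame of one transcript.

    ``start_nt`` is the first nucleotide of the first codon, ``end_nt`` the
    last nucleotide of the last codon, both 1-based inclusive, so
    ``end_nt - start_nt + 1 == 3 * len(aa_seq)``.  ``aa_seq`` never contains
    a stop character; ORFs are stop-to-stop (or stop-to-edge) spans, with no
    AUG requirement.
    """

    transcript_id: str
    frame: int
    start_nt: int
    end_nt: int
    aa_seq: str

    def __post_init__(self) -> None:
        if self.frame not in VALID_FRAMES:
            raise ValueError(f"invalid frame {self.frame!r}")
        if self.start_nt < 1 or self.end_nt < self.start_nt:
            raise ValueError(
                f"bad coordinates {self.start_nt}-{self.end_nt} for ORF on "
                f"{self.transcript_id!r}"
            )
        if (self.start_nt - self.frame) % 3 != 0:
            raise ValueError(
                f"start {self.start_nt} not aligned to frame {self.frame}"
            )
        if self.length_nt != 3 * len(self.aa_seq):
            raise ValueError(
                f"length {self.length_nt} nt inconsistent with "
                f"{len(self.aa_seq)} aa translation"
            )
        if "*" in self.aa_seq:
            raise ValueError("ORF translation must not contain stop characters")

    @property
    def length_nt(self) -> int:
        return self.end_nt - self.start_nt + 1

    @property
    def length_aa(self) -> int:
        return len(self.aa_seq)

    @property
    def tag(self) -> str:
        from .tags import format_orf_tag

        return format_orf_tag(self)


@dataclass(frozen=True)
class ChimericModel:
    """One modeled PRF product: two arms from two frames joined at a PRF site.

    ``orf_a_tag`` is the ORF contributing the left arm, ``orf_b_tag`` the
    right arm (the order carries no biological meaning).  ``prf_value`` is the
    signed nucleotide displacement of the slip: -2/-1/+1/+2 for overlap
    scenarios, +1..+10 for the gap scenario.  ``iteration`` is the 1-based
    index of the junction step within its scenario window.
    """

    orf_a_tag: str
    orf_b_tag: str
    prf_value: int
    iteration: int
    scenario_tag: str
    left_arm_aa: str
    right_arm_aa: str

    def __post_init__(self) -> None:
        from .tags import SCENARIO_TAGS

        if self.scenario_tag not in SCENARIO_TAGS:
            raise ValueError(f"unknown scenario tag {self.scenario_tag!r}")
        if self.iteration < 1:
            raise ValueError("iterations are 1-based")
        if self.prf_value == 0:
            raise ValueError("PRF value cannot be zero")
        if not self.left_arm_aa or not self.right_arm_aa:
            raise ValueError("both arms must be non-empty")
        if "*" in self.aa_seq:
            raise ValueError("chimeric model must be stop-free")

    @property
    def aa_seq(self) -> str:
        return self.left_arm_aa + self.right_arm_aa

    @property
    def length_aa(self) -> int:
        return len(self.left_arm_aa) + len(self.right_arm_aa)

    @property
    def model_tag(self) -> str:
        from .tags import format_model_tag

        return format_model_tag(self)


@dataclass
class ModelingConfig:
    """All thresholds of the chimeric modeler.

    Defaults follow the published settings: 30 aa minimum ORF length (the
    OpenProt convention), a 40 aa total model cap sized so a typical MS
    peptide (7-35 aa) spans the junction, 10 aa minimum arms for embedded
    overlaps, a 1 aa minimum second arm for UTR overlaps, 20 aa arms for the
    non-overlapping (translational-bypass-like) scenario, and gaps of at most
    10 nt bridged by forward slips.
    """

    min_orf_len_aa: int = 30
    model_len_cap_aa: int = 40
    min_arm_scenario1_aa: int = 10
    min_second_arm_scenario2_aa: int = 1
    arm_scenario3_aa: int = 20
    max_gap_nt: int = 10
    prf_values: frozenset[int] = frozenset({-2, -1, 1, 2})
    threads: int = 1
    collapse_identical: bool = False

    def __post_init__(self) -> None:
        self.prf_values = frozenset(self.prf_values)
        if self.min_orf_len_aa < 1:
            raise ValueError("min_orf_len_aa must be >= 1")
        if 2 * self.min_arm_scenario1_aa > self.model_len_cap_aa:
            raise ValueError(
                "model_len_cap_aa must fit two minimum scenario-1 arms"
            )
        if self.min_second_arm_scenario2_aa < 1:
            raise ValueError("min_second_arm_scenario2_aa must be >= 1")
        if self.max_gap_nt < 1:
            raise ValueError("max_gap_nt must be >= 1")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")
        if any(d == 0 or abs(d) > 2 for d in self.prf_values):
            raise ValueError("overlap PRF values must be in {-2,-1,+1,+2}")
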