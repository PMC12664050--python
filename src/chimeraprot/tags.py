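"""The ORF and model tag grammar.

Every sequence the pipeline emits carries a FASTA-header tag that encodes its
provenance, so downstream MS hits can be traced back to transcript
coordinates without auxiliary files.

ORF tag::

    {transcript_id}_{frame}F_{start}-{end}_{length}

e.g. ``MtrunA17_Chr6g0457461_3F_438-596_159``: forward frame 3, nucleotides
438..596 (1-based inclusive), 159 nt total.  Transcript identifiers may
themselves contain underscores, so tags are parsed positionally from the
right.  ASCII hyphen and ASCII ``+``/``-`` are used throughout: tags must be
byte-safe FASTA headers.

Model tag::

    {orf_a_tag}_{orf_b_tag}_{prf:+d}_iteration_{i}_{scenario_tag}

where ``orf_a_tag`` contributed the left arm, ``prf`` is the signed
frameshift value, ``i`` the 1-based junction step, and ``scenario_tag`` one
of the eight controlled-vocabulary strings in :data:`SCENARIO_TAGS` (the
prime symbol is spelled out, e.g. ``Within_3prime_of_altORF``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import TYPE_CHECKING

from .core import ChimeraProtError, VALID_FRAMES

if TYPE_CHECKING:  # pragma: no cover
    from .core import ChimericModel, OrfRecord


class TagError(ChimeraProtError):
    """A tag does not conform to the grammar; the message names the field."""


#: Controlled vocabulary of scenario tags.  ``Within_*``: one ORF embedded in
#: the other, models at the 5'/3' portion of the embedded altORF.
#: ``Overlap_*``: partial overlap, part of the altORF in a UTR.  ``Span_*``:
#: the altORF spans the whole refORF, models around the refORF start/stop.
#: ``NonOverlap_*``: gap-separated ORFs joined by a forward slip.
SCENARIO_TAGS = (
    "Within_5prime_of_altORF",
    "Within_3prime_of_altORF",
    "Overlap_5prime_UTR",
    "Overlap_3prime_UTR",
    "Span_5prime_of_refORF",
    "Span_3prime_of_refORF",
    "NonOverlap_5prime_UTR",
    "NonOverlap_3prime_UTR",
)


@dataclass(frozen=True)
class OrfTagFields:
    """Fields decoded from an ORF tag."""

    transcript_id: str
    frame: int
    start_nt: int
    end_nt: int
    length_nt: int

    @property
    def tag(self) -> str:
        return (
            f"{self.transcript_id}_{self.frame}F_"
            f"{self.start_nt}-{self.end_nt}_{self.length_nt}"
        )


@dataclass(frozen=True)
class ModelTagFields:
    """Fields decoded from a chimeric-model tag."""

    orf_a: OrfTagFields
    orf_b: OrfTagFields
    prf_value: int
    iteration: int
    scenario_tag: str


def format_orf_tag(rec: "OrfRecord | OrfTagFields") -> str:
    return (
        f"{rec.transcript_id}_{rec.frame}F_"
        f"{rec.start_nt}-{rec.end_nt}_{rec.length_nt}"
    )


_FRAME_RE = re.compile(r"([123])F")
_COORD_RE = re.compile(r"(\d+)-(\d+)")


def parse_orf_tag(tag: str) -> OrfTagFields:
    """Decode an ORF tag, parsing positionally from the right."""
    parts = tag.rsplit("_", 3)
    if len(parts) != 4 or not parts[0]:
        raise TagError(
            f"ORF tag {tag!r}: expected transcript-id_frame_coords_length"
        )
    transcript_id, frame_s, coords_s, length_s = parts
    m = _FRAME_RE.fullmatch(frame_s)
    if not m:
        raise TagError(f"ORF tag {tag!r}: bad frame field {frame_s!r}")
    frame = int(m.group(1))
    if frame not in VALID_FRAMES:  # pragma: no cover - regex enforces
        raise TagError(f"ORF tag {tag!r}: bad frame {frame}")
    m = _COORD_RE.fullmatch(coords_s)
    if not m:
        raise TagError(f"ORF tag {tag!r}: bad coordinate field {coords_s!r}")
    start_nt, end_nt = int(m.group(1)), int(m.group(2))
    if not length_s.isdigit():
        raise TagError(f"ORF tag {tag!r}: bad length field {length_s!r}")
    length_nt = int(length_s)
    if end_nt < start_nt or start_nt < 1:
        raise TagError(f"ORF tag {tag!r}: bad coordinates {start_nt}-{end_nt}")
    if length_nt != end_nt - start_nt + 1:
        raise TagError(
            f"ORF tag {tag!r}: length field {length_nt} inconsistent with "
            f"coordinates ({end_nt}-{start_nt}+1={end_nt - start_nt + 1})"
        )
    return OrfTagFields(transcript_id, frame, start_nt, end_nt, length_nt)


def format_model_tag(m: "ChimericModel") -> str:
    if m.scenario_tag not in SCENARIO_TAGS:
        raise TagError(f"unknown scenario tag {m.scenario_tag!r}")
    return (
        f"{m.orf_a_tag}_{m.orf_b_tag}_{m.prf_value:+d}"
        f"_iteration_{m.iteration}_{m.scenario_tag}"
    )


_MODEL_MID_RE = re.compile(r"(.*)_([+-]\d+)_iteration_(\d+)")
# A candidate split point between the two concatenated ORF tags.
_ORF_BOUNDARY_RE = re.compile(r"_[123]F_\d+-\d+_(\d+)_")


def parse_model_tag(tag: str) -> ModelTagFields:
    """Decode a model tag; round-trips with :func:`format_model_tag`."""
    scenario = next(
        (s for s in SCENARIO_TAGS if tag.endswith("_" + s)), None
    )
    if scenario is None:
        raise TagError(f"model tag {tag!r}: unknown scenario tag suffix")
    head = tag[: -(len(scenario) + 1)]
    m = _MODEL_MID_RE.fullmatch(head)
    if not m:
        raise TagError(
            f"model tag {tag!r}: missing PRF value / iteration fields"
        )
    orf_part, prf_s, iter_s = m.group(1), m.group(2), m.group(3)
    prf_value = int(prf_s)
    if prf_value == 0:
        raise TagError(f"model tag {tag!r}: PRF value cannot be zero")
    iteration = int(iter_s)
    if iteration < 1:
        raise TagError(f"model tag {tag!r}: iterations are 1-based")
    # Split orf_part into two valid ORF tags; transcript ids may contain
    # underscores and even coordinate-like tokens, so try every boundary
    # that ends a syntactically complete ORF tag.
    last_err: TagError | None = None
    for bm in _ORF_BOUNDARY_RE.finditer(orf_part):
        split_at = bm.end(1)  # end of the length field of orf_a
        a_s, b_s = orf_part[:split_at], orf_part[split_at + 1 :]
        try:
            return ModelTagFields(
                parse_orf_tag(a_s), parse_orf_tag(b_s),
                prf_value, iteration, scenario,
            )
        except TagError as err:
            last_err = err
    raise TagError(
        f"model tag {tag!r}: cannot split {orf_part!r} into two ORF tags"
        + (f" ({last_err})" if last_err else "")
    )
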