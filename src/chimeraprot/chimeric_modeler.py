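"""Module 3: generate chimeric protein models for candidate altORF pairs.

For every user-listed candidate altORF the modeler finds partner ORFs on the
same transcript, classifies the pair geometry into one of four scenarios,
and sweeps a junction (the putative PRF site) across a modeling window in
one-codon steps called *iterations*.  Each iteration is modeled once per
admissible PRF value (the signed nucleotide slip), producing a model made of
a left arm translated in the left ORF's frame and a right arm translated in
the right ORF's frame.

Scenarios (relative geometry of the altORF-role "guest" and refORF-role
"host" on the transcript):

* **Embedded** (``S1_embedded``): guest inside host.  Two windows: one
  around the guest start (host -> guest switch, left arm from the host) and
  one around the guest end (guest -> host switch).  Both arms have a 10 aa
  minimum, so a window of ``overlap`` aa yields ``overlap - 10 + 1``
  iterations per PRF value (Equation-of-counts in
  :func:`count_models_eq1`).
* **Partial overlap** (``S2_partial_overlap``): guest sticks into a UTR at
  one end.  One window around the host boundary inside the overlap; 30
  nominal iterations, the last contributing a single residue from the
  second ORF.
* **Spanning** (``SPAN_refORF_inside_altORF``): the designated refORF lies
  entirely inside the altORF; both host boundaries get a window, handled
  like partial overlaps.
* **Gap** (``S3_gap``): disjoint ORFs separated by 1..10 nt, joined by a
  single forward slip equal to the gap; exactly one model of 20 aa + 20 aa.

A model whose arm would read through a stop codon, leave its source ORF's
stop-free span, or run off the transcript is *defective* and dropped.
Output is sorted by model tag, so results are byte-identical for any thread
count.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from itertools import combinations
from os import PathLike
from typing import Iterable, Optional, Sequence, Union

from .core import (
    ChimeraProtError,
    ChimericModel,
    ConsistencyError,
    ModelingConfig,
    OrfRecord,
    Transcript,
    translate_frame,
)
from .fasta import FastaRecord, read_fasta, write_fasta
from .orf_separator import orf_record_from_fasta
from .tags import SCENARIO_TAGS

logger = logging.getLogger(__name__)

S1_EMBEDDED = "S1_embedded"
S2_PARTIAL_OVERLAP = "S2_partial_overlap"
S3_GAP = "S3_gap"
SPAN = "SPAN_refORF_inside_altORF"
NO_SCENARIO = "none"

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"


def prf_values_between(
    frame_from: int,
    frame_to: int,
    allowed: Iterable[int] = frozenset({-2, -1, 1, 2}),
) -> set[int]:
    """PRF values that switch a ribosome from ``frame_from`` to ``frame_to``.

    A slip of ``d`` nucleotides reaches frame ``frame_from + d (mod 3)``, so
    each ordered pair of distinct frames admits exactly two values from
    {-2, -1, +1, +2} (e.g. frames 3 -> 1 via +1 or -2).  Identical frames
    admit none within an overlap.
    """
    for f in (frame_from, frame_to):
        if f not in (1, 2, 3):
            raise ValueError(f"invalid frame {f!r}")
    if frame_from == frame_to:
        return set()
    return {d for d in allowed if (d - (frame_to - frame_from)) % 3 == 0}


def count_models_eq1(overlap_len_aa: int, min_size_aa: int) -> int:
    """Models per ORF-to-ORF switch for one embedded-overlap window.

    ``(overlap - minimum + 1)`` junction iterations, each modeled for the
    two PRF directions: ``N = (overlap_len_aa - min_size_aa + 1) * 2``.
    """
    if min_size_aa < 1:
        raise ValueError("min_size_aa must be >= 1")
    if overlap_len_aa < min_size_aa:
        raise ValueError("overlap_len_aa must be >= min_size_aa")
    return (overlap_len_aa - min_size_aa + 1) * 2


@dataclass(frozen=True)
class ScenarioClassification:
    """Geometry of an ORF pair: scenario, modeling sides, and roles.

    ``host`` plays the refORF role and ``guest`` the altORF role; for
    altORF-altORF pairs the longer ORF takes the host role (tie broken by
    smaller start coordinate).
    """

    scenario: str
    sides: frozenset[str]
    host: OrfRecord
    guest: OrfRecord
    gap_nt: int = 0
    overlap: Optional[tuple[int, int]] = None


@dataclass(frozen=True)
class JunctionDefect:
    """Bookkeeping for one removed (defective) model."""

    scenario_tag: str
    prf_value: int
    iteration: int
    reason: str


def classify_pair(
    orf_a: OrfRecord,
    orf_b: OrfRecord,
    cfg: Optional[ModelingConfig] = None,
    a_is_ref: bool = False,
    b_is_ref: bool = False,
) -> ScenarioClassification:
    """Classify the relative geometry of two ORFs on one transcript."""
    cfg = cfg or ModelingConfig()
    if orf_a.transcript_id != orf_b.transcript_id:
        raise ValueError("ORFs must come from the same transcript")
    if orf_a.tag == orf_b.tag:
        raise ValueError("ORF pair must have distinct tags")
    ov_s = max(orf_a.start_nt, orf_b.start_nt)
    ov_e = min(orf_a.end_nt, orf_b.end_nt)
    overlapping = ov_s <= ov_e
    if overlapping and orf_a.frame == orf_b.frame:
        raise ConsistencyError(
            f"same-frame overlapping ORFs {orf_a.tag} / {orf_b.tag}: "
            "impossible for stop-to-stop spans"
        )
    # refORF-role assignment: an explicit ref designation wins; otherwise the
    # longer ORF is treated as the refORF (tie: smaller start coordinate).
    if a_is_ref != b_is_ref:
        host, guest = (orf_a, orf_b) if a_is_ref else (orf_b, orf_a)
    else:
        key = lambda o: (-o.length_nt, o.start_nt)
        host, guest = sorted((orf_a, orf_b), key=key)
    if not overlapping:
        earlier, later = sorted((host, guest), key=lambda o: o.start_nt)
        gap = later.start_nt - earlier.end_nt - 1
        side = FIVE_PRIME if guest.start_nt < host.start_nt else THREE_PRIME
        if 1 <= gap <= cfg.max_gap_nt:
            return ScenarioClassification(
                S3_GAP, frozenset({side}), host, guest, gap_nt=gap
            )
        return ScenarioClassification(
            NO_SCENARIO, frozenset(), host, guest, gap_nt=max(gap, 0)
        )
    overlap = (ov_s, ov_e)
    if host.start_nt <= guest.start_nt and guest.end_nt <= host.end_nt:
        return ScenarioClassification(
            S1_EMBEDDED, frozenset({FIVE_PRIME, THREE_PRIME}),
            host, guest, overlap=overlap,
        )
    if guest.start_nt <= host.start_nt and host.end_nt <= guest.end_nt:
        # The designated refORF lies wholly inside the altORF.
        return ScenarioClassification(
            SPAN, frozenset({FIVE_PRIME, THREE_PRIME}),
            host, guest, overlap=overlap,
        )
    side = FIVE_PRIME if guest.start_nt < host.start_nt else THREE_PRIME
    return ScenarioClassification(
        S2_PARTIAL_OVERLAP, frozenset({side}), host, guest, overlap=overlap
    )


def build_junction(
    transcript: Transcript,
    left_orf: OrfRecord,
    right_orf: OrfRecord,
    junction_nt: int,
    left_arm_len_aa: int,
    delta: int,
    total_len_aa: int,
) -> Union[tuple[str, str], JunctionDefect]:
    """Assemble the two arms of one model around a junction.

    The left arm is the last ``left_arm_len_aa`` codons of the left frame
    ending at codon-final nucleotide ``junction_nt``; the right arm is the
    next ``total_len_aa - left_arm_len_aa`` codons of the right frame
    beginning at ``junction_nt + 1 + delta``.  Returns the arm translations,
    or a :class:`JunctionDefect` when an arm reads a stop codon, leaves its
    source ORF's stop-free span, or runs off the transcript.
    """
    if delta == 0:
        raise ValueError("delta cannot be zero")
    if (junction_nt + 1 - left_orf.frame) % 3 != 0:
        raise ValueError(
            f"junction {junction_nt} is not a codon end of frame "
            f"{left_orf.frame}"
        )
    right_start = junction_nt + 1 + delta
    if (right_start - right_orf.frame) % 3 != 0:
        raise ValueError(
            f"delta {delta:+d} inconsistent with frame pair "
            f"{left_orf.frame} -> {right_orf.frame}"
        )
    k = left_arm_len_aa
    right_len = total_len_aa - k
    if k < 1 or right_len < 1:
        raise ValueError("both arms need at least one codon")

    def defect(reason: str) -> JunctionDefect:
        return JunctionDefect("", delta, 0, reason)

    left_start = junction_nt - 3 * k + 1
    right_end = right_start + 3 * right_len - 1
    if left_start < 1 or right_start < 1 or right_end > len(transcript.seq):
        return defect("off_transcript")
    if left_start < left_orf.start_nt or junction_nt > left_orf.end_nt:
        return defect("left_arm_outside_orf")
    if right_start < right_orf.start_nt or right_end > right_orf.end_nt:
        return defect("right_arm_outside_orf")
    left_aa = translate_frame(transcript.seq[left_start - 1 : junction_nt], 1)
    right_aa = translate_frame(transcript.seq[right_start - 1 : right_end], 1)
    if "*" in left_aa:
        return defect("stop_in_left_arm")
    if "*" in right_aa:
        return defect("stop_in_right_arm")
    return left_aa, right_aa


def _emit(
    transcript: Transcript,
    left: OrfRecord,
    right: OrfRecord,
    junction: int,
    k: int,
    total: int,
    delta: int,
    iteration: int,
    scenario_tag: str,
    models: list[ChimericModel],
    defects: Optional[list[JunctionDefect]],
) -> None:
    res = build_junction(transcript, left, right, junction, k, delta, total)
    if isinstance(res, JunctionDefect):
        if defects is not None:
            defects.append(
                JunctionDefect(scenario_tag, delta, iteration, res.reason)
            )
        return
    left_aa, right_aa = res
    models.append(
        ChimericModel(
            orf_a_tag=left.tag,
            orf_b_tag=right.tag,
            prf_value=delta,
            iteration=iteration,
            scenario_tag=scenario_tag,
            left_arm_aa=left_aa,
            right_arm_aa=right_aa,
        )
    )


def _start_anchored_side(
    transcript: Transcript,
    left: OrfRecord,
    right: OrfRecord,
    cfg: ModelingConfig,
    scenario_tag: str,
    left_min: int,
    right_min: int,
    models: list[ChimericModel],
    defects: Optional[list[JunctionDefect]],
) -> None:
    """Junction sweep anchored at the right ORF's start.

    The first right arm begins at the right ORF's first codon; the right
    arm's far end is pinned ``cap - A0`` codons downstream (clipped to the
    right ORF), so successive iterations grow the left arm from its nominal
    ``A0`` residues and shrink the right arm by one codon each step.
    """
    a0, cap = cfg.min_arm_scenario1_aa, cfg.model_len_cap_aa
    e = min(right.start_nt + 3 * (cap - a0) - 1, right.end_nt)
    for delta in sorted(prf_values_between(left.frame, right.frame, cfg.prf_values)):
        p1 = right.start_nt - 1 - delta
        a = max(p1 - (3 * a0 - 1), left.start_nt)
        i = 0
        while True:
            i += 1
            p = p1 + 3 * (i - 1)
            r = p + 1 + delta
            right_len = (e - r) // 3 + 1
            if right_len < right_min:
                break
            k = (p - a) // 3 + 1
            if k < max(left_min, 1):
                continue
            _emit(
                transcript, left, right, p, k, k + right_len, delta, i,
                scenario_tag, models, defects,
            )


def _end_anchored_side(
    transcript: Transcript,
    left: OrfRecord,
    right: OrfRecord,
    cfg: ModelingConfig,
    scenario_tag: str,
    left_min: int,
    right_min: int,
    models: list[ChimericModel],
    defects: Optional[list[JunctionDefect]],
) -> None:
    """Junction sweep anchored at the left ORF's end.

    The left arm's start is pinned ``cap - A0`` codons upstream of the left
    ORF's last nucleotide (clipped to the left ORF); the window extends
    ``A0`` codons past that end, so the left arm grows from ``A0`` residues
    while the right arm shrinks toward the window edge.
    """
    a0, cap = cfg.min_arm_scenario1_aa, cfg.model_len_cap_aa
    a = max(left.end_nt - (3 * (cap - a0) - 1), left.start_nt)
    p1 = a + 3 * a0 - 1
    for delta in sorted(prf_values_between(left.frame, right.frame, cfg.prf_values)):
        e = min(left.end_nt + 3 * a0 + delta, right.end_nt)
        i = 0
        while True:
            i += 1
            p = p1 + 3 * (i - 1)
            r = p + 1 + delta
            right_len = (e - r) // 3 + 1
            if right_len < right_min:
                break
            k = (p - a) // 3 + 1
            if k < max(left_min, 1):
                continue
            _emit(
                transcript, left, right, p, k, k + right_len, delta, i,
                scenario_tag, models, defects,
            )


def generate_models_for_pair(
    transcript: Transcript,
    classification: ScenarioClassification,
    cfg: Optional[ModelingConfig] = None,
    defects: Optional[list[JunctionDefect]] = None,
) -> list[ChimericModel]:
    """All (non-defective) chimeric models for one classified ORF pair.

    Pass a list as ``defects`` to additionally collect one record per model
    removed by the defect filter.
    """
    cfg = cfg or ModelingConfig()
    c = classification
    models: list[ChimericModel] = []
    if c.scenario == NO_SCENARIO:
        return models
    a0 = cfg.min_arm_scenario1_aa
    m2 = cfg.min_second_arm_scenario2_aa
    if c.scenario == S1_EMBEDDED:
        if FIVE_PRIME in c.sides:
            _start_anchored_side(
                transcript, c.host, c.guest, cfg, "Within_5prime_of_altORF",
                a0, a0, models, defects,
            )
        if THREE_PRIME in c.sides:
            _end_anchored_side(
                transcript, c.guest, c.host, cfg, "Within_3prime_of_altORF",
                a0, a0, models, defects,
            )
    elif c.scenario == S2_PARTIAL_OVERLAP:
        if FIVE_PRIME in c.sides:
            _start_anchored_side(
                transcript, c.guest, c.host, cfg, "Overlap_5prime_UTR",
                1, m2, models, defects,
            )
        if THREE_PRIME in c.sides:
            _start_anchored_side(
                transcript, c.host, c.guest, cfg, "Overlap_3prime_UTR",
                1, m2, models, defects,
            )
    elif c.scenario == SPAN:
        if FIVE_PRIME in c.sides:
            _start_anchored_side(
                transcript, c.guest, c.host, cfg, "Span_5prime_of_refORF",
                1, m2, models, defects,
            )
        if THREE_PRIME in c.sides:
            _end_anchored_side(
                transcript, c.host, c.guest, cfg, "Span_3prime_of_refORF",
                1, m2, models, defects,
            )
    elif c.scenario == S3_GAP:
        up, down = sorted((c.host, c.guest), key=lambda o: o.start_nt)
        tag = (
            "NonOverlap_5prime_UTR"
            if FIVE_PRIME in c.sides
            else "NonOverlap_3prime_UTR"
        )
        k = min(cfg.arm_scenario3_aa, up.length_aa)
        right_len = min(cfg.arm_scenario3_aa, down.length_aa)
        _emit(
            transcript, up, down, up.end_nt, k, k + right_len, c.gap_nt, 1,
            tag, models, defects,
        )
    else:  # pragma: no cover
        raise ValueError(f"unknown scenario {c.scenario!r}")
    return models


def enumerate_pairs(
    candidate_ids: Sequence[str],
    alt_records: Iterable[OrfRecord],
    ref_records: Iterable[OrfRecord],
) -> list[tuple[OrfRecord, OrfRecord, bool]]:
    """Resolve candidate altORFs and pair them with same-transcript partners.

    Each candidate is paired with every refORF on its transcript and with
    every *other candidate* altORF on its transcript; each unordered pair is
    emitted once, sorted for determinism.  The third tuple element flags a
    refORF partner.
    """
    alt_by_tag = {r.tag: r for r in alt_records}
    missing = sorted(set(candidate_ids) - set(alt_by_tag))
    if missing:
        raise ChimeraProtError(
            "candidate tags not found in the altProt catalog: "
            + ", ".join(missing)
        )
    refs_by_tx: dict[str, list[OrfRecord]] = {}
    for r in ref_records:
        refs_by_tx.setdefault(r.transcript_id, []).append(r)
    cands = sorted(set(candidate_ids))
    pairs: list[tuple[OrfRecord, OrfRecord, bool]] = []
    for tag in cands:
        cand = alt_by_tag[tag]
        partners = sorted(
            refs_by_tx.get(cand.transcript_id, ()), key=lambda r: r.tag
        )
        if not partners:
            logger.info("candidate %s: no refORF partner on its transcript", tag)
        for ref in partners:
            pairs.append((cand, ref, True))
    cands_by_tx: dict[str, list[str]] = {}
    for tag in cands:
        cands_by_tx.setdefault(alt_by_tag[tag].transcript_id, []).append(tag)
    for tx_tags in cands_by_tx.values():
        for ta, tb in combinations(sorted(tx_tags), 2):
            pairs.append((alt_by_tag[ta], alt_by_tag[tb], False))
    pairs.sort(key=lambda p: (p[0].tag, p[1].tag))
    return pairs


def _read_candidates(path: Union[str, PathLike]) -> list[str]:
    tags: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                tags.append(line)
    return tags


def model_pairs(
    transcripts: dict[str, Transcript],
    pairs: Sequence[tuple[OrfRecord, OrfRecord, bool]],
    cfg: ModelingConfig,
) -> tuple[list[ChimericModel], list[JunctionDefect]]:
    """Classify and model a batch of (candidate, partner, partner_is_ref)."""
    models: list[ChimericModel] = []
    defects: list[JunctionDefect] = []
    for alt, partner, partner_is_ref in pairs:
        try:
            transcript = transcripts[alt.transcript_id]
        except KeyError:
            raise ChimeraProtError(
                f"transcript {alt.transcript_id!r} not in the transcriptome"
            ) from None
        classification = classify_pair(
            alt, partner, cfg, a_is_ref=False, b_is_ref=partner_is_ref
        )
        models.extend(
            generate_models_for_pair(transcript, classification, cfg, defects)
        )
    return models, defects


def _model_chunk(args):  # multiprocessing entry point
    transcripts, pairs, cfg = args
    return model_pairs(transcripts, pairs, cfg)


def simulate_chimeric_proteins(
    transcriptome: Union[str, PathLike],
    alt: Union[str, PathLike],
    ref: Union[str, PathLike],
    candidates: Union[str, PathLike],
    out: Union[str, PathLike, None] = None,
    cfg: Optional[ModelingConfig] = None,
) -> tuple[list[ChimericModel], dict]:
    """Run the full modeling stage from the four input files.

    Inputs: the transcriptome (nucleotide FASTA), the altProt and refProt
    FASTA files from Module 2 (headers are ORF tags), and a plain-text list
    of candidate altProt identifiers (one tag per line, ``#`` comments
    allowed).  Writes an amino-acid FASTA of models sorted lexicographically
    by model tag -- byte-identical output for any thread count -- and
    returns the models plus run statistics.
    """
    cfg = cfg or ModelingConfig()
    transcripts: dict[str, Transcript] = {}
    for rec in read_fasta(transcriptome):
        transcripts[rec.id] = Transcript(rec.id, rec.seq)
    alt_recs = [orf_record_from_fasta(r) for r in read_fasta(alt)]
    ref_recs = [orf_record_from_fasta(r) for r in read_fasta(ref)]
    cand_tags = _read_candidates(candidates)
    ref_tags = {r.tag for r in ref_recs}
    bad = sorted(set(cand_tags) & ref_tags)
    if bad:
        raise ChimeraProtError(
            "candidates must be altProts; these tags are refProts: "
            + ", ".join(bad)
        )
    pairs = enumerate_pairs(cand_tags, alt_recs, ref_recs)

    if cfg.threads == 1 or len(pairs) < 2:
        models, defects = model_pairs(transcripts, pairs, cfg)
    else:
        # Partition work by candidate ORF; the final sort makes the output
        # independent of scheduling.
        groups: dict[str, list[tuple[OrfRecord, OrfRecord, bool]]] = {}
        for pair in pairs:
            groups.setdefault(pair[0].tag, []).append(pair)
        group_list = [groups[t] for t in sorted(groups)]
        n_chunks = min(len(group_list), cfg.threads * 4)
        chunks: list[list] = [[] for _ in range(n_chunks)]
        for idx, grp in enumerate(group_list):
            chunks[idx % n_chunks].extend(grp)
        args = []
        for chunk in chunks:
            needed = {p[0].transcript_id for p in chunk}
            args.append(
                ({k: transcripts[k] for k in needed}, chunk, cfg)
            )
        models, defects = [], []
        with ProcessPoolExecutor(max_workers=cfg.threads) as pool:
            for m, d in pool.map(_model_chunk, args):
                models.extend(m)
                defects.extend(d)

    n_collapsed = 0
    if cfg.collapse_identical:
        by_seq: dict[str, ChimericModel] = {}
        for m in models:
            prev = by_seq.get(m.aa_seq)
            if prev is None or m.model_tag < prev.model_tag:
                by_seq[m.aa_seq] = m
        n_collapsed = len(models) - len(by_seq)
        models = list(by_seq.values())
        logger.info("collapsed %d models with identical sequences", n_collapsed)

    models.sort(key=lambda m: m.model_tag)
    per_scenario = {t: 0 for t in SCENARIO_TAGS}
    for m in models:
        per_scenario[m.scenario_tag] += 1
    stats = {
        "n_pairs": len(pairs),
        "n_models": len(models),
        "n_defects": len(defects),
        "n_collapsed": n_collapsed,
        "per_scenario": per_scenario,
    }
    logger.info(
        "modeled %d pairs -> %d models (%d defective removed); per scenario: %s",
        len(pairs), len(models), len(defects),
        {k: v for k, v in per_scenario.items() if v},
    )
    if out is not None:
        write_fasta((FastaRecord(m.model_tag, m.aa_seq) for m in models), out)
    return models, stats
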