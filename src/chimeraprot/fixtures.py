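"""Deterministic synthetic transcripts with planted ORF geometries.

Every scenario the modeler handles can be planted here with *certified*
stop-free modeling windows, so each printed model count is known in closed
form before the modeler runs.  Certification is self-verifying: the
generated transcript is re-scanned with :func:`~chimeraprot.orf_detector.detect_orfs`
and accepted only if exactly the planted ORFs (and nothing else at or above
the certification threshold) are recovered at the planted coordinates.

Construction is by constrained rejection sampling: bounding stop codons are
written first and their nucleotides locked; stop codons intruding on the
planted spans are resampled codon-by-codon; incidental ORFs elsewhere (the
third frame, the UTR portions) are broken by planting stops at positions
that provably do not disturb any protected span.  Closed-form multi-frame
stop-free construction is over-constrained, so bounded retries back the
whole procedure.

All randomness flows from a single integer seed; the same seed always
yields byte-identical sequences.  Codon usage and GC content are uniform,
not realistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from os import PathLike
from typing import Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    ChimeraProtError,
    ModelingConfig,
    OrfRecord,
    Transcript,
    STOP_CODONS,
    translate_frame,
)
from .chimeric_modeler import count_models_eq1
from .fasta import FastaRecord, write_fasta
from .orf_detector import detect_orfs

logger = logging.getLogger(__name__)


class FixtureError(ChimeraProtError):
    """Certification failed after bounded retries, or infeasible geometry."""


_BASES = "ACGT"
_STOPS = tuple(sorted(STOP_CODONS))
_NONSTOP = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in STOP_CODONS
)

#: Certification threshold: the ORF length the study scanned at (20 aa).
CERT_MIN_LEN_AA = 20

#: Scenario labels accepted by :func:`make_transcriptome`.
SCENARIOS = ("S1_embedded", "S2_partial_overlap", "SPAN_refORF_inside_altORF", "S3_gap")


@dataclass(frozen=True)
class PlantedPair:
    """A certified fixture: transcript, the two planted ORFs, and the model
    count the default-configured modeler must produce for the pair."""

    transcript: Transcript
    host: OrfRecord
    guest: OrfRecord
    scenario: str
    expected_models: int

    def __iter__(self) -> Iterator:
        return iter((self.transcript, self.host, self.guest))


# --- constrained sequence construction --------------------------------------


def _align_up(pos: int, frame: int) -> int:
    """Smallest codon-start position >= pos in the given frame."""
    return pos + ((frame - pos) % 3)


def _codon_at(seq: list[str], start: int) -> str:
    return "".join(seq[start - 1 : start + 2])


def _protected_codons_overlapping(
    regions: Sequence[tuple[int, int, int]], lo: int, hi: int
) -> Iterator[tuple[int, int]]:
    """(frame, codon_start) of protected codons touching nts [lo, hi]."""
    for frame, a, b in regions:
        first = max(a, _align_up(max(lo - 2, a), frame))
        for cs in range(first, min(b - 2, hi) + 1, 3):
            yield frame, cs


def _fix_codon(
    rng: np.random.Generator, seq: list[str], start: int, locked: set[int]
) -> bool:
    """Resample the free nucleotides of a stop codon until it is not a stop."""
    free = [i for i in range(start, start + 3) if i not in locked]
    if not free:
        return False
    for _ in range(30):
        for i in free:
            seq[i - 1] = _BASES[rng.integers(4)]
        if _codon_at(seq, start) not in STOP_CODONS:
            return True
    return False


def _build_certified(
    rng: np.random.Generator,
    length: int,
    planned: Sequence[tuple[int, int, int]],
    required_stops: Sequence[tuple[int, int]],
    min_len_aa: int = CERT_MIN_LEN_AA,
    max_attempts: int = 60,
) -> str:
    """A random sequence whose ORF content is exactly ``planned``.

    ``planned``: (frame, start_nt, end_nt) stop-free spans.
    ``required_stops``: (frame, codon_start_nt) of bounding stop codons.

    Planted spans shorter than ``min_len_aa`` stay protected and bounded but
    are not expected in the detector output.
    """
    planned_set = {
        (f, a, b) for f, a, b in planned if (b - a + 1) // 3 >= min_len_aa
    }
    for _ in range(max_attempts):
        seq = [ _BASES[i] for i in rng.integers(4, size=length) ]
        locked: set[int] = set()
        ok = True
        for _frame, cs in required_stops:
            stop = _STOPS[rng.integers(len(_STOPS))]
            seq[cs - 1 : cs + 2] = list(stop)
            locked.update(range(cs, cs + 3))
        # clear stops from the protected spans (bounded multi-pass: fixing a
        # codon in one frame can create a stop in an overlapping frame)
        for _pass in range(60):
            dirty = False
            for frame, a, b in planned:
                for cs in range(a, b - 1, 3):
                    if _codon_at(seq, cs) in STOP_CODONS:
                        if not _fix_codon(rng, seq, cs, locked):
                            ok = False
                        dirty = True
                if not ok:
                    break
            if not ok or not dirty:
                break
        if not ok or dirty:
            continue
        if _suppress_incidental(rng, seq, planned, planned_set, locked, min_len_aa):
            s = "".join(seq)
            if _verify(s, planned, planned_set, required_stops, min_len_aa):
                return s
    raise FixtureError(
        f"could not certify fixture after {max_attempts} attempts "
        f"(length {length}, {len(planned)} planted ORFs)"
    )


def _suppress_incidental(
    rng: np.random.Generator,
    seq: list[str],
    planned: Sequence[tuple[int, int, int]],
    planned_set: set,
    locked: set[int],
    min_len_aa: int,
) -> bool:
    """Break incidental ORFs by planting stops outside protected spans."""
    for _pass in range(40):
        t = Transcript("certify", "".join(seq))
        found = {
            (o.frame, o.start_nt, o.end_nt) for o in detect_orfs(t, min_len_aa)
        }
        if found == planned_set:
            return True
        if planned_set - found:
            return False  # a planted ORF was broken; reseed
        for frame, s, e in sorted(found - planned_set):
            if not _plant_stop(rng, seq, frame, s, e, planned, locked):
                return False
    return False


def _plant_stop(
    rng: np.random.Generator,
    seq: list[str],
    frame: int,
    s: int,
    e: int,
    planned: Sequence[tuple[int, int, int]],
    locked: set[int],
) -> bool:
    """Plant one stop codon inside ORF (frame, s, e) without side effects."""
    starts = list(range(s, e - 1, 3))
    rng.shuffle(starts)
    for cs in starts:
        if any(i in locked for i in range(cs, cs + 3)):
            continue
        saved = seq[cs - 1 : cs + 2]
        stops = list(_STOPS)
        rng.shuffle(stops)
        for stop in stops:
            seq[cs - 1 : cs + 2] = list(stop)
            if all(
                _codon_at(seq, pcs) not in STOP_CODONS
                for _f, pcs in _protected_codons_overlapping(planned, cs, cs + 2)
            ):
                locked.update(range(cs, cs + 3))
                return True
        seq[cs - 1 : cs + 2] = saved
    return False


def _verify(
    s: str,
    planned: Sequence[tuple[int, int, int]],
    planned_set: set,
    required_stops: Sequence[tuple[int, int]],
    min_len_aa: int,
) -> bool:
    for frame, a, b in planned:
        if "*" in translate_frame(s[a - 1 : b], 1):
            return False
    for _frame, cs in required_stops:
        if s[cs - 1 : cs + 2] not in STOP_CODONS:
            return False
    t = Transcript("certify", s)
    found = {(o.frame, o.start_nt, o.end_nt) for o in detect_orfs(t, min_len_aa)}
    return found == planned_set


def _orf(transcript: Transcript, frame: int, start: int, end: int) -> OrfRecord:
    return OrfRecord(
        transcript_id=transcript.id,
        frame=frame,
        start_nt=start,
        end_nt=end,
        aa_seq=translate_frame(transcript.seq[start - 1 : end], 1),
    )


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# --- closed-form expected counts --------------------------------------------


def expected_embedded_models(
    guest_len_aa: int, cfg: Optional[ModelingConfig] = None
) -> int:
    """Models for a certified embedded pair (both sides, both PRF values)."""
    cfg = cfg or ModelingConfig()
    overlap = min(guest_len_aa, cfg.model_len_cap_aa - cfg.min_arm_scenario1_aa)
    return 2 * count_models_eq1(overlap, cfg.min_arm_scenario1_aa)


def expected_utr_overlap_models(cfg: Optional[ModelingConfig] = None) -> int:
    """Models for one certified partial-overlap side (full windows)."""
    cfg = cfg or ModelingConfig()
    return 2 * (cfg.model_len_cap_aa - cfg.min_arm_scenario1_aa)


def expected_span_models(cfg: Optional[ModelingConfig] = None) -> int:
    """Models for a certified spanning pair.

    The window at the refORF start behaves like a partial overlap (full
    30x2).  At the refORF stop the nominal 30-iteration sweep loses every
    iteration whose ref-frame arm would read through the ref stop codon, so
    only ``(cap - A0) - A0 + 1`` iterations per PRF value survive the defect
    filter.
    """
    cfg = cfg or ModelingConfig()
    w = cfg.model_len_cap_aa - cfg.min_arm_scenario1_aa
    return 2 * w + 2 * (w - cfg.min_arm_scenario1_aa + 1)


# --- scenario generators -----------------------------------------------------


def make_embedded_pair(
    seed,
    host_len_aa: int = 100,
    guest_len_aa: int = 30,
    frames: tuple[int, int] = (3, 1),
    guest_offset_nt: Optional[int] = None,
    transcript_id: Optional[str] = None,
    min_len_aa: int = CERT_MIN_LEN_AA,
) -> PlantedPair:
    """A transcript with a guest altORF embedded in a host refORF.

    ``frames`` is (host, guest).  The guest needs at least 12 host codons on
    each flank so both modeling windows fit without truncation.
    """
    f_h, f_g = frames
    if f_h == f_g:
        raise FixtureError("host and guest must be in different frames")
    h_s = f_h + 3
    h_e = h_s + 3 * host_len_aa - 1
    offset = guest_offset_nt if guest_offset_nt is not None else 3 * (
        (host_len_aa - guest_len_aa) // 2
    )
    g_s = _align_up(h_s + max(offset, 36), f_g)
    g_e = g_s + 3 * guest_len_aa - 1
    if g_e + 36 > h_e:
        raise FixtureError(
            "guest does not fit inside host with >= 12 codons on each flank"
        )
    rng = _rng(seed)
    planned = [(f_h, h_s, h_e), (f_g, g_s, g_e)]
    required = [(f_h, h_s - 3), (f_h, h_e + 1), (f_g, g_s - 3), (f_g, g_e + 1)]
    seq = _build_certified(rng, h_e + 6, planned, required, min_len_aa)
    t = Transcript(transcript_id or f"embedded_seed{seed}", seq)
    return PlantedPair(
        t, _orf(t, f_h, h_s, h_e), _orf(t, f_g, g_s, g_e),
        "S1_embedded", expected_embedded_models(guest_len_aa),
    )


def make_utr_overlap_pair(
    seed,
    side: str = "five_prime",
    alt_len_aa: int = 45,
    ref_len_aa: int = 60,
    frames: tuple[int, int] = (1, 2),
    transcript_id: Optional[str] = None,
    min_len_aa: int = CERT_MIN_LEN_AA,
) -> PlantedPair:
    """A partial-overlap pair: the altORF sticks into the 5' or 3' UTR.

    ``frames`` is (refORF, altORF).  Geometry is sized so the full modeling
    window is stop-free: the overlap spans at least 30 codons of the window
    and the first arm has its 10 upstream codons available.
    """
    f_h, f_g = frames
    if f_h == f_g:
        raise FixtureError("the two ORFs must be in different frames")
    if side not in ("five_prime", "three_prime"):
        raise FixtureError(f"unknown side {side!r}")
    if alt_len_aa < 44 or ref_len_aa < 31:
        raise FixtureError(
            "need alt_len_aa >= 44 and ref_len_aa >= 31 for certified windows"
        )
    if side == "five_prime":
        g_s = f_g + 3
        g_e = g_s + 3 * alt_len_aa - 1
        h_s = _align_up(g_s + 36, f_h)
        h_e = h_s + 3 * ref_len_aa - 1
        if g_e - h_s + 1 < 90 or h_e <= g_e:
            raise FixtureError("overlap too short for a certified window")
        length = h_e + 6
    else:
        h_s = f_h + 3
        h_e = h_s + 3 * ref_len_aa - 1
        g_s = _align_up(h_e - 92, f_g)
        g_e = g_s + 3 * alt_len_aa - 1
        if g_s - h_s < 36 or g_e <= h_e or h_e - g_s + 1 < 88:
            raise FixtureError("overlap too short for a certified window")
        length = g_e + 6
    rng = _rng(seed)
    planned = [(f_h, h_s, h_e), (f_g, g_s, g_e)]
    required = [(f_h, h_s - 3), (f_h, h_e + 1), (f_g, g_s - 3), (f_g, g_e + 1)]
    seq = _build_certified(rng, length, planned, required, min_len_aa)
    t = Transcript(transcript_id or f"utr_{side}_seed{seed}", seq)
    return PlantedPair(
        t, _orf(t, f_h, h_s, h_e), _orf(t, f_g, g_s, g_e),
        "S2_partial_overlap", expected_utr_overlap_models(),
    )


def make_span_pair(
    seed,
    ref_len_aa: int = 40,
    frames: tuple[int, int] = (1, 3),
    transcript_id: Optional[str] = None,
    min_len_aa: int = CERT_MIN_LEN_AA,
) -> PlantedPair:
    """An altORF spanning the whole refORF (both refORF ends in the altORF).

    ``frames`` is (refORF, altORF); the altORF extends at least 12 codons
    past each refORF end.
    """
    f_h, f_g = frames
    if f_h == f_g:
        raise FixtureError("the two ORFs must be in different frames")
    if ref_len_aa < 31:
        raise FixtureError("need ref_len_aa >= 31 for certified windows")
    g_s = f_g + 3
    h_s = _align_up(g_s + 36, f_h)
    h_e = h_s + 3 * ref_len_aa - 1
    alt_len = (h_e + 36 - g_s + 1 + 2) // 3 + 1
    g_e = g_s + 3 * alt_len - 1
    rng = _rng(seed)
    planned = [(f_h, h_s, h_e), (f_g, g_s, g_e)]
    required = [(f_h, h_s - 3), (f_h, h_e + 1), (f_g, g_s - 3), (f_g, g_e + 1)]
    seq = _build_certified(rng, g_e + 6, planned, required, min_len_aa)
    t = Transcript(transcript_id or f"span_seed{seed}", seq)
    return PlantedPair(
        t, _orf(t, f_h, h_s, h_e), _orf(t, f_g, g_s, g_e),
        "SPAN_refORF_inside_altORF", expected_span_models(),
    )


#: Gaps realizable between two maximal stop-to-stop ORFs.  For gaps 1, 2, 4
#: and 5 nt the two bounding stop codons would have to share nucleotides in
#: ways no standard-code assignment allows (every stop starts with T and
#: ends in A or G), so those gaps can never separate detector-emitted ORFs.
def feasible_gap(gap_nt: int) -> bool:
    return gap_nt == 3 or gap_nt >= 6


def make_gap_pair(
    seed,
    gap_nt: int = 7,
    up_len_aa: int = 25,
    down_len_aa: int = 25,
    up_frame: int = 1,
    transcript_id: Optional[str] = None,
    min_len_aa: int = CERT_MIN_LEN_AA,
) -> PlantedPair:
    """Two disjoint ORFs separated by ``gap_nt`` nucleotides.

    The downstream frame follows from the gap (a gap divisible by 3 joins
    same-frame ORFs); for same-frame pairs every codon in the gap region is
    a stop, as maximality requires.  The pair yields one model when
    ``gap_nt`` is within the configured maximum, none otherwise.
    """
    if not feasible_gap(gap_nt):
        raise FixtureError(
            f"gap of {gap_nt} nt cannot separate two maximal stop-to-stop "
            "ORFs under the standard genetic code (feasible: 3 or >= 6)"
        )
    u_s = up_frame + 3
    u_e = u_s + 3 * up_len_aa - 1
    d_s = u_e + 1 + gap_nt
    d_frame = (d_s - 1) % 3 + 1
    d_e = d_s + 3 * down_len_aa - 1
    planned = [(up_frame, u_s, u_e), (d_frame, d_s, d_e)]
    required = [(up_frame, u_s - 3), (d_frame, d_e + 1)]
    if d_frame == up_frame:
        # all in-frame codons from the up-ORF stop to the down-ORF start
        required += [(up_frame, cs) for cs in range(u_e + 1, d_s - 2, 3)]
    else:
        required += [(up_frame, u_e + 1), (d_frame, d_s - 3)]
    rng = _rng(seed)
    seq = _build_certified(rng, d_e + 6, planned, required, min_len_aa)
    t = Transcript(transcript_id or f"gap{gap_nt}_seed{seed}", seq)
    cfg = ModelingConfig()
    up, down = _orf(t, up_frame, u_s, u_e), _orf(t, d_frame, d_s, d_e)
    # refORF role falls to the longer ORF (tie: smaller start) = up here
    host, guest = (up, down) if up_len_aa >= down_len_aa else (down, up)
    return PlantedPair(
        t, host, guest, "S3_gap",
        1 if gap_nt <= cfg.max_gap_nt else 0,
    )


_MAKERS = {
    "S1_embedded": make_embedded_pair,
    "S2_partial_overlap": make_utr_overlap_pair,
    "SPAN_refORF_inside_altORF": make_span_pair,
    "S3_gap": make_gap_pair,
}


def make_transcriptome(
    seed,
    n_transcripts: int,
    scenario_mix: Union[str, Sequence[str]] = "S1_embedded",
    out_fasta: Union[str, PathLike, None] = None,
    out_manifest: Union[str, PathLike, None] = None,
    **maker_kwargs,
) -> tuple[list[PlantedPair], pd.DataFrame]:
    """Generate ``n_transcripts`` certified fixtures plus a manifest.

    ``scenario_mix`` is one scenario name or a sequence cycled over the
    transcripts.  The manifest tabulates, per transcript, the planted ORF
    tags and the closed-form expected model count; all randomness derives
    from ``seed``.
    """
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    scenarios = (
        [scenario_mix] if isinstance(scenario_mix, str) else list(scenario_mix)
    )
    for s in scenarios:
        if s not in _MAKERS:
            raise ValueError(f"unknown scenario {s!r}; choose from {SCENARIOS}")
    children = np.random.SeedSequence(seed).spawn(n_transcripts)
    pairs: list[PlantedPair] = []
    rows = []
    for i, child in enumerate(children):
        scenario = scenarios[i % len(scenarios)]
        pair = _MAKERS[scenario](
            child, transcript_id=f"fx{i:06d}_{scenario}", **maker_kwargs
        )
        pairs.append(pair)
        rows.append(
            {
                "transcript_id": pair.transcript.id,
                "scenario": scenario,
                "host_tag": pair.host.tag,
                "guest_tag": pair.guest.tag,
                "expected_models": pair.expected_models,
            }
        )
    manifest = pd.DataFrame(rows)
    if out_fasta is not None:
        write_fasta(
            (FastaRecord(p.transcript.id, p.transcript.seq) for p in pairs),
            out_fasta,
        )
    if out_manifest is not None:
        manifest.to_csv(out_manifest, sep="\t", index=False)
    logger.info(
        "generated %d certified fixtures; expected model total %d",
        n_transcripts, int(manifest["expected_models"].sum()),
    )
    return pairs, manifest
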