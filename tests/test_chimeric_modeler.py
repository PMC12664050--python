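"""Pair classification, junction mechanics, and per-scenario model counts."""

import random
from collections import Counter

import pytest

from chimeraprot import (
    ChimeraProtError,
    ConsistencyError,
    JunctionDefect,
    ModelingConfig,
    OrfRecord,
    Transcript,
    build_junction,
    classify_pair,
    count_models_eq1,
    enumerate_pairs,
    generate_models_for_pair,
    parse_model_tag,
    prf_values_between,
)
from chimeraprot.fixtures import (
    make_embedded_pair,
    make_gap_pair,
    make_span_pair,
    make_utr_overlap_pair,
)


class TestPrfValues:
    @pytest.mark.parametrize(
        "f_from,f_to,expected",
        [
            (3, 1, {1, -2}),
            (1, 3, {2, -1}),
            (1, 2, {1, -2}),
            (2, 1, {-1, 2}),
            (2, 3, {1, -2}),
            (3, 2, {-1, 2}),
            (2, 2, set()),
            (1, 1, set()),
        ],
    )
    def test_values(self, f_from, f_to, expected):
        assert prf_values_between(f_from, f_to) == expected

    def test_modular_arithmetic_oracle(self):
        # a slip of d nucleotides lands in frame ((f-1+d) mod 3)+1
        for f_from in (1, 2, 3):
            for d in (-2, -1, 1, 2):
                f_to = (f_from - 1 + d) % 3 + 1
                assert d in prf_values_between(f_from, f_to)

    def test_invalid_frame(self):
        with pytest.raises(ValueError):
            prf_values_between(0, 1)


class TestCountModelsEq1:
    @pytest.mark.parametrize(
        "overlap,minimum,expected",
        [(30, 10, 42), (10, 10, 2), (20, 10, 22), (21, 10, 24)],
    )
    def test_values(self, overlap, minimum, expected):
        assert count_models_eq1(overlap, minimum) == expected

    def test_preconditions(self):
        with pytest.raises(ValueError):
            count_models_eq1(9, 10)
        with pytest.raises(ValueError):
            count_models_eq1(10, 0)


def _rec(tid, frame, start, end):
    n_aa = (end - start + 1) // 3
    return OrfRecord(tid, frame, start, end, "A" * n_aa)


class TestClassifyPair:
    def test_embedded_guest(self):
        host = _rec("t", 1, 100, 699)  # 200 aa
        guest = _rec("t", 3, 420, 509)  # 30 aa, inside host
        c = classify_pair(guest, host, b_is_ref=True)
        assert c.scenario == "S1_embedded"
        assert c.sides == {"five_prime", "three_prime"}
        assert (c.host, c.guest) == (host, guest)
        assert c.overlap == (420, 509)

    def test_partial_overlap_five_prime(self):
        host = _rec("t", 1, 100, 699)
        guest = _rec("t", 2, 5, 199)  # starts before host, ends inside
        c = classify_pair(guest, host, b_is_ref=True)
        assert c.scenario == "S2_partial_overlap"
        assert c.sides == {"five_prime"}

    def test_partial_overlap_three_prime(self):
        host = _rec("t", 1, 100, 699)
        guest = _rec("t", 2, 650, 799)
        c = classify_pair(guest, host, b_is_ref=True)
        assert c.scenario == "S2_partial_overlap"
        assert c.sides == {"three_prime"}

    def test_span_ref_inside_alt(self):
        ref = _rec("t", 1, 100, 399)
        alt = _rec("t", 3, 6, 500)  # contains the refORF
        c = classify_pair(alt, ref, b_is_ref=True)
        assert c.scenario == "SPAN_refORF_inside_altORF"
        assert c.sides == {"five_prime", "three_prime"}
        assert (c.host, c.guest) == (ref, alt)

    def test_gap_five_nt(self):
        up = _rec("t", 1, 100, 198)
        down = _rec("t", 3, 204, 302)  # gap = 204-198-1 = 5
        c = classify_pair(down, up, b_is_ref=True)
        assert c.scenario == "S3_gap"
        assert c.gap_nt == 5

    @pytest.mark.parametrize("down_start,expected", [(199, "none"), (211, "none")])
    def test_abutting_and_wide_gaps_excluded(self, down_start, expected):
        # gap 0 (abutting) and gap 11 both fall outside the 1..10 window
        up = _rec("t", 1, 100, 198)
        frame = (down_start - 1) % 3 + 1
        down = _rec("t", frame, down_start, down_start + 89)
        c = classify_pair(down, up, b_is_ref=True)
        assert c.scenario == expected

    def test_alt_alt_longer_takes_ref_role(self):
        long_alt = _rec("t", 1, 100, 699)
        short_alt = _rec("t", 3, 420, 509)
        c = classify_pair(short_alt, long_alt)
        assert c.scenario == "S1_embedded"
        assert c.host == long_alt

    def test_alt_alt_tie_smaller_start_is_host(self):
        a = _rec("t", 1, 10, 99)
        b = _rec("t", 2, 50, 139)
        c = classify_pair(b, a)
        assert c.host == a

    def test_same_frame_overlap_is_inconsistent(self):
        a = _rec("t", 1, 100, 399)
        b = _rec("t", 1, 250, 549)
        with pytest.raises(ConsistencyError):
            classify_pair(a, b)

    def test_different_transcripts_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(_rec("t1", 1, 1, 90), _rec("t2", 2, 2, 91))


class TestBuildJunction:
    def test_arms_come_from_their_orfs(self, embedded_pair):
        t, host, guest = embedded_pair
        delta = sorted(prf_values_between(host.frame, guest.frame))[0]
        junction = guest.start_nt - 1 - delta
        res = build_junction(t, host, guest, junction, 10, delta, 40)
        left, right = res
        assert (len(left), len(right)) == (10, 30)
        assert left in host.aa_seq
        assert right in guest.aa_seq

    def test_two_deltas_offset_by_one_codon(self, embedded_pair):
        # the two PRF values of a frame pair differ by 3 nt, so for a fixed
        # junction the right arms are shifted by exactly one codon
        t, host, guest = embedded_pair
        d_fwd, d_bwd = max(prf_values_between(host.frame, guest.frame)), min(
            prf_values_between(host.frame, guest.frame)
        )
        assert d_fwd - d_bwd == 3
        junction = guest.start_nt + 45  # mid-guest
        junction += (host.frame - 1 - junction) % 3  # align to a host codon end
        _, right_fwd = build_junction(t, host, guest, junction, 10, d_fwd, 20)
        _, right_bwd = build_junction(t, host, guest, junction, 10, d_bwd, 20)
        assert right_bwd[1:] == right_fwd[:-1]

    def test_planted_stop_is_a_defect(self, embedded_pair):
        t, host, guest = embedded_pair
        delta = sorted(prf_values_between(host.frame, guest.frame))[0]
        junction = guest.start_nt - 1 - delta
        # plant a stop 5 codons into the shifted frame (inside the right arm)
        pos = junction + delta + 3 * 4  # 0-based start of the 5th right codon
        mutated = Transcript(t.id, t.seq[:pos] + "TAA" + t.seq[pos + 3 :])
        res = build_junction(mutated, host, guest, junction, 10, delta, 40)
        assert isinstance(res, JunctionDefect)
        assert res.reason == "stop_in_right_arm"

    def test_arm_leaving_orf_span_is_a_defect(self, embedded_pair):
        t, host, guest = embedded_pair
        delta = sorted(prf_values_between(host.frame, guest.frame))[0]
        junction = guest.start_nt - 1 - delta
        res = build_junction(t, host, guest, junction, 10, delta, 45)
        assert isinstance(res, JunctionDefect)
        assert res.reason == "right_arm_outside_orf"

    def test_inconsistent_delta_rejected(self, embedded_pair):
        t, host, guest = embedded_pair
        deltas = prf_values_between(host.frame, guest.frame)
        bad = next(d for d in (-2, -1, 1, 2) if d not in deltas)
        junction = guest.start_nt + (host.frame - 1 - guest.start_nt) % 3
        with pytest.raises(ValueError, match="inconsistent"):
            build_junction(t, host, guest, junction, 10, bad, 40)


def _models(pair, cfg=None, defects=None):
    c = classify_pair(pair.guest, pair.host, cfg, b_is_ref=True)
    return generate_models_for_pair(pair.transcript, c, cfg, defects)


class TestGenerateModels:
    def test_embedded_30aa_guest_counts(self, embedded_pair):
        models = _models(embedded_pair)
        by_side = Counter(m.scenario_tag for m in models)
        assert by_side == {
            "Within_5prime_of_altORF": 42,
            "Within_3prime_of_altORF": 42,
        }
        # equal numbers per PRF value within each side
        per_delta = Counter((m.scenario_tag, m.prf_value) for m in models)
        assert set(per_delta.values()) == {21}

    def test_embedded_20aa_guest_truncated_window(self):
        pair = make_embedded_pair(2, guest_len_aa=20)
        models = _models(pair)
        assert Counter(m.scenario_tag for m in models) == {
            "Within_5prime_of_altORF": 22,
            "Within_3prime_of_altORF": 22,
        }
        # short guest: every model is 10 aa + the 20-aa window = 30 aa
        assert {m.length_aa for m in models} == {30}

    def test_s1_count_matches_equation_for_random_overlaps(self):
        rng = random.Random(23)
        for _ in range(12):
            g = rng.randint(10, 30)
            frames = rng.choice([(3, 1), (1, 2), (2, 3), (1, 3)])
            pair = make_embedded_pair(rng.randrange(2**31), guest_len_aa=g, frames=frames)
            per_side = count_models_eq1(min(g, 30), 10)
            assert len(_models(pair)) == 2 * per_side

    @pytest.mark.parametrize("side,tag", [
        ("five_prime", "Overlap_5prime_UTR"),
        ("three_prime", "Overlap_3prime_UTR"),
    ])
    def test_utr_overlap_sides(self, side, tag):
        pair = make_utr_overlap_pair(3, side=side)
        models = _models(pair)
        assert Counter(m.scenario_tag for m in models) == {tag: 60}
        # 30 iterations x 2 PRF values; the last model keeps 1 aa of arm 2
        assert min(len(m.right_arm_aa) for m in models) == 1
        assert max(m.length_aa for m in models) == 40

    def test_span_pair_sides(self):
        pair = make_span_pair(4)
        defects = []
        models = _models(pair, defects=defects)
        by_side = Counter(m.scenario_tag for m in models)
        assert by_side["Span_5prime_of_refORF"] == 60
        # at the refORF stop the sweep loses the iterations whose ref arm
        # would read through the stop codon: 21 survive per PRF value
        assert by_side["Span_3prime_of_refORF"] == 42
        assert all(d.reason == "left_arm_outside_orf" for d in defects)

    @pytest.mark.parametrize("gap", [3, 6, 7, 10])
    def test_gap_single_model(self, gap):
        pair = make_gap_pair(5, gap_nt=gap)
        models = _models(pair)
        assert len(models) == 1
        m = models[0]
        assert m.prf_value == gap
        assert (m.iteration, m.length_aa) == (1, 40)
        assert (len(m.left_arm_aa), len(m.right_arm_aa)) == (20, 20)

    def test_gap_can_join_same_frame_orfs(self):
        pair = make_gap_pair(6, gap_nt=6)
        assert pair.host.frame == pair.guest.frame
        assert len(_models(pair)) == 1

    def test_gap_eleven_generates_nothing(self):
        pair = make_gap_pair(7, gap_nt=11)
        assert _models(pair) == []

    def test_defects_accounted_individually(self, embedded_pair):
        t, host, guest = embedded_pair
        # plant a stop 5 codons into the guest: some right arms of the
        # five-prime sweep now read through it and are dropped as defects
        pos = guest.start_nt - 1 + 3 * 5
        mutated = Transcript(t.id, t.seq[:pos] + "TAA" + t.seq[pos + 3 :])
        defects = []
        c = classify_pair(guest, host, b_is_ref=True)
        models = generate_models_for_pair(mutated, c, defects=defects)
        assert len(models) < 84
        assert len(models) + len(defects) == 84
        assert all(isinstance(d, JunctionDefect) for d in defects)

    def test_models_respect_cap_and_are_stop_free(self):
        rng = random.Random(29)
        makers = [
            lambda s: make_embedded_pair(s, guest_len_aa=rng.randint(10, 30)),
            lambda s: make_utr_overlap_pair(s, side=rng.choice(["five_prime", "three_prime"])),
            make_span_pair,
            lambda s: make_gap_pair(s, gap_nt=rng.choice([3, 6, 7, 8, 9, 10])),
        ]
        for maker in makers:
            for _ in range(3):
                pair = maker(rng.randrange(2**31))
                for m in _models(pair):
                    assert m.length_aa <= 40
                    assert "*" not in m.aa_seq

    def test_model_tag_regenerates_model(self, embedded_pair):
        # the tag alone (plus transcript and catalogs) pins down the model:
        # re-running the pair and matching scenario/PRF/iteration recovers
        # identical arms
        t, host, guest = embedded_pair
        models = _models(embedded_pair)
        by_key = {
            (m.scenario_tag, m.prf_value, m.iteration): m for m in models
        }
        assert len(by_key) == len(models)
        for m in models[:: 7]:
            f = parse_model_tag(m.model_tag)
            assert f.orf_a.tag in (host.tag, guest.tag)
            again = by_key[(f.scenario_tag, f.prf_value, f.iteration)]
            assert (again.left_arm_aa, again.right_arm_aa) == (
                m.left_arm_aa, m.right_arm_aa,
            )


class TestEnumeratePairs:
    def test_all_paired_combinations(self, embedded_pair):
        t, host, guest = embedded_pair
        # two candidate altORFs A,B plus one refORF C on one transcript
        a, b, c = guest, _shift_tag(guest, t), host
        pairs = enumerate_pairs([a.tag, b.tag], [a, b], [c])
        names = {frozenset((p[0].tag, p[1].tag)) for p in pairs}
        assert names == {
            frozenset((a.tag, c.tag)),
            frozenset((b.tag, c.tag)),
            frozenset((a.tag, b.tag)),
        }

    def test_candidate_order_is_irrelevant(self, embedded_pair):
        t, host, guest = embedded_pair
        a, b = guest, _shift_tag(guest, t)
        fwd = enumerate_pairs([a.tag, b.tag], [a, b], [host])
        rev = enumerate_pairs([b.tag, a.tag], [a, b], [host])
        assert fwd == rev

    def test_lonely_candidate_yields_nothing(self, embedded_pair):
        _, _, guest = embedded_pair
        assert enumerate_pairs([guest.tag], [guest], []) == []

    def test_missing_candidate_is_hard_error(self, embedded_pair):
        _, host, guest = embedded_pair
        with pytest.raises(ChimeraProtError, match="nonexistent"):
            enumerate_pairs(["nonexistent_1F_1-90_90"], [guest], [host])


def _shift_tag(orf, t):
    """A second altORF record three codons downstream (same frame)."""
    return OrfRecord(
        orf.transcript_id, orf.frame, orf.start_nt + 9, orf.end_nt,
        orf.aa_seq[3:],
    )
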