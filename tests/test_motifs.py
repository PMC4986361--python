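import math

import numpy as np
import pytest

from summitshift.consensus import CoPeak, ConsensusSummit
from summitshift.formats_io import PWM, GenomicInterval
from summitshift.motifs import (
    MotifSite,
    assign_cts,
    cts_center_and_orientation,
    reverse_complement,
    scan_pwm,
)


def brute_force_scan(sequence, pwm, threshold):
    """Per-window, per-strand score enumeration in plain Python."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = len(pwm)
    hits = []
    for start in range(len(sequence) - L + 1):
        window = sequence[start : start + L]
        for strand in ("+", "-"):
            probe = window if strand == "+" else reverse_complement(window)
            if any(b not in idx for b in probe):
                continue
            score = sum(
                math.log(pwm.matrix[i, idx[b]] / pwm.background[idx[b]])
                for i, b in enumerate(probe)
            )
            if score >= threshold:
                hits.append((start, strand, score))
    return hits


def sharp_pwm(consensus, p=0.97):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    m = np.full((len(consensus), 4), (1 - p) / 3)
    for i, b in enumerate(consensus):
        m[i, idx[b]] = p
    return PWM(matrix=m)


class TestScanPwm:
    def test_uniform_pwm_scores_zero_everywhere(self, uniform_pwm):
        assert scan_pwm("ACGTACGTACGT", uniform_pwm, threshold=6) == []
        hits = scan_pwm("ACGTACGT", uniform_pwm, threshold=0.0, both_strands=False)
        assert all(h.score == 0.0 for h in hits) and len(hits) == 5

    def test_consensus_score_closed_form(self):
        pwm = sharp_pwm("ACGT")
        (hit,) = [h for h in scan_pwm("ACGT", pwm, threshold=5.0) if h.strand == "+"]
        assert hit.score == pytest.approx(4 * math.log(0.97 / 0.25), abs=1e-12)

    def test_consensus_attains_maximum_over_random_windows(self):
        pwm = sharp_pwm("ACGTA")
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 300)) + "ACGTA"
        hits = scan_pwm(seq, pwm, threshold=-1e9, both_strands=False)
        best = max(hits, key=lambda h: h.score)
        assert seq[best.interval.start : best.interval.end] == "ACGTA"

    def test_sequence_shorter_than_motif(self):
        assert scan_pwm("AC", sharp_pwm("ACGTA"), threshold=0) == []

    def test_windows_with_n_never_hit(self):
        pwm = sharp_pwm("ACGT")
        assert scan_pwm("ACNT", pwm, threshold=-1e9) == []

    def test_matches_brute_force_on_random_kilobase(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), 1000))
        pwm = sharp_pwm("TGCAT", p=0.7)
        threshold = 1.0
        got = sorted(
            (h.interval.start, h.strand, h.score)
            for h in scan_pwm(seq, pwm, threshold=threshold)
        )
        expected = sorted(brute_force_scan(seq, pwm, threshold))
        assert [(s, st) for s, st, _ in got] == [(s, st) for s, st, _ in expected]
        assert np.allclose([x[2] for x in got], [x[2] for x in expected])

    def test_reverse_complement_mirrors_hit_set(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), 400))
        pwm = sharp_pwm("GATTACA", p=0.6)
        fwd = scan_pwm(seq, pwm, threshold=0.5)
        rc = scan_pwm(reverse_complement(seq), pwm, threshold=0.5)
        L = len(seq)
        mirrored = sorted(
            (L - h.interval.end, "-" if h.strand == "+" else "+", round(h.score, 9))
            for h in rc
        )
        assert mirrored == sorted(
            (h.interval.start, h.strand, round(h.score, 9)) for h in fwd
        )


def site(start, end, strand="+", score=10.0, chrom="chr1"):
    return MotifSite(interval=GenomicInterval(chrom, start, end, strand), score=score)


def copeak(ctcf_pos, cohesin_pos, chrom="chr1"):
    return CoPeak(
        ctcf=ConsensusSummit(chrom, ctcf_pos, "CTCF", 2),
        cohesin=ConsensusSummit(chrom, cohesin_pos, "cohesin", 2),
    )


class TestAssignCts:
    def test_no_candidate(self):
        a = assign_cts(copeak(100, 110), [])
        assert a.cts is None and a.rule_used == "none_found"

    def test_single_candidate(self):
        c = site(95, 114)
        a = assign_cts(copeak(100, 110), [c])
        assert a.cts == c and a.rule_used == "single"

    def test_overlapping_candidates_collapse_to_best_score(self):
        lo = site(95, 114, score=8.1)
        hi = site(100, 119, score=10.3)
        a = assign_cts(copeak(105, 115), [lo, hi])
        assert a.cts == hi and a.rule_used == "overlap_best_score"

    def test_disjoint_candidates_prefer_shift_following(self):
        # cohesin at 130: the "+" site centered at 109 has it downstream in
        # motif orientation; the "-" site centered at 69 has it upstream
        # (for a "-" motif, downstream means lower genomic coordinates)
        plus = site(100, 119, "+", score=7.0)
        minus = site(60, 79, "-", score=12.0)
        a = assign_cts(copeak(105, 130), [plus, minus], window=50)
        assert a.cts == plus and a.rule_used == "shift_following"

    def test_opposite_orientation_falls_back_to_best_score(self):
        # cohesin upstream of both "+" motif centers -> neither follows
        a1 = site(60, 79, "+", score=7.0)
        a2 = site(90, 109, "+", score=9.0)
        a = assign_cts(copeak(90, 55), [a1, a2], window=50)
        assert a.cts == a2 and a.rule_used == "opposite_best_score"

    def test_candidates_outside_window_ignored(self):
        far = site(300, 319)
        a = assign_cts(copeak(100, 110), [far], window=50)
        assert a.rule_used == "none_found"

    def test_deterministic_and_input_order_invariant(self):
        minus = site(90, 109, "-", score=5.0)
        plus = site(110, 129, "+", score=5.0)
        a = assign_cts(copeak(110, 40), [minus, plus], window=50)
        b = assign_cts(copeak(110, 40), [plus, minus], window=50)
        assert a.cts == b.cts and a.rule_used == b.rule_used
        assert a.cts is not None

    def test_equal_score_tie_prefers_plus_strand(self):
        # both disjoint sites follow the shift with equal scores
        plus = site(100, 119, "+", score=5.0)
        minus = site(60, 79, "-", score=5.0)
        a = assign_cts(copeak(105, 85), [plus, minus], window=50)
        # cohesin at 85: downstream of neither? for "+": 85 < 109 (no);
        # for "-": 85 > 69 (no) -> fallback, tie broken to "+"
        assert a.rule_used == "opposite_best_score" and a.cts == plus


class TestCtsCenter:
    def test_odd_length_integer_center(self):
        center, orient = cts_center_and_orientation(site(1000, 1019))
        assert (center, orient) == (1009.0, "+")

    def test_even_length_half_integer_center(self):
        center, _ = cts_center_and_orientation(site(1000, 1020))
        assert center == 1009.5

    def test_strand_flip_preserves_center(self):
        assert site(1000, 1019, "+").center == site(1000, 1019, "-").center
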