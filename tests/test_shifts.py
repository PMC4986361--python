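import numpy as np
import pandas as pd
import pytest

from conftest import make_summit
from summitshift.consensus import CoPeak, ConsensusSummit
from summitshift.formats_io import FragmentSet, GenomicInterval
from summitshift.motifs import CtsAssignment, MotifSite
from summitshift.shifts import (
    CoverageProfile,
    NoSignalError,
    ShiftRecord,
    average_coverage_profile,
    distance_to_anchor,
    oriented_offset,
    profile_maximum,
    rolling_mean,
    summarize_shifts,
    summit_shift_table,
)


def cts(start=1000, length=19, strand="+", chrom="chr1"):
    return MotifSite(
        interval=GenomicInterval(chrom, start, start + length, strand), score=10.0
    )


def assignment(site):
    cp = CoPeak(
        ctcf=ConsensusSummit(site.chrom, int(site.center), "CTCF", 2),
        cohesin=ConsensusSummit(site.chrom, int(site.center) + 6, "cohesin", 2),
    )
    return CtsAssignment(copeak=cp, cts=site, rule_used="single")


class TestOrientedOffset:
    def test_plus_strand(self):
        assert oriented_offset(1005, cts()) == -4.0  # center 1009.0

    def test_minus_strand_antisymmetry(self):
        assert oriented_offset(1013, cts(strand="-")) == -4.0

    def test_zero_at_center_both_strands(self):
        assert oriented_offset(1009, cts()) == 0.0
        assert oriented_offset(1009, cts(strand="-")) == 0.0

    def test_chromosome_mismatch_raises(self):
        with pytest.raises(ValueError):
            oriented_offset(1005, cts(), chrom="chr2")

    def test_strand_flip_negates_any_offset(self):
        rng = np.random.default_rng(0)
        for pos in rng.integers(900, 1100, 20):
            plus = oriented_offset(int(pos), cts(strand="+"))
            minus = oriented_offset(int(pos), cts(strand="-"))
            assert plus == -minus


def frag(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def brute_force_profile(fragments, cts_set, W):
    total = np.zeros(2 * W + 1)
    for site in cts_set:
        anchor = int(np.floor(site.center))
        depth = np.zeros(2 * W + 1)
        for k, p in enumerate(range(anchor - W, anchor + W + 1)):
            depth[k] = sum(
                1
                for f in fragments.fragments
                if f.chrom == site.chrom and f.start <= p < f.end
            )
        if site.strand == "-":
            depth = depth[::-1]
        total += depth
    return total / len(cts_set)


class TestAverageCoverageProfile:
    def test_full_window_fragment_gives_constant_one(self):
        site = cts(1000)
        fs = FragmentSet("a", [frag(800, 1300)])
        prof = average_coverage_profile(fs, [site], half_window=100)
        assert np.all(prof.depth == 1.0)

    def test_minus_strand_window_is_reversed(self):
        site = cts(1000, strand="-")  # center 1009
        fs = FragmentSet("a", [frag(1014, 1020)])  # genomic offsets +5..+10
        prof = average_coverage_profile(fs, [site], half_window=20)
        covered = prof.offsets[prof.depth > 0]
        assert covered.min() == -10 and covered.max() == -5

    def test_two_sites_average(self):
        s1, s2 = cts(1000), cts(5000)
        fs = FragmentSet("a", [frag(1009, 1010), frag(1009, 1010)])  # depth 2 at s1
        prof = average_coverage_profile(fs, [s1, s2], half_window=10)
        assert prof.depth[prof.offsets == 0][0] == 1.0

    def test_empty_cts_set_raises(self):
        with pytest.raises(ValueError):
            average_coverage_profile(FragmentSet("a", []), [], half_window=10)

    def test_matches_per_bp_overlap_oracle(self):
        rng = np.random.default_rng(13)
        sites = [
            cts(int(p), strand=str(rng.choice(["+", "-"])))
            for p in rng.integers(200, 3000, 5)
        ]
        frags = [
            frag(int(s), int(s) + int(rng.integers(20, 300)))
            for s in rng.integers(0, 3200, 50)
        ]
        fs = FragmentSet("a", frags)
        prof = average_coverage_profile(fs, sites, half_window=60)
        assert np.allclose(prof.depth, brute_force_profile(fs, sites, 60))


class TestProfileMaximum:
    def test_triangle_apex(self):
        offs = np.arange(-5, 6)
        depth = 10.0 - np.abs(offs - 3)
        prof = CoverageProfile(offsets=offs, depth=depth, n_sites=1)
        pos, _ = profile_maximum(prof, smooth_window=1)
        assert pos == 3

    def test_constant_profile_ties_to_zero(self):
        prof = CoverageProfile(np.arange(-5, 6), np.ones(11), n_sites=1)
        assert profile_maximum(prof)[0] == 0

    def test_negative_wins_absolute_tie(self):
        offs = np.arange(-2, 3)
        depth = np.array([0, 1.0, 0, 1.0, 0])
        prof = CoverageProfile(offs, depth, n_sites=1)
        assert profile_maximum(prof, smooth_window=1)[0] == -1

    def test_delta_smoothed_to_one_fifth(self):
        offs = np.arange(-5, 6)
        depth = np.zeros(11)
        depth[5] = 5.0
        prof = CoverageProfile(offs, depth, n_sites=1)
        pos, height = profile_maximum(prof, smooth_window=5)
        assert pos == 0 and height == pytest.approx(1.0)

    def test_all_zero_raises_no_signal(self):
        prof = CoverageProfile(np.arange(-2, 3), np.zeros(5), n_sites=1)
        with pytest.raises(NoSignalError):
            profile_maximum(prof)


class TestRollingMean:
    def test_mass_conserved_up_to_edges(self):
        v = np.array([0, 0, 6.0, 0, 0])
        sm = rolling_mean(v, 3)
        assert sm.sum() == pytest.approx(v.sum())

    def test_edge_windows_shrink(self):
        sm = rolling_mean([3.0, 0, 0], 3)
        assert sm[0] == pytest.approx(1.5)  # mean of first two only


class TestSummitShiftTable:
    def test_offset_sign_convention(self):
        site = cts(1000)  # center 1009
        summits = [make_summit("chr1", 1005, "s1", "CTCF")]
        (rec,) = summit_shift_table(summits, [assignment(site)])
        assert rec.offset == -4.0

    def test_no_summit_in_window_no_record(self):
        site = cts(1000)
        summits = [make_summit("chr1", 1100, "s1", "CTCF")]
        assert summit_shift_table(summits, [assignment(site)]) == []

    def test_nearest_summit_chosen(self):
        site = cts(1000)  # center 1009
        summits = [
            make_summit("chr1", 1006, "s1", "RAD21"),  # offset -3
            make_summit("chr1", 1029, "s1", "RAD21"),  # offset +20
        ]
        (rec,) = summit_shift_table(summits, [assignment(site)])
        assert rec.offset == -3.0

    def test_one_record_per_protein_sample_group(self):
        site = cts(1000)
        summits = [
            make_summit("chr1", 1005, "s1", "CTCF"),
            make_summit("chr1", 1010, "s2", "CTCF"),
            make_summit("chr1", 1015, "s1", "RAD21"),
        ]
        recs = summit_shift_table(summits, [assignment(site)])
        assert len(recs) == 3
        assert {(r.protein, r.sample_id) for r in recs} == {
            ("CTCF", "s1"), ("CTCF", "s2"), ("RAD21", "s1")
        }


class TestSummarizeShifts:
    def test_degenerate_group(self):
        recs = [ShiftRecord("CTCF", "s1", f"c{i}", -4.0) for i in range(3)]
        row = summarize_shifts(recs).iloc[0]
        assert row["median"] == -4.0 and row["sd"] == 0.0

    def test_interpolated_quartiles(self):
        recs = [ShiftRecord("CTCF", "s1", f"c{i}", o) for i, o in enumerate([-6, -4, -2])]
        row = summarize_shifts(recs).iloc[0]
        assert (row["mean"], row["median"]) == (-4.0, -4.0)
        assert (row["q1"], row["q3"]) == (-5.0, -3.0)

    def test_grouping_contract(self):
        recs = [
            ShiftRecord("CTCF", "s1", "c1", -4.0),
            ShiftRecord("CTCF", "s2", "c1", -2.0),
        ]
        assert len(summarize_shifts(recs, by="protein")) == 1
        assert len(summarize_shifts(recs, by="protein_sample")) == 2

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            out = summarize_shifts([])
        assert out.empty


class TestDistanceToAnchor:
    def test_signed_difference(self):
        coh = [ShiftRecord("RAD21", "s1", "c1", 6.0)]
        ctcf = [ShiftRecord("CTCF", "s1", "c1", -4.0)]
        hist = distance_to_anchor(coh, ctcf, smooth_window=1)["RAD21"]
        assert hist.loc[hist["frequency"] > 0, "distance"].tolist() == [10]

    def test_identical_offsets_give_zero(self):
        coh = [ShiftRecord("SMC3", "s1", "c1", 2.0)]
        ctcf = [ShiftRecord("CTCF", "s1", "c1", 2.0)]
        hist = distance_to_anchor(coh, ctcf, smooth_window=1)["SMC3"]
        assert hist.loc[hist["frequency"] > 0, "distance"].tolist() == [0]

    def test_mass_equals_shared_records(self):
        rng = np.random.default_rng(4)
        coh = [
            ShiftRecord("RAD21", "s1", f"c{i}", float(rng.integers(-10, 10)))
            for i in range(30)
        ]
        ctcf = [
            ShiftRecord("CTCF", "s1", f"c{i}", float(rng.integers(-10, 10)))
            for i in range(20)  # only 20 shared sites
        ]
        hist = distance_to_anchor(coh, ctcf, smooth_window=1)["RAD21"]
        assert hist["frequency"].sum() == 20

    def test_cross_sample_anchor_uses_site_mean(self):
        coh = [ShiftRecord("RAD21", "r1", "c1", 6.0)]
        ctcf = [
            ShiftRecord("CTCF", "a1", "c1", -3.0),
            ShiftRecord("CTCF", "a2", "c1", -5.0),
        ]
        hist = distance_to_anchor(coh, ctcf, smooth_window=1)["RAD21"]
        assert hist.loc[hist["frequency"] > 0, "distance"].tolist() == [10]


class TestGlobalAntisymmetry:
    def test_flipping_cts_strands_negates_all_offsets(self, noisy_dataset):
        from summitshift.pipeline import run_shift_from_dataset

        result = run_shift_from_dataset(noisy_dataset)
        flipped_assignments = []
        for a in result.assignments:
            if a.cts is None:
                flipped_assignments.append(a)
                continue
            iv = a.cts.interval
            flipped = MotifSite(
                interval=GenomicInterval(
                    iv.chrom, iv.start, iv.end, "-" if iv.strand == "+" else "+"
                ),
                score=a.cts.score,
            )
            flipped_assignments.append(
                CtsAssignment(copeak=a.copeak, cts=flipped, rule_used=a.rule_used)
            )
        flipped_records = summit_shift_table(
            noisy_dataset.summits, flipped_assignments
        )
        orig = result.records.sort_values(["protein", "sample_id", "cts_id"])
        flip = (
            pd.DataFrame(
                [(r.protein, r.sample_id, r.offset) for r in flipped_records],
                columns=["protein", "sample_id", "offset"],
            )
            .sort_values(["protein", "sample_id"])
        )
        a = np.sort(orig["offset"].to_numpy())
        b = np.sort(-flip["offset"].to_numpy())
        assert np.array_equal(a, b)
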