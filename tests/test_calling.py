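"""Arm-level CNA calling: threshold examples, the per-base oracle, the
clonality filter and SEG round-trips."""

import numpy as np
import pandas as pd
import pytest

from mmstrat import calling, simulate as sim
from mmstrat.calling import call_arm_events, filter_major, load_seg
from mmstrat.catalogue import arm_table, focal_regions

from conftest import seg_frame


def per_base_oracle(segments, arms, focal, broad_fraction=0.25):
    """Brute-force caller: materialise a per-base CN vector per arm and
    compute qualifying fractions / focal overlaps directly."""
    calls = set()
    for _, arm in arms.iterrows():
        s, e = int(arm.start), int(arm.end)
        regions = focal[(focal.chromosome == arm.chromosome) & (focal.arm == arm.arm)]
        for sample in segments["sample_id"].unique():
            cn = np.full(e - s, 2.0)
            segs = segments[(segments.sample_id == sample)
                            & (segments.chromosome == arm.chromosome)]
            for _, row in segs.iterrows():
                lo, hi = max(int(row.start), s), min(int(row.end), e)
                if lo < hi:
                    cn[lo - s:hi - s] = row.cn
            for direction, mask in (("gain", cn >= 2.1), ("loss", cn <= 1.9)):
                qualifies = mask.sum() / (e - s) > broad_fraction
                if not qualifies:
                    for _, reg in regions.iterrows():
                        lo, hi = max(int(reg.start), s), min(int(reg.end), e)
                        if lo < hi and mask[lo - s:hi - s].any():
                            qualifies = True
                            break
                if qualifies:
                    calls.add((sample, int(arm.chromosome), arm.arm, direction))
    return calls


class TestThresholdExamples:
    def test_broad_gain_above_threshold_is_called_clonal(self, toy_arms, toy_focal):
        # 30% of 1q (12000-22000) at CN 2.5, CCF 95 -> broad gain, clonal
        seg = seg_frame([("s", 1, 12000, 15000, 2.5, 0.6, 95.0)])
        calls = call_arm_events(seg, toy_arms, toy_focal)
        assert len(calls) == 1
        c = calls.iloc[0]
        assert (c.variable, c.level, c.basis, c.clonality_class) == \
            ("Amp 1q", "gain", "broad", "clonal")

    def test_cn_just_below_gain_threshold_never_calls(self, toy_arms, toy_focal):
        seg = seg_frame([("s", 1, 12000, 22000, 2.05, 0.6, 99.0)])
        assert len(call_arm_events(seg, toy_arms, toy_focal)) == 0

    def test_focal_homozygous_loss_small_span(self, toy_arms, toy_focal):
        # 2% of 13q but overlapping the focal region -> focal homo_loss
        seg = seg_frame([("s", 13, 5100, 5300, 0.5, 0.95, 80.0)])
        calls = call_arm_events(seg, toy_arms, toy_focal)
        assert len(calls) == 1
        c = calls.iloc[0]
        assert c.variable == "Del 13q"
        assert c.level == "homo_loss"
        assert c.basis == "focal:RB1toy"
        assert c.clonality_class == "subclonal_major"
        assert c.loh

    def test_broad_preferred_over_focal_when_both_hold(self, toy_arms, toy_focal):
        seg = seg_frame([("s", 13, 4000, 9000, 1.5, 0.9, 90.0)])  # 50% + focal
        calls = call_arm_events(seg, toy_arms, toy_focal)
        assert list(calls.basis) == ["broad"]

    def test_high_gain_upgrade_is_length_weighted(self, toy_arms, toy_focal):
        # 3.5 over 3kb and 2.5 over 1kb -> weighted mean 3.25 < 3.4: stays gain
        seg = seg_frame([("s", 1, 0, 3000, 3.5, 0.6, 95.0),
                         ("s", 1, 3000, 4000, 2.5, 0.6, 95.0)])
        calls = call_arm_events(seg, toy_arms, toy_focal)
        assert list(calls.level) == ["gain"]
        seg2 = seg_frame([("s", 1, 0, 3000, 3.6, 0.6, 95.0),
                          ("s", 1, 3000, 4000, 3.0, 0.6, 95.0)])
        assert list(call_arm_events(seg2, toy_arms, toy_focal).level) == ["high_gain"]

    def test_sub_minor_ccf_dropped_entirely(self, toy_arms, toy_focal):
        seg = seg_frame([("s", 1, 0, 9000, 2.5, 0.6, 5.0)])
        assert len(call_arm_events(seg, toy_arms, toy_focal)) == 0

    def test_acrocentric_p_coordinates_rejected(self, toy_arms, toy_focal):
        seg = seg_frame([("s", 13, 100, 900, 2.5, 0.6, 95.0)])
        with pytest.raises(ValueError, match="acrocentric"):
            call_arm_events(seg, toy_arms, toy_focal)


def test_per_base_oracle_fuzz(toy_arms, toy_focal):
    """100 random segment layouts agree with the explicit per-base caller."""
    rng = np.random.default_rng(9)
    for case in range(100):
        rows = []
        for sample in ("a", "b"):
            for _, arm in toy_arms.iterrows():
                pos = int(arm.start)
                while pos < int(arm.end) - 200:
                    length = int(rng.integers(200, 4000))
                    end = min(pos + length, int(arm.end))
                    cn = float(rng.choice([0.4, 1.0, 1.8, 2.0, 2.2, 2.5, 3.6]))
                    rows.append((sample, int(arm.chromosome), pos, end, cn,
                                 0.5, float(rng.uniform(20, 100))))
                    pos = end + int(rng.integers(0, 1500))
        seg = seg_frame(rows)
        got = call_arm_events(seg, toy_arms, toy_focal)
        got_keys = set(zip(got.sample_id, got.chromosome, got.arm, got.direction))
        assert got_keys == per_base_oracle(seg, toy_arms, toy_focal), f"case {case}"


def test_gain_monotonicity_under_cn_increase(toy_arms, toy_focal):
    """Raising any segment's CN never removes a gain call."""
    rng = np.random.default_rng(4)
    for _ in range(20):
        rows = [("s", 1, int(a), int(a + 2000),
                 float(rng.choice([1.5, 2.0, 2.3, 3.0])), 0.5, 80.0)
                for a in range(12000, 22000, 2500)]
        seg = seg_frame(rows)
        before = call_arm_events(seg, toy_arms, toy_focal)
        gains_before = set(before[before.direction == "gain"].variable)
        bumped = seg.copy()
        i = int(rng.integers(0, len(bumped)))
        bumped.loc[bumped.index[i], "cn"] += 0.5
        after = call_arm_events(bumped, toy_arms, toy_focal)
        assert gains_before <= set(after[after.direction == "gain"].variable)


class TestFilterMajor:
    def test_keeps_exactly_ccf_at_least_50(self, toy_arms, toy_focal):
        seg = seg_frame([("a", 1, 0, 9000, 2.5, 0.6, 95.0),
                         ("b", 1, 0, 9000, 2.5, 0.6, 60.0),
                         ("c", 1, 0, 9000, 2.5, 0.6, 45.0)])
        calls = call_arm_events(seg, toy_arms, toy_focal)
        major = filter_major(calls)
        assert sorted(major.sample_id) == ["a", "b"]

    def test_empty_input_and_idempotence(self, toy_arms, toy_focal):
        empty = call_arm_events(seg_frame([]), toy_arms, toy_focal)
        assert len(filter_major(empty)) == 0
        seg = seg_frame([("a", 1, 0, 9000, 2.5, 0.6, 95.0)])
        calls = call_arm_events(seg, toy_arms, toy_focal)
        once = filter_major(calls)
        pd.testing.assert_frame_equal(once, filter_major(once))
        assert set(once.index) <= set(calls.index)


def test_clonality_classes_partition_bands():
    from mmstrat.calling import clonality_class
    for ccf, expected in [(95.0, "clonal"), (90.4, "clonal"), (90.0, "subclonal_major"),
                          (50.0, "subclonal_major"), (49.9, "subclonal_minor"),
                          (10.0, "subclonal_minor"), (9.9, None)]:
        assert clonality_class(ccf) == expected


class TestSegIO:
    def test_well_formed_file_roundtrips(self, tmp_path):
        seg = seg_frame([("s", 1, 0, 5000, 2.5, 0.6, 95.0),
                         ("s", 2, 100, 900, 1.5, 0.9, 80.0),
                         ("t", 1, 0, 5000, 2.0, 0.5, 100.0)])
        path = tmp_path / "x.seg"
        sim.write_seg(seg, path)
        back = load_seg(path)
        pd.testing.assert_frame_equal(
            back.sort_values(["sample_id", "chromosome", "start"]).reset_index(drop=True),
            seg.sort_values(["sample_id", "chromosome", "start"]).reset_index(drop=True),
            check_dtype=False)

    def test_start_after_end_names_the_row(self, tmp_path):
        path = tmp_path / "bad.seg"
        path.write_text("Sample\tChromosome\tStart\tEnd\tCN\tBAF\tCCF\n"
                        "s\t1\t100\t50\t2.5\t0.6\t90\n")
        with pytest.raises(ValueError, match=r"line\(s\) \[2\]"):
            load_seg(path)

    def test_non_numeric_cn_rejected_with_line(self, tmp_path):
        path = tmp_path / "bad.seg"
        path.write_text("Sample\tChromosome\tStart\tEnd\tCN\tBAF\tCCF\n"
                        "s\t1\t1\t50\tNA\t0.6\t90\n")
        with pytest.raises(ValueError, match="non-numeric"):
            load_seg(path)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.seg"
        path.write_text("Sample\tChromosome\tStart\n")
        with pytest.raises(ValueError, match="missing columns"):
            load_seg(path)

    def test_overlapping_segments_rejected(self, tmp_path):
        path = tmp_path / "bad.seg"
        path.write_text("Sample\tChromosome\tStart\tEnd\tCN\tBAF\tCCF\n"
                        "s\t1\t1\t500\t2.5\t0.6\t90\n"
                        "s\t1\t400\t900\t2.0\t0.5\t100\n")
        with pytest.raises(ValueError, match="overlap"):
            load_seg(path)


class TestEmission:
    def test_single_deletion_truth_emits_one_qualifying_segment(self):
        p = sim.SyntheticPatient("p1", [sim.TruthEvent("Del 13q", 95.0, "loss")],
                                 None, "1q/13", False, "BO-1", 10, True, 20, False)
        seg = sim.emit_segments(p, rng=np.random.default_rng(3))
        altered = seg[seg.cn != 2.0]
        assert len(altered) == 1
        row = altered.iloc[0]
        arms = arm_table()
        q13 = arms[(arms.chromosome == 13) & (arms.arm == "q")].iloc[0]
        assert row.chromosome == 13 and row.cn <= 1.9
        assert (row.end - row.start) / (q13.end - q13.start) > 0.25
        assert row.ccf == 95.0

    def test_empty_truth_is_all_diploid(self):
        p = sim.SyntheticPatient("p1", [], None, "1q&13-", False, "BO-1",
                                 10, True, 20, False)
        seg = sim.emit_segments(p, rng=np.random.default_rng(3))
        assert (seg.cn == 2.0).all()
        # one segment per arm, spanning it
        assert len(seg) == len(arm_table())

    def test_unknown_variable_lists_catalogue(self):
        p = sim.SyntheticPatient("p1", [sim.TruthEvent("Del 23q", 95.0, "loss")],
                                 None, "1q/13", False, "BO-1", 10, True, 20, False)
        with pytest.raises(ValueError, match="catalogue"):
            sim.emit_segments(p, rng=np.random.default_rng(3))

    def test_roundtrip_recovers_major_truth_exactly(self, bo_patients,
                                                    bo_major_calls):
        """emit -> call -> filter reproduces every CCF>=50 truth event for
        all patients of the calibrated cohort (includes focal emissions)."""
        by_sample = bo_major_calls.groupby("sample_id")["variable"].apply(set)
        for p in bo_patients[:200]:
            got = set(by_sample.get(p.patient_id, set()))
            assert got == p.major_alterations(), p.patient_id
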