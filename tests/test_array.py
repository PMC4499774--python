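"""Peptide library construction, spot filtering, positivity and hotspots."""

import numpy as np
import pandas as pd
import pytest

import csos2kit as ck

from conftest import random_record


def make_hits(signals, positives, start_id=1, step=1):
    ids = [start_id + i * step for i in range(len(signals))]
    return pd.DataFrame(
        {
            "peptide_id": ids,
            "mean_signal": signals,
            "n_detectable": [4 if p else 0 for p in positives],
            "n_replicates": [4] * len(signals),
            "positive": positives,
        }
    )


class TestLibrary:
    def test_peptide_count_formula(self, rng):
        rec = random_record(rng, 792)
        lib = ck.build_library(rec, k=8, step=1)
        assert len(lib) == 785

    def test_peptide_id_is_start_coordinate(self, rng):
        rec = random_record(rng, 792)
        lib = ck.build_library(rec)
        pid, seq = lib.peptides[672]
        assert pid == 673
        assert seq == rec.sequence[672:680]

    def test_every_peptide_matches_substring_oracle(self, rng):
        rec = random_record(rng, 60)
        lib = ck.build_library(rec, k=8, step=1)
        for pid, seq in lib.peptides:
            assert seq == rec.sequence[pid - 1 : pid + 7]

    def test_k_exceeding_length_raises(self, rng):
        with pytest.raises(ValueError):
            ck.build_library(random_record(rng, 5), k=8)


class TestDetectability:
    def test_both_conditions_met(self):
        assert ck.call_detectable(131.0, 0.4 * 131.0, 100.0, 10.0)

    def test_below_three_sigma_fails_regardless_of_sd(self):
        assert not ck.call_detectable(129.0, 0.0, 100.0, 10.0)

    def test_ratio_exactly_half_fails(self):
        assert not ck.call_detectable(200.0, 100.0, 100.0, 10.0)

    def test_zero_signal_with_noise_fails_quietly(self):
        assert not ck.call_detectable(0.0, 5.0, -100.0, 10.0)


class TestPositivity:
    def _spots(self, signals, spot_sd=1.0):
        return pd.DataFrame(
            {
                "peptide_id": [1] * len(signals),
                "replicate": range(1, len(signals) + 1),
                "signal": signals,
                "spot_sd": [spot_sd] * len(signals),
            }
        )

    @pytest.mark.parametrize(
        "n_high,n_total,expected",
        [(3, 4, True), (2, 4, False), (5, 8, True), (1, 1, True), (0, 4, False)],
    )
    def test_strict_majority_rule(self, n_high, n_total, expected):
        signals = [200.0] * n_high + [100.0] * (n_total - n_high)
        row = ck.call_positive(self._spots(signals), background_mean=100.0,
                               background_sd=10.0)
        assert row["n_detectable"] == n_high
        assert bool(row["positive"]) is expected

    def test_mean_signal_averages_all_replicates(self):
        row = ck.call_positive(self._spots([200.0, 200.0, 200.0, 120.0]),
                               background_mean=100.0, background_sd=10.0)
        assert row["mean_signal"] == pytest.approx(np.mean([100, 100, 100, 20]))

    def test_raising_a_replicate_never_flips_positive_to_negative(self):
        base = [200.0, 200.0, 200.0, 120.0]
        before = ck.call_positive(self._spots(base), 100.0, 10.0)
        assert before["positive"]
        for i in range(4):
            bumped = list(base)
            bumped[i] += 500.0
            after = ck.call_positive(self._spots(bumped), 100.0, 10.0)
            assert after["positive"]
            assert after["n_detectable"] >= before["n_detectable"]

    def test_replicate_sd_fallback_when_spot_sd_missing(self):
        spots = self._spots([200.0, 201.0, 199.0, 200.0])
        spots["spot_sd"] = np.nan
        table = ck.SpotTable("a", spots, background_mean=100.0, background_sd=10.0)
        hits = ck.hit_table(table)  # falls back to replicate-level SD
        assert bool(hits.iloc[0]["positive"])

    def test_detectable_count_conserved_across_table(self, rng):
        parent = random_record(rng, 60)
        lib = ck.build_library(parent)
        table, _ = ck.simulate_array(
            lib, [ck.Hotspot(center=30, width=23, amplitude=100.0)], seed=3
        )
        hits = ck.hit_table(table)
        per_spot = sum(
            ck.call_detectable(row.signal, row.spot_sd, table.background_mean,
                               table.background_sd)
            for row in table.data.itertuples()
        )
        assert hits["n_detectable"].sum() == per_spot


class TestHotspots:
    def test_five_run_has_no_local_max_mark(self):
        # 15 strong singleton positives occupy the top-10 ranks; the weak
        # 5-run peak below them must not be marked (needs a run of >5)
        strong = make_hits([100.0 + i for i in range(15)],
                           [True] * 15, start_id=1, step=2)
        run = make_hits([10, 11, 14, 11, 10], [True] * 5, start_id=100)
        ann = ck.annotate_hotspots(pd.concat([strong, run], ignore_index=True))
        assert not (ann.marks["mark_reason"] == "local_max_run").any()
        assert set(ann.marks["peptide_id"]) <= set(strong["peptide_id"])

    def test_seven_run_unimodal_yields_single_peak_mark(self):
        strong = make_hits([100.0 + i for i in range(15)],
                           [True] * 15, start_id=1, step=2)
        run = make_hits([10, 12, 14, 16, 14, 12, 10], [True] * 7, start_id=100)
        ann = ck.annotate_hotspots(pd.concat([strong, run], ignore_index=True))
        local = ann.marks[ann.marks["mark_reason"] == "local_max_run"]
        assert list(local["peptide_id"]) == [103]

    def test_plateau_marked_at_leftmost_element(self):
        strong = make_hits([100.0 + i for i in range(15)],
                           [True] * 15, start_id=1, step=2)
        run = make_hits([10, 12, 16, 16, 12, 11, 10], [True] * 7, start_id=100)
        ann = ck.annotate_hotspots(pd.concat([strong, run], ignore_index=True))
        local = ann.marks[ann.marks["mark_reason"] == "local_max_run"]
        assert list(local["peptide_id"]) == [102]

    def test_top10_ties_break_toward_lower_id(self):
        hits = make_hits([50.0] * 12, [True] * 12)
        ann = ck.annotate_hotspots(hits)
        top = ann.marks[ann.marks["mark_reason"] == "top10"]
        assert list(top["peptide_id"]) == list(range(1, 11))

    def test_marked_subset_of_positive_and_argmax_saturation_100(self):
        hits = make_hits([5, 80, 40, 20, 10, 60], [False, True, True, True, True, True])
        ann = ck.annotate_hotspots(hits)
        assert 1 not in set(ann.marks["peptide_id"])
        assert ann.marks["saturation_pct"].max() == pytest.approx(100.0)
        argmax = ann.marks.loc[ann.marks["saturation_pct"].idxmax(), "peptide_id"]
        assert argmax == 2

    def test_no_positive_peptides_gives_empty_annotation(self):
        hits = make_hits([1.0, 2.0], [False, False])
        assert len(ck.annotate_hotspots(hits)) == 0

    def test_runs_broken_by_coordinate_gaps(self):
        # six positives but with a coordinate gap: two runs of 3, no marks
        strong = make_hits([100.0 + i for i in range(15)],
                           [True] * 15, start_id=1000)
        a = make_hits([10, 14, 10], [True] * 3, start_id=100)
        b = make_hits([10, 14, 10], [True] * 3, start_id=105)
        ann = ck.annotate_hotspots(pd.concat([strong, a, b], ignore_index=True))
        assert not (ann.marks["mark_reason"] == "local_max_run").any()


class TestAssayReport:
    def test_merged_rows_equal_sum_of_marks(self, rng):
        parent = random_record(rng, 120)
        lib = ck.build_library(parent)
        tables = [
            ck.simulate_array(lib, [ck.Hotspot(center=40, width=23, amplitude=80.0)],
                              assay_name=f"assay{i}", seed=100 + i)[0]
            for i in range(3)
        ]
        rep = ck.assay_report(lib, tables)
        assert len(rep.merged) == sum(len(a) for a in rep.annotations.values())

    def test_identical_tables_give_identical_annotations(self, rng):
        parent = random_record(rng, 100)
        lib = ck.build_library(parent)
        t1, _ = ck.simulate_array(lib, [ck.Hotspot(center=50, width=23, amplitude=80.0)],
                                  assay_name="a", seed=9)
        t2 = ck.SpotTable("b", t1.data.copy(), t1.background_mean, t1.background_sd)
        rep = ck.assay_report(lib, [t1, t2])
        pd.testing.assert_frame_equal(rep.annotations["a"].marks,
                                      rep.annotations["b"].marks)

    def test_shifted_hotspots_shift_the_peak_mark(self, rng):
        parent = random_record(rng, 200)
        lib = ck.build_library(parent)
        peaks = {}
        for name, center in (("x", 100), ("y", 102)):
            table, _ = ck.simulate_array(
                lib,
                [ck.Hotspot(center=center, width=23, amplitude=120.0,
                            profile="triangular")],
                assay_name=name, seed=55,
            )
            rep = ck.assay_report(lib, [table])
            marks = rep.annotations[name].marks
            peaks[name] = int(marks.loc[marks["saturation_pct"].idxmax(), "peptide_id"])
        assert abs((peaks["y"] - peaks["x"]) - 2) <= 1

    def test_mismatched_library_raises(self, rng):
        parent = random_record(rng, 60)
        other = random_record(rng, 200, "other")
        lib_small = ck.build_library(parent)
        lib_big = ck.build_library(other)
        table, _ = ck.simulate_array(lib_big, [], seed=1)
        with pytest.raises(ValueError, match="not in the library"):
            ck.assay_report(lib_small, [table])
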