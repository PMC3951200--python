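import itertools

import numpy as np
import pandas as pd
import pytest

from divquail.divergence import (
    classify_outliers,
    composite_table,
    percentile_bounds,
)
from divquail.io_align import select_top_hits
from divquail.qc import (
    correlation_matrix,
    merge_nonoverlapping_hsps,
    recheck_conserved_outliers,
    size_percentile_control,
    trace_fp_filter,
)
from divquail.synth import make_alignment_table, make_hsp_set, SyntheticAlignmentSpec


def kendall_tau_b_oracle(x, y):
    """O(n^2) concordant/discordant pair counting with tie correction."""
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i, j in itertools.combinations(range(n), 2):
        dx = np.sign(x[i] - x[j])
        dy = np.sign(y[i] - y[j])
        if dx == 0 and dy == 0:
            ties_x += 1
            ties_y += 1
        elif dx == 0:
            ties_x += 1
        elif dy == 0:
            ties_y += 1
        elif dx == dy:
            concordant += 1
        else:
            discordant += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - ties_x) * (n0 - ties_y))
    return (concordant - discordant) / denom


class TestMergeNonoverlapping:
    def test_greedy_drops_overlapping_lower_score(self):
        hsps = make_hsp_set(
            [(1, 100, 100.0, 200.0), (50, 150, 90.0, 150.0), (200, 300, 90.0, 100.0)],
            "c1",
        )
        merged = merge_nonoverlapping_hsps(hsps)
        assert merged.members["q_start"].tolist() == [1, 200]
        assert merged.total_alignment_length == 100 + 101

    def test_single_short_perfect_hit(self):
        merged = merge_nonoverlapping_hsps(make_hsp_set([(1, 19, 100.0, 38.0)], "c1"))
        assert merged.total_alignment_length == 19
        assert merged.recomputed_composite == pytest.approx(0.052631579, abs=5e-10)

    def test_weighted_identity_arithmetic(self):
        hsps = make_hsp_set([(1, 100, 100.0, 200.0), (200, 300, 90.0, 100.0)], "c1")
        merged = merge_nonoverlapping_hsps(hsps)
        expected_identity = (100.0 * 100 + 90.0 * 101) / 201
        assert merged.weighted_identity == pytest.approx(expected_identity, abs=1e-9)
        assert merged.recomputed_composite == pytest.approx(
            (expected_identity / 100.0) / 201, abs=1e-9
        )
        assert merged.recomputed_composite == pytest.approx(0.0047251, abs=5e-7)

    def test_members_pairwise_disjoint_and_shuffle_invariant(self, rng):
        for _ in range(10):
            starts = rng.integers(1, 2000, 15)
            layout = [
                (int(s), int(s + rng.integers(10, 400)), 90.0,
                 float(rng.choice([50.0, 100.0, 100.0, 200.0])))
                for s in starts
            ]
            hsps = make_hsp_set(layout, "c1")
            merged = merge_nonoverlapping_hsps(hsps)
            spans = sorted(
                zip(merged.members["q_start"] - 1, merged.members["q_end"])
            )
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2
            shuffled = hsps.sample(frac=1.0, random_state=1).reset_index(drop=True)
            again = merge_nonoverlapping_hsps(shuffled)
            assert sorted(again.members["q_start"]) == sorted(
                merged.members["q_start"]
            )
            assert again.recomputed_composite == merged.recomputed_composite
            lo = merged.members["percent_identity"].min()
            hi = merged.members["percent_identity"].max()
            assert lo <= merged.weighted_identity <= hi

    def test_empty_and_mixed_contig_errors(self):
        with pytest.raises(ValueError):
            merge_nonoverlapping_hsps(make_hsp_set([], "c1"))
        mixed = pd.concat(
            [
                make_hsp_set([(1, 50, 90.0, 50.0)], "c1"),
                make_hsp_set([(1, 50, 90.0, 50.0)], "c2"),
            ]
        )
        with pytest.raises(ValueError, match="single contig"):
            merge_nonoverlapping_hsps(mixed)


class TestRecheckConserved:
    def _bounds(self, lower_value):
        # bounds whose lower cutoff we control, via a three-point sample
        return percentile_bounds(
            [lower_value * 0.5, lower_value * 2, lower_value * 4], 50, 99
        )

    def test_single_hsp_recomputation_equals_original(self):
        hsps = make_hsp_set([(1, 20_000, 98.0, 30_000.0)], "c1")
        records = composite_table(select_top_hits(hsps))
        bounds = percentile_bounds([records.loc[0, "composite"], 1e-3, 1e-2], 60, 99)
        calls = classify_outliers(records, bounds)
        report = recheck_conserved_outliers(calls, hsps, bounds)
        assert len(report) == 1
        assert report.loc[0, "recomputed_composite"] == pytest.approx(
            report.loc[0, "original_composite"], rel=1e-12
        )
        assert bool(report.loc[0, "still_outlier"])

    def test_appended_comparable_identity_only_confirms(self, rng):
        # appending non-overlapping alignment at similar identity can only
        # lengthen the alignment and hence shrink the composite
        for trial in range(20):
            top_len = int(rng.integers(10_000, 40_000))
            top_id = float(rng.uniform(92, 100))
            layout = [(1, top_len, top_id, float(top_len))]
            cursor = top_len + int(rng.integers(100, 500))
            for _ in range(int(rng.integers(1, 5))):
                seg = int(rng.integers(500, 5000))
                seg_id = float(np.clip(top_id + rng.uniform(-5, 5), 60, 100))
                layout.append((cursor, cursor + seg - 1, seg_id, float(seg)))
                cursor += seg + int(rng.integers(100, 500))
            hsps = make_hsp_set(layout, "c1")
            merged = merge_nonoverlapping_hsps(hsps)
            original = (top_id / 100.0) / top_len
            assert merged.recomputed_composite <= original

    def test_contig_without_hsps_flagged(self):
        calls = pd.DataFrame(
            [{"contig_id": "ghost", "tail": "conserved", "composite": 1e-5,
              "fp_flag": False}]
        )
        hsps = make_hsp_set([(1, 50, 90.0, 50.0)], "other")
        report = recheck_conserved_outliers(calls, hsps, self._bounds(1e-4))
        assert bool(report.loc[0, "flagged"])
        assert np.isnan(report.loc[0, "recomputed_composite"])

    def test_empty_conserved_set(self):
        calls = pd.DataFrame(columns=["contig_id", "tail", "composite", "fp_flag"])
        hsps = make_hsp_set([(1, 50, 90.0, 50.0)], "c1")
        assert recheck_conserved_outliers(calls, hsps, self._bounds(1e-4)).empty


class TestTraceFpFilter:
    @pytest.mark.parametrize(
        "original, alternatives, expected",
        [
            (100.0, [115.0], True),    # boundary inclusive: >= 15% larger
            (100.0, [114.9], False),
            (100.0, [], False),        # nothing to compare against
            (100.0, [50.0, 120.0], True),
            (200.0, [229.0, 100.0], False),
        ],
    )
    def test_decision_rule(self, original, alternatives, expected):
        assert trace_fp_filter(original, alternatives).is_false_positive is expected

    def test_boundary_property_over_magnitudes(self):
        for b in (0.5, 1.0, 37.0, 1e4):
            assert trace_fp_filter(b, [1.15 * b]).is_false_positive
            assert not trace_fp_filter(b, [1.15 * b - 1e-6 * b]).is_false_positive

    def test_nonpositive_original_rejected(self):
        with pytest.raises(ValueError):
            trace_fp_filter(0.0, [10.0])


class TestCorrelationMatrix:
    def _tables(self, length, gc, pid, al):
        n = len(length)
        ids = [f"c{i}" for i in range(n)]
        meta = pd.DataFrame({"contig_id": ids, "length": length, "gc_fraction": gc})
        comp = pd.DataFrame(
            {
                "contig_id": ids,
                "percent_identity": pid,
                "alignment_length": al,
                "composite": np.asarray(pid) / 100.0 / np.asarray(al),
            }
        )
        return meta, comp

    def test_perfectly_linear_pair(self):
        x = np.arange(1.0, 11.0)
        meta, comp = self._tables(x, 0.3 + x / 100, 60 + x, 2 * x + 1)
        m = correlation_matrix(meta, comp)
        assert m.pearson.loc["contig_length", "alignment_length"] == pytest.approx(1.0)
        assert m.kendall.loc["contig_length", "alignment_length"] == pytest.approx(1.0)
        assert (np.diag(m.pearson) == 1.0).all()

    def test_strictly_decreasing_pair(self):
        x = np.arange(1.0, 11.0)
        meta, comp = self._tables(x, 0.3 + x / 100, 100 - x, 2 * x)
        m = correlation_matrix(meta, comp)
        assert m.pearson.loc["contig_length", "percent_identity"] == pytest.approx(-1.0)
        assert m.kendall.loc["contig_length", "percent_identity"] == pytest.approx(-1.0)

    def test_hand_counted_tau(self):
        # pairs: 8 concordant, 2 discordant -> tau = 6/10
        meta, comp = self._tables(
            [1, 2, 3, 4, 5], [0.31, 0.36, 0.33, 0.39, 0.37], [61, 63, 62, 65, 64],
            [10, 30, 20, 50, 40],
        )
        m = correlation_matrix(meta, comp)
        assert m.kendall.loc["contig_length", "alignment_length"] == pytest.approx(0.6)

    def test_tau_matches_pair_counting_oracle(self, rng):
        for n in (4, 10, 25, 50):
            x = rng.integers(0, 10, n).astype(float)
            y = rng.integers(0, 10, n).astype(float)
            if len(set(x)) == 1 or len(set(y)) == 1:
                continue
            meta, comp = self._tables(
                x, rng.uniform(0.3, 0.6, n), 60 + y, rng.integers(30, 100, n)
            )
            m = correlation_matrix(meta, comp)
            assert m.kendall.loc["contig_length", "percent_identity"] == pytest.approx(
                kendall_tau_b_oracle(x, y), abs=1e-12
            )

    def test_constant_column_reported_missing(self):
        meta, comp = self._tables(
            [5, 5, 5, 5], [0.31, 0.35, 0.40, 0.44], [61, 70, 80, 90], [10, 20, 30, 40]
        )
        with pytest.warns(UserWarning, match="constant"):
            m = correlation_matrix(meta, comp)
        assert np.isnan(m.pearson.loc["contig_length", "gc_fraction"])
        assert m.pearson.loc["contig_length", "contig_length"] == 1.0

    def test_too_few_rows(self):
        meta, comp = self._tables([1, 2], [0.3, 0.4], [61, 62], [10, 20])
        with pytest.raises(ValueError):
            correlation_matrix(meta, comp)


class TestSizePercentileControl:
    def _meta(self, lengths):
        return pd.DataFrame(
            {
                "contig_id": [f"c{i}" for i in range(len(lengths))],
                "length": lengths,
                "gc_fraction": 0.4,
            }
        )

    def _calls(self, ids):
        return pd.DataFrame(
            {"contig_id": ids, "tail": "diverged", "composite": 0.05,
             "fp_flag": False}
        )

    def test_disjoint_sets_overlap_zero(self):
        lengths = list(range(1000, 1100))
        meta = self._meta(lengths)
        calls = self._calls(["c50", "c51"])  # mid-size contigs
        result = size_percentile_control(meta, calls, 1.0, 99.0)
        assert result.overlap_count == 0
        assert result.overlap_ids == frozenset()

    def test_calls_subset_of_size_outliers(self):
        lengths = list(range(1000, 1100))
        meta = self._meta(lengths)
        calls = self._calls(["c0", "c99"])  # the extreme sizes
        result = size_percentile_control(meta, calls, 1.0, 99.0)
        assert result.overlap_count == len(calls)
        assert result.overlap_ids == frozenset(calls["contig_id"])

    def test_matches_brute_force_set_intersection(self, rng):
        for _ in range(10):
            lengths = rng.integers(300, 100_000, 200)
            meta = self._meta(lengths)
            called = rng.choice(meta["contig_id"], 10, replace=False)
            calls = self._calls(list(called))
            lo, hi = 2.0, 98.0
            result = size_percentile_control(meta, calls, lo, hi)
            lo_v = np.percentile(lengths, lo)
            hi_v = np.percentile(lengths, hi)
            expected = {
                cid
                for cid, ln in zip(meta["contig_id"], lengths)
                if ln <= lo_v or ln >= hi_v
            }
            assert result.size_outlier_ids == frozenset(expected)
            assert result.overlap_ids == frozenset(expected) & set(called)


class TestEndToEndQc:
    def test_synthetic_conserved_outliers_all_confirmed(self):
        spec = SyntheticAlignmentSpec(9998, 0, 2, seed=13)
        hits, meta, truth = make_alignment_table(spec)
        records = composite_table(select_top_hits(hits))
        bounds = percentile_bounds(records["composite"])
        calls = classify_outliers(records, bounds)
        report = recheck_conserved_outliers(calls, hits, bounds)
        conserved_planted = report[
            report["contig_id"].isin(truth.planted_conserved_ids)
        ]
        assert len(conserved_planted) == 2
        assert conserved_planted["still_outlier"].all()
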