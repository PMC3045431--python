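"""Error thresholds, dual-strand calling, QC score and allele-count estimation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolscreen.caller import (
    call_variants,
    error_thresholds,
    estimate_allele_count,
    fr_ratio_score,
    frequency_table,
    min_detectable_count,
    run_calling,
    substitution_frequencies,
)
from poolscreen.pileup import Amplicon, PileupColumn
from poolscreen.simulate import PoolDesign, Variant, simulate_columns


def _col(ref="G", fwd=None, rev=None, pos=10):
    zero = {"A": 0, "C": 0, "G": 0, "T": 0}
    return PileupColumn("chr1", pos, ref, {**zero, **(fwd or {})}, {**zero, **(rev or {})})


def _freq_frame(f_fwd, f_rev, ref="G", alt="A", depth=1000, pos=10):
    n_fwd, n_rev = round(f_fwd * depth), round(f_rev * depth)
    return pd.DataFrame(
        [
            {
                "chrom": "chr1", "pos": pos, "ref": ref, "alt": alt,
                "n_fwd": n_fwd, "n_rev": n_rev,
                "depth_fwd": depth, "depth_rev": depth,
                "f_fwd": n_fwd / depth, "f_rev": n_rev / depth,
                "f_combined": (n_fwd + n_rev) / (2 * depth),
                "depth_total": 2 * depth,
            }
        ]
    )


class TestSubstitutionFrequencies:
    def test_single_strand_alt_arithmetic(self):
        col = _col(fwd={"G": 99, "A": 1}, rev={"G": 100})
        recs = {r.alt: r for r in substitution_frequencies(col)}
        assert recs["A"].f_fwd == pytest.approx(0.01)
        assert recs["A"].f_rev == 0.0
        assert recs["A"].f_combined == pytest.approx(0.005)
        assert recs["A"].depth_total == 200

    def test_zero_frequency_records_retained(self):
        recs = substitution_frequencies(_col(fwd={"G": 50}, rev={"G": 50}))
        assert sorted(r.alt for r in recs) == ["A", "C", "T"]
        assert all(r.f_combined == 0 for r in recs)

    def test_n_reference_and_empty_strand_skipped(self):
        assert substitution_frequencies(_col(ref="N", fwd={"A": 5}, rev={"A": 5})) == []
        assert substitution_frequencies(_col(fwd={"G": 5})) == []

    def test_combined_frequency_bracketed_by_strands(self):
        col = _col(fwd={"G": 90, "A": 10}, rev={"G": 99, "A": 1})
        rec = next(r for r in substitution_frequencies(col) if r.alt == "A")
        assert min(rec.f_fwd, rec.f_rev) <= rec.f_combined <= max(rec.f_fwd, rec.f_rev)

    def test_reported_depth_and_frequency_imply_read_count(self):
        # a pool record printed as frequency 0.012 at depth 33904 corresponds
        # to ~407 supporting reads; check the arithmetic is invertible
        assert round(0.012 * 33904) == 407
        col = _col(ref="A", fwd={"A": 16749, "T": 203}, rev={"A": 16748, "T": 204})
        rec = next(r for r in substitution_frequencies(col) if r.alt == "T")
        assert rec.depth_total == 33904
        assert rec.f_combined == pytest.approx(0.012, abs=5e-5)


def _quantile_oracle(values, q):
    """Independent linear-interpolation quantile (sorted order statistics)."""
    xs = sorted(values)
    h = (len(xs) - 1) * q
    lo = math.floor(h)
    if lo + 1 >= len(xs):
        return xs[-1]
    return xs[lo] + (h - lo) * (xs[lo + 1] - xs[lo])


def _error_frame(values_by_type):
    """Build a frequency table exposing given per-strand frequency values."""
    rows = []
    pos = 1
    for (ref, alt), values in values_by_type.items():
        for v in values:
            rows.append(
                {
                    "chrom": "chr1", "pos": pos, "ref": ref, "alt": alt,
                    "n_fwd": 0, "n_rev": 0, "depth_fwd": 100, "depth_rev": 100,
                    "f_fwd": v, "f_rev": v, "f_combined": v, "depth_total": 200,
                }
            )
            pos += 1
    return pd.DataFrame(rows)


def _all_types(values):
    return {(r, a): values for r in "ACGT" for a in "ACGT" if r != a}


class TestErrorThresholds:
    def test_constant_distribution_threshold_is_the_constant(self):
        thr = error_thresholds(_error_frame(_all_types([0.003] * 50)))
        assert thr.threshold_fwd("G", "A") == pytest.approx(0.003)
        assert thr.unreliable == frozenset()

    def test_linear_interpolation_matches_independent_oracle(self):
        grid = [i / 1000 for i in range(0, 11)]  # 0, 0.001, ..., 0.01
        thr = error_thresholds(_error_frame(_all_types(grid)), q=0.975)
        # both strands contribute: each grid value appears twice
        expected = _quantile_oracle(grid + grid, 0.975)
        assert thr.threshold_fwd("A", "C") == pytest.approx(expected)

    def test_nearest_rank_matches_independent_oracle(self):
        grid = [i / 1000 for i in range(0, 11)]
        thr = error_thresholds(
            _error_frame(_all_types(grid)), q=0.975, method="nearest-rank"
        )
        xs = sorted(grid + grid)
        expected = xs[math.ceil(0.975 * len(xs)) - 1]
        assert thr.threshold_fwd("A", "C") == expected

    def test_sparse_types_flagged_unreliable(self):
        values = _all_types([0.001] * 50)
        values[("G", "A")] = [0.001] * 10  # 20 obs after strand pooling, < 40
        thr = error_thresholds(_error_frame(values))
        assert ("G", "A") in thr.unreliable
        assert ("A", "C") not in thr.unreliable

    def test_missing_type_is_an_error(self):
        values = _all_types([0.001] * 50)
        del values[("T", "G")]
        with pytest.raises(ValueError, match="T>G"):
            error_thresholds(_error_frame(values))

    def test_per_strand_mode_separates_strands(self):
        df = _error_frame(_all_types([0.001] * 50))
        df.loc[(df.ref == "G") & (df.alt == "A"), "f_fwd"] = 0.02
        thr = error_thresholds(df, mode="per-strand")
        assert thr.threshold_fwd("G", "A") == pytest.approx(0.02)
        assert thr.threshold_rev("G", "A") == pytest.approx(0.001)

    def test_noisier_substitution_type_gets_higher_threshold(self, error_only_design):
        # simulation oracle: with lambda(A>C) = 10 x lambda(G>A), the A>C
        # cutoff must come out above the G>A cutoff
        import dataclasses

        wins = 0
        for seed in range(20):
            design = dataclasses.replace(error_only_design, seed=3000 + seed)
            cols, _ = simulate_columns(design)
            thr = error_thresholds(frequency_table(cols))
            wins += thr.threshold_fwd("A", "C") > thr.threshold_fwd("G", "A")
        assert wins == 20


class TestCalling:
    def test_clear_dual_strand_signal_called(self):
        thr = error_thresholds(_error_frame(_all_types([0.01] * 50)))
        calls = call_variants(_freq_frame(0.02, 0.02), thr, n_individuals=311)
        assert bool(calls["called"].iloc[0])

    def test_one_strand_artifact_rejected(self):
        # high frequency on a single strand is the signature the dual-strand
        # rule exists to kill, however extreme the one-sided signal
        thr = error_thresholds(_error_frame(_all_types([0.01] * 50)))
        calls = call_variants(_freq_frame(0.05, 0.0), thr, n_individuals=311)
        assert not bool(calls["called"].iloc[0])
        assert calls["fr_score"].iloc[0] == pytest.approx(2.0)

    def test_exactly_at_threshold_not_called(self):
        thr = error_thresholds(_error_frame(_all_types([0.01] * 50)))
        calls = call_variants(_freq_frame(0.01, 0.01), thr, n_individuals=311)
        assert not bool(calls["called"].iloc[0])

    def test_shallow_positions_not_callable(self):
        thr = error_thresholds(_error_frame(_all_types([0.001] * 50)))
        calls = call_variants(
            _freq_frame(0.1, 0.1, depth=40), thr, n_individuals=311,
            min_depth_per_strand=50,
        )
        assert not bool(calls["called"].iloc[0])
        calls = call_variants(
            _freq_frame(0.1, 0.1, depth=40), thr, n_individuals=311,
            min_depth_per_strand=30,
        )
        assert bool(calls["called"].iloc[0])

    def test_two_pass_threshold_excludes_called_positions(self):
        design = PoolDesign(
            n_individuals=311,
            amplicons=[Amplicon("chr1", 100, 700, 0, 0)],
            mean_depth_per_strand=5000.0,
            variants=[Variant(300, "G", "A", 40)],
            seed=11,
        )
        cols, _ = simulate_columns(design)
        thr1, calls1 = run_calling(cols, n_individuals=311)
        thr2, calls2 = run_calling(cols, n_individuals=311, two_pass=True)
        # removing the variant from the error histogram can only lower the cutoff
        assert thr2.threshold_fwd("G", "A") <= thr1.threshold_fwd("G", "A")
        assert set(calls1.loc[calls1.called, "pos"]) <= set(calls2.loc[calls2.called, "pos"])


class TestStrandBalanceScore:
    @pytest.mark.parametrize(
        "f_fwd, f_rev, expected",
        [(0.01, 0.01, 0.0), (0.02, 0.0, 2.0), (0.03, 0.01, 1.0)],
    )
    def test_known_scores(self, f_fwd, f_rev, expected):
        assert fr_ratio_score(f_fwd, f_rev) == pytest.approx(expected)

    def test_no_signal_gives_nan(self):
        assert math.isnan(fr_ratio_score(0.0, 0.0))

    @settings(derandomize=True, max_examples=200)
    @given(
        st.floats(0, 1, allow_nan=False),
        st.floats(0, 1, allow_nan=False),
    )
    def test_score_bounded_and_symmetric(self, f, r):
        if f + r == 0:
            return
        s = fr_ratio_score(f, r)
        assert 0.0 <= s <= 2.0
        assert s == pytest.approx(fr_ratio_score(r, f))


class TestAlleleCounts:
    @pytest.mark.parametrize(
        "freq, n, expected",
        [(0.012, 311, 7), (0.0, 311, 0), (1.0, 311, 622), (1.5 / 622, 311, 2)],
    )
    def test_estimate_rounds_half_away_from_zero(self, freq, n, expected):
        assert estimate_allele_count(freq, n) == expected

    def test_estimate_round_trips_exact_pool_frequencies(self):
        for n in (1, 2, 3, 10, 311, 360, 1000):
            k = np.arange(0, 2 * n + 1)
            est = np.floor(k / (2 * n) * 2 * n + 0.5).astype(int)
            assert (est == k).all()
            # spot-check through the scalar API
            for kk in (0, 1, n, 2 * n):
                assert estimate_allele_count(kk / (2 * n), n) == kk

    @pytest.mark.parametrize("threshold, expected", [(0.004, 3), (0.010, 7), (0.0, 1)])
    def test_min_detectable_count_examples(self, threshold, expected):
        # exhaustive oracle: smallest k in 1..20 with k/622 > t
        oracle = next(k for k in range(1, 21) if k / 622 > threshold)
        assert oracle == expected
        assert min_detectable_count(threshold, 311) == expected

    def test_min_detectable_strict_at_exact_boundary(self):
        # k/(2N) must strictly exceed the cutoff, so t = 3/622 cannot be
        # cleared by k=3 itself
        assert min_detectable_count(3 / 622, 311) == 4

    def test_detectability_consistent_with_estimation(self):
        n = 311
        for t in (0.001, 0.004, 0.01, 0.02):
            k_min = min_detectable_count(t, n)
            assert k_min / (2 * n) > t
            assert (k_min - 1) / (2 * n) <= t
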