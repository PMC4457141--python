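import io
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from chronophase import timeseries_xcorr as tx

from conftest import TIMEPOINTS, make_expression_matrix


def brute_force_lagged_pearson(e, l):
    """Oracle: explicit Pearson over every circular rotation of l."""
    return np.array([np.corrcoef(e, np.roll(l, -j))[0, 1] for j in range(len(e))])


def fpkm_tsv(values_by_transcript):
    cols = ["transcript_id"] + [
        f"{c}_ZT{int(zt):02d}_rep{r}" for c in ("E", "L") for zt in TIMEPOINTS for r in (1, 2)
    ]
    lines = ["\t".join(cols)]
    for tid, vals in values_by_transcript.items():
        lines.append("\t".join([tid] + [f"{v:g}" for v in vals]))
    return io.StringIO("\n".join(lines) + "\n")


class TestLoadFpkmTable:
    def test_roundtrip_through_writer(self):
        rng = np.random.default_rng(0)
        m = make_expression_matrix(
            {f"T{i}": rng.random(24) * 10 for i in range(2)}
        )
        buf = io.StringIO()
        tx.write_fpkm_table(m, buf)
        buf.seek(0)
        back = tx.load_fpkm_table(buf)
        assert back.data.shape == (2, 24)
        np.testing.assert_allclose(back.data.to_numpy(), m.data.to_numpy(), rtol=1e-6)

    def test_duplicated_transcript_id_rejected(self):
        buf = fpkm_tsv({"A": np.ones(24)})
        text = buf.getvalue()
        dup = text + text.splitlines()[1] + "\n"
        with pytest.raises(ValueError, match="duplicated"):
            tx.load_fpkm_table(io.StringIO(dup))

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="no transcripts"):
            tx.load_fpkm_table(fpkm_tsv({}))

    def test_negative_fpkm_rejected(self):
        vals = np.ones(24)
        vals[3] = -1
        with pytest.raises(ValueError, match="negative"):
            tx.load_fpkm_table(fpkm_tsv({"A": vals}))

    def test_missing_cell_rejected(self):
        buf = fpkm_tsv({"A": np.ones(24)})
        lines = buf.getvalue().splitlines()
        lines[1] = "\t".join(lines[1].split("\t")[:-1])  # ragged row
        with pytest.raises((ValueError, pd.errors.ParserError)):
            tx.load_fpkm_table(io.StringIO("\n".join(lines)))


class TestAverageReplicates:
    def test_mean_of_two_replicates(self):
        flat = np.concatenate([np.tile([2.0, 4.0], 6), np.tile([0.0, 0.0], 6)])
        m = make_expression_matrix({"A": flat})
        avg = tx.average_replicates(m)
        assert avg.loc["A", ("E", 0.0)] == pytest.approx(3.0)
        assert avg.loc["A", ("L", 0.0)] == pytest.approx(0.0)


class TestZscoreRows:
    def test_three_point_example(self):
        z, const = tx.zscore_rows(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(z[0], [-1.22474487, 0.0, 1.22474487], atol=1e-8)
        assert not const[0]

    def test_constant_row_flagged_not_raised(self):
        z, const = tx.zscore_rows(np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]))
        assert const.tolist() == [True, False]
        assert np.isnan(z[0]).all()

    def test_idempotent_on_standardized_rows(self):
        row = np.array([[1.0, 2.0, 3.0, 7.0]])
        z1, _ = tx.zscore_rows(row)
        z2, _ = tx.zscore_rows(z1)
        np.testing.assert_allclose(z2, z1, atol=1e-12)

    @given(
        st.lists(
            st.lists(st.floats(-100, 100), min_size=4, max_size=12),
            min_size=1,
            max_size=5,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    def test_rows_have_zero_mean_unit_variance(self, rows):
        z, const = tx.zscore_rows(np.array(rows, dtype=float))
        for zr, is_const in zip(z, const):
            if not is_const:
                assert abs(zr.mean()) < 1e-9
                assert abs(zr.var() - 1.0) < 1e-9


class TestHierarchicalCluster:
    def test_identical_rows_merge_first(self):
        mat = np.array([[1.0, 2.0, 3.0], [9.0, 1.0, 4.0], [1.0, 2.0, 3.0]])
        Z, _ = tx.hierarchical_cluster_rows(mat, "euclidean", "average")
        assert sorted(Z[0, :2].astype(int).tolist()) == [0, 2]
        assert Z[0, 2] == pytest.approx(0.0)

    def test_merge_order_matches_brute_force_average_linkage(self):
        rng = np.random.default_rng(3)
        mat = rng.random((5, 6))
        Z, _ = tx.hierarchical_cluster_rows(mat, "euclidean", "average")

        # brute-force agglomeration over explicit pairwise averages
        clusters = {i: [i] for i in range(5)}
        dist = {
            (i, j): np.linalg.norm(mat[i] - mat[j])
            for i in range(5)
            for j in range(i + 1, 5)
        }
        merge_heights = []
        next_id = 5
        while len(clusters) > 1:
            keys = sorted(clusters)
            best = min(
                ((a, b) for a in keys for b in keys if a < b),
                key=lambda ab: np.mean(
                    [dist[tuple(sorted((i, j)))] for i in clusters[ab[0]] for j in clusters[ab[1]]]
                ),
            )
            h = np.mean(
                [dist[tuple(sorted((i, j)))] for i in clusters[best[0]] for j in clusters[best[1]]]
            )
            merge_heights.append(h)
            clusters[next_id] = clusters.pop(best[0]) + clusters.pop(best[1])
            next_id += 1
        np.testing.assert_allclose(Z[:, 2], merge_heights, rtol=1e-9)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            tx.hierarchical_cluster_rows(np.array([[1.0, 2.0]]))

    def test_constant_row_rejected_under_correlation(self):
        mat = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="constant"):
            tx.hierarchical_cluster_rows(mat, "correlation", "average")


class TestLaggedXcorr:
    def test_identical_series_peak_at_lag_zero(self):
        e = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 0.0])
        r = tx.lagged_xcorr(e, e)
        assert r[0] == pytest.approx(1.0)
        assert tx.max_xcorr(e, e) == (pytest.approx(1.0), 0.0)

    def test_circular_shift_moves_peak(self):
        e = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 0.0])
        l = np.roll(e, 1)
        r_max, lag = tx.max_xcorr(e, l)
        assert r_max == pytest.approx(1.0)
        assert lag == pytest.approx(4.0)

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            e, l = rng.random(6), rng.random(6)
            np.testing.assert_allclose(
                tx.lagged_xcorr(e, l), brute_force_lagged_pearson(e, l), atol=1e-12
            )

    def test_constant_series_degenerate(self):
        with pytest.raises(tx.DegenerateSeriesError):
            tx.lagged_xcorr(np.ones(6), np.arange(6.0))

    def test_antiphase_argmax_found_by_enumeration(self):
        e = np.array([0.0, 1.0, 1.0, 0.0, -1.0, -1.0])
        l = -e
        r = tx.lagged_xcorr(e, l)
        r_max, lag = tx.max_xcorr(e, l)
        assert r_max == pytest.approx(r.max())
        assert lag == pytest.approx(-12.0)  # 3-step shift canonicalized

    def test_tie_breaks_prefer_small_then_negative_lag(self):
        # constant r across lags: tie resolved to lag 0
        r = np.full(6, 0.5)
        assert tx._pick_best_lag(r, 4.0) == (0.5, 0.0)
        r2 = np.array([0.1, 0.9, 0.2, 0.2, 0.2, 0.9])  # +4 vs -4: negative wins
        assert tx._pick_best_lag(r2, 4.0)[1] == -4.0


class TestFpkmVariance:
    def test_constant_transcript_zero_variance(self):
        assert tx.fpkm_variance(np.full(6, 3.0), np.full(6, 3.0)) == 0.0

    def test_two_level_hand_example(self):
        assert tx.fpkm_variance(np.zeros(6), np.full(6, 2.0)) == pytest.approx(1.0)

    def test_quadratic_scaling(self):
        rng = np.random.default_rng(5)
        e, l = rng.random(6), rng.random(6)
        v = tx.fpkm_variance(e, l)
        assert tx.fpkm_variance(3 * e, 3 * l) == pytest.approx(9 * v)


class TestFdrThreshold:
    def test_hand_worked_example(self):
        # at c=0.8 the plug-in FDR is (1/4) * 3/2 = 0.375 > 0.05; at 0.9 it is 0
        for method in ("null_quantile", "plugin"):
            thr = tx.fdr_threshold(
                [0.9, 0.8, 0.2], [0.85, 0.3, 0.2, 0.1], alpha=0.05, method=method
            )
            assert thr.threshold_score == pytest.approx(0.9)

    def test_null_below_all_observed_gives_smallest_observed(self):
        thr = tx.fdr_threshold([0.5, 0.7, 0.9], [0.1, 0.2], alpha=0.05)
        assert thr.threshold_score == pytest.approx(0.5)

    def test_no_qualifying_score_gives_infinity(self):
        thr = tx.fdr_threshold([0.1, 0.2], [0.5, 0.6, 0.9, 0.95], alpha=0.05)
        assert math.isinf(thr.threshold_score)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tx.fdr_threshold([0.5], [0.5], alpha=1.5)

    def test_matched_distributions_admit_about_alpha(self):
        rng = np.random.default_rng(11)
        observed = rng.random(4000)
        null = rng.random(40000)
        thr = tx.fdr_threshold(observed, null, alpha=0.05)
        frac = (observed >= thr.threshold_score).mean()
        assert 0.03 < frac < 0.07

    def test_lowering_alpha_never_grows_significant_set(self):
        rng = np.random.default_rng(13)
        observed = rng.random(500)
        null = rng.random(5000)
        prev = None
        for alpha in (0.2, 0.1, 0.05, 0.01):
            thr = tx.fdr_threshold(observed, null, alpha=alpha).threshold_score
            n_sig = int((observed >= thr).sum())
            if prev is not None:
                assert n_sig <= prev
            prev = n_sig


class TestScreenAndClassify:
    def test_labels_follow_threshold_and_variance_floor(self):
        thr = tx.FdrThreshold(0.05, 0.8, 10, 100, 1, 0)
        results = [
            tx.XCorrResult("hi", np.ones(6), 1.0, 0.0, 50.0),
            tx.XCorrResult("lo", np.ones(6), 0.3, 4.0, 50.0),
            tx.XCorrResult("flat", np.ones(6), 1.0, 0.0, 0.0),
        ]
        labels = tx.classify_transcripts(results, thr, variance_floor=1.0)
        assert labels == {
            "hi": "phase_concordant",
            "lo": "divergent",
            "flat": "low_variance",
        }

    def test_permutation_null_deterministic_given_seed(self):
        rng = np.random.default_rng(21)
        m = make_expression_matrix({f"T{i}": rng.random(24) * 5 for i in range(20)})
        n1 = tx.permutation_null(m, n_perm=5, seed=3)
        n2 = tx.permutation_null(m, n_perm=5, seed=3)
        np.testing.assert_array_equal(n1.scores, n2.scores)
        n3 = tx.permutation_null(m, n_perm=5, seed=4)
        assert not np.array_equal(n1.scores, n3.scores)

    def test_degenerate_transcripts_contribute_no_null_scores(self):
        rng = np.random.default_rng(22)
        m = make_expression_matrix(
            {"const": np.full(24, 2.0), "var": rng.random(24)}
        )
        null = tx.permutation_null(m, n_perm=4, seed=0)
        assert null.scores.size == 4  # only the non-constant transcript

    def test_screen_flags_degenerate_and_reports_frame(self):
        rng = np.random.default_rng(23)
        m = make_expression_matrix(
            {"const": np.full(24, 2.0), **{f"T{i}": rng.random(24) for i in range(10)}}
        )
        screen = tx.run_xcorr_screen(m, n_perm=5, seed=1)
        frame = screen.to_frame()
        assert frame.loc["const", "note"] == "degenerate"
        assert screen.labels["const"] == "low_variance"
        assert set(frame.columns) >= {"r_max", "best_lag_hours", "fpkm_variance", "label"}


class TestListOverlapReport:
    def test_published_style_overlap(self):
        a = {f"g{i}" for i in range(152)}
        b = {f"g{i}" for i in range(64)} | {f"x{i}" for i in range(13)}
        rep = tx.list_overlap_report(a, b)
        assert rep == {"n_a": 152, "n_b": 77, "n_intersection": 64, "pct_of_smaller": 83}

    def test_identical_and_disjoint_sets(self):
        assert tx.list_overlap_report({"a", "b"}, {"a", "b"})["pct_of_smaller"] == 100
        assert tx.list_overlap_report({"a"}, {"b"})["pct_of_smaller"] == 0
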