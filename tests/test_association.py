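import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import naive_spearman_rho
from recland.association import (
    ConstantInputError,
    NoRecombiningIntervalsError,
    correlate_tracks,
    exclude_zero_intervals,
    format_matrix,
    spearman,
    stars,
)
from recland.coordinates import ChromosomeModel, build_interval_grid
from recland.features import FeatureTrack
from recland.recmap import RecombinationTrack


def _tracks(rates, gc=None, cgi=None, gene_pct=None, chrom="chr1", interval=1_000_000):
    rates = np.asarray(rates, dtype=float)
    n = rates.size
    grid = build_interval_grid(ChromosomeModel(chrom, n * interval), interval)
    rec = RecombinationTrack(
        grid=grid,
        foci=np.zeros(n, dtype=int),
        n_cells=100,
        cM=rates * (interval / 1e6),
        rate=rates,
    )
    feat = FeatureTrack(
        grid=grid,
        gc=np.asarray(gc if gc is not None else np.linspace(0.4, 0.6, n)),
        cgi_count=np.asarray(cgi if cgi is not None else np.arange(n)),
        gene_count=np.ones(n, dtype=int),
        gene_pct=np.asarray(gene_pct if gene_pct is not None else np.full(n, 100.0 / n)),
    )
    return rec, feat


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman([1, 2, 3, 4], [40, 30, 20, 10])
        assert rho == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        rho, _ = spearman([1, 2, 3], [2, 1, 3])
        assert rho == pytest.approx(0.5)

    def test_constant_vector_flagged(self):
        with pytest.raises(ConstantInputError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_short(self):
        with pytest.raises(ValueError, match="at least 3"):
            spearman([1, 2], [1, 2])

    def test_exact_p_matches_enumeration_n4(self):
        # perfect monotone arrangement of 4 distinct values: 2 of the 24
        # permutations reach |rho| = 1, so the exact two-sided p is 1/12
        _, p = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert p == pytest.approx(2 / 24)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(1)
        x, y = rng.random(50), rng.random(50)
        from scipy import stats

        rho, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    @given(
        st.lists(st.integers(0, 50), min_size=5, max_size=8),
        st.lists(st.integers(0, 50), min_size=8, max_size=8),
    )
    @settings(max_examples=50, deadline=None)
    def test_rho_matches_naive_ranks(self, x, y):
        y = y[: len(x)]
        x_arr, y_arr = np.array(x, float), np.array(y, float)
        if np.all(x_arr == x_arr[0]) or np.all(y_arr == y_arr[0]):
            return
        rho, _ = spearman(x_arr, y_arr)
        assert rho == pytest.approx(naive_spearman_rho(x, y))

    @given(st.lists(st.integers(-1000, 1000), min_size=11, max_size=30, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_monotone_transform(self, x):
        rng = np.random.default_rng(0)
        y = rng.permutation(len(x)).astype(float)
        x = np.array(x, dtype=float)
        rho1, p1 = spearman(x, y)
        rho2, p2 = spearman(np.exp(x / 500), y)  # strictly increasing transform
        assert rho1 == pytest.approx(rho2)
        assert p1 == pytest.approx(p2)


class TestExcludeZeroIntervals:
    def test_all_positive_unchanged(self):
        r, f, dropped = exclude_zero_intervals([1.0, 2.0], [5.0, 6.0])
        assert r.tolist() == [1.0, 2.0] and f.tolist() == [5.0, 6.0] and dropped == 0

    def test_all_zero_rejected(self):
        with pytest.raises(NoRecombiningIntervalsError):
            exclude_zero_intervals([0.0, 0.0], [1.0, 2.0])

    def test_direct_filter(self):
        r, f, dropped = exclude_zero_intervals([0, 1, 0, 2], [5, 6, 7, 8])
        assert r.tolist() == [1.0, 2.0]
        assert f.tolist() == [6.0, 8.0]
        assert dropped == 2

    @given(
        rates=st.lists(st.floats(0, 10), min_size=1, max_size=30),
    )
    @settings(max_examples=50, deadline=None)
    def test_survivors_unaltered(self, rates):
        feats = list(range(len(rates)))
        expected = [(r, f) for r, f in zip(rates, feats) if r != 0]
        if not expected:
            with pytest.raises(NoRecombiningIntervalsError):
                exclude_zero_intervals(rates, feats)
            return
        r, f, dropped = exclude_zero_intervals(rates, feats)
        assert list(zip(r.tolist(), f.tolist())) == expected
        assert dropped == len(rates) - len(expected)


class TestCorrelateTracks:
    def test_feature_equal_to_rate_gives_rho_1(self):
        rates = np.arange(1, 13, dtype=float)
        rec, feat = _tracks(rates, gc=rates, cgi=rates, gene_pct=rates)
        results = correlate_tracks({"chr1": rec}, {"chr1": feat})
        assert {r.feature for r in results} == {"gc", "cgi", "gene"}
        for r in results:
            assert r.rho == pytest.approx(1.0)
            assert r.significant

    def test_null_feature_rarely_significant(self):
        # independent feature: p > 0.05 in >= 90% of 200 seeded replicates
        rng = np.random.default_rng(2024)
        n_sig = 0
        for _ in range(200):
            rates = rng.random(100)
            gc = rng.random(100)
            rec, feat = _tracks(rates, gc=gc)
            (res,) = correlate_tracks({"chr1": rec}, {"chr1": feat}, features=["gc"])
            assert abs(res.rho) < 0.5
            if res.p_value <= 0.05:
                n_sig += 1
        assert n_sig <= 20

    def test_pooled_counts_add_up(self):
        rec1, feat1 = _tracks(np.arange(1, 11, dtype=float), chrom="chr1")
        rec2, feat2 = _tracks(np.arange(1, 11, dtype=float), chrom="chr2")
        results = correlate_tracks(
            {"chr1": rec1, "chr2": rec2},
            {"chr1": feat1, "chr2": feat2},
            pooled=["chr1", "chr2"],
            features=["gc"],
        )
        by_scope = {r.chromosome: r for r in results}
        assert by_scope["pooled_chr1_chr2"].n_pairs == 20
        assert (
            by_scope["pooled_chr1_chr2"].n_pairs
            == by_scope["chr1"].n_pairs + by_scope["chr2"].n_pairs
        )

    def test_nonzero_mode_drops_zero_intervals(self):
        rates = np.array([0.0, 1, 2, 3, 0, 4, 5, 6, 7, 8, 9, 10])
        rec, feat = _tracks(rates)
        (res_all,) = correlate_tracks({"chr1": rec}, {"chr1": feat}, features=["gc"])
        (res_nz,) = correlate_tracks(
            {"chr1": rec}, {"chr1": feat}, mode="nonzero_only", features=["gc"]
        )
        assert res_all.n_pairs == 12
        assert res_nz.n_pairs == 10
        assert res_nz.zero_excluded and not res_all.zero_excluded

    def test_grid_mismatch_rejected(self):
        rec, _ = _tracks(np.arange(1, 13, dtype=float))
        _, feat = _tracks(np.arange(1, 7, dtype=float))
        with pytest.raises(ValueError, match="grid mismatch"):
            correlate_tracks({"chr1": rec}, {"chr1": feat})

    def test_missing_gc_excluded_pairwise(self):
        rates = np.arange(1, 13, dtype=float)
        gc = np.linspace(0.4, 0.6, 12)
        gc[3] = np.nan
        rec, feat = _tracks(rates, gc=gc)
        (res,) = correlate_tracks({"chr1": rec}, {"chr1": feat}, features=["gc"])
        assert res.n_pairs == 11

    def test_arm_mask_restricts_intervals(self):
        rates = np.arange(1, 13, dtype=float)
        rec, feat = _tracks(rates)
        (res,) = correlate_tracks(
            {"chr1": rec},
            {"chr1": feat},
            features=["gc"],
            masks={"chr1": (4_000_000, 12_000_000)},
        )
        assert res.n_pairs == 8  # intervals 4..11 of the 12 Mb chromosome


class TestFormatMatrix:
    def test_threshold_mapping(self):
        rates = np.arange(1, 13, dtype=float)
        rec, feat = _tracks(rates, gc=rates)
        results = correlate_tracks({"chr1": rec}, {"chr1": feat}, features=["gc"])
        table = format_matrix(results)
        assert table.loc["chr1", "gc"].startswith("1.00")
        assert table.loc["chr1", "gc"].endswith("***")

    def test_blank_when_not_significant(self):
        rng = np.random.default_rng(5)
        found_blank = False
        for _ in range(10):
            rec, feat = _tracks(rng.random(12), gc=rng.random(12))
            results = correlate_tracks({"chr1": rec}, {"chr1": feat}, features=["gc"])
            if results[0].p_value > 0.2:
                table = format_matrix(results)
                assert table.loc["chr1", "gc"] == ""
                found_blank = True
                break
        assert found_blank

    def test_stars_mapping(self):
        assert stars(0.004) == "**"
        assert stars(0.0004) == "***"
        assert stars(0.04) == "*"
        assert stars(0.5) == ""
        assert stars(None) == ""

    def test_empty_feature_column_omitted_with_warning(self):
        rates = np.arange(1, 13, dtype=float)
        rec, feat = _tracks(rates, gc=np.full(12, np.nan))
        results = correlate_tracks({"chr1": rec}, {"chr1": feat}, features=["gc", "cgi"])
        with pytest.warns(UserWarning, match="no computable result"):
            table = format_matrix(results)
        assert "gc" not in table.columns
        assert "cgi" in table.columns

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError, match="no association results"):
            format_matrix([])


class TestBenjaminiHochberg:
    def test_bh_is_more_conservative(self):
        rng = np.random.default_rng(8)
        rec1, feat1 = _tracks(np.arange(1, 13, dtype=float) + rng.random(12), chrom="chr1")
        rec2, feat2 = _tracks(rng.random(12), gc=rng.random(12), chrom="chr2")
        raw = correlate_tracks({"chr1": rec1, "chr2": rec2}, {"chr1": feat1, "chr2": feat2})
        adj = correlate_tracks(
            {"chr1": rec1, "chr2": rec2}, {"chr1": feat1, "chr2": feat2}, bh_correct=True
        )
        for r, a in zip(raw, adj):
            if r.p_value is not None:
                assert a.p_value >= r.p_value - 1e-12
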