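import math

import numpy as np
import pytest
from scipy import stats

from chipxpress.correlation import (
    TruncationParams,
    correlation_zscore,
    tf_diagnostics,
    truncated_abs_correlation_all,
    truncated_correlation,
)

from conftest import make_compendium_raw, random_compendium

NEG_INF = float("-inf")


def oracle_truncated(x, y, c):
    """Independent loop-based oracle: filter samples by hand, then Pearson."""
    xs, ys = [], []
    for xi, yi in zip(x, y):
        if xi >= c:
            xs.append(xi)
            ys.append(yi)
    if len(xs) < 3 or len(set(xs)) == 1 or len(set(ys)) == 1:
        return None, len(xs)
    return stats.pearsonr(xs, ys).statistic, len(xs)


class TestTruncatedCorrelation:
    def test_self_correlation_is_one(self, small_cp):
        res = truncated_correlation(
            small_cp, "g000", "g000", TruncationParams(c=NEG_INF)
        )
        assert res.valid
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.a == pytest.approx(1.0, abs=1e-12)
        assert res.n_used == small_cp.n_samples

    def test_worked_example_four_retained_samples(self):
        # samples with TF value >= 0 are 1,2,3,6 (1-based); frozen oracle value
        # from scipy.stats.pearsonr on the hand-filtered subset
        cp = make_compendium_raw(
            ["tf", "y"],
            [[2, 1, 0.5, -1, -2, 0.2], [2.1, 0.9, 0.6, 5, 5, 0.1]],
        )
        res = truncated_correlation(cp, "tf", "y", TruncationParams(c=0.0))
        assert res.valid
        assert res.n_used == 4
        assert res.r == pytest.approx(0.9928346591550155, abs=1e-12)
        assert res.a == pytest.approx(0.9928346591550155, abs=1e-12)

    def test_gene_constant_within_truncation_set_invalid(self):
        cp = make_compendium_raw(
            ["tf", "y"],
            [[1, 2, 3, -1, -2], [7, 7, 7, 1, 2]],
        )
        res = truncated_correlation(cp, "tf", "y", TruncationParams(c=0.0))
        assert not res.valid
        assert math.isnan(res.r) and math.isnan(res.a)

    def test_too_few_retained_samples_invalid(self):
        cp = make_compendium_raw(["tf", "y"], [[5, -1, -1, -2], [1, 2, 3, 4]])
        res = truncated_correlation(cp, "tf", "y", TruncationParams(c=0.0))
        assert not res.valid
        assert res.n_used == 1

    def test_absent_tf_errors(self, small_cp):
        with pytest.raises(KeyError, match="TF not in compendium"):
            truncated_correlation(small_cp, "nope", "g000")

    def test_absent_gene_errors_single_but_not_batch(self, small_cp):
        with pytest.raises(KeyError, match="gene not in compendium"):
            truncated_correlation(small_cp, "g000", "nope")
        res = truncated_abs_correlation_all(small_cp, "g000", ["g001", "nope"])
        assert res[0].valid and not res[1].valid

    def test_batch_equals_single_calls(self, small_cp):
        genes = ["g003", "g007", "g011"]
        params = TruncationParams(c=0.2)
        batch = truncated_abs_correlation_all(small_cp, "g000", genes, params)
        for g, b in zip(genes, batch):
            s = truncated_correlation(small_cp, "g000", g, params)
            assert (b.r, b.a, b.n_used, b.valid) == (s.r, s.a, s.n_used, s.valid)

    def test_no_truncation_equals_plain_pearson(self, small_cp):
        params = TruncationParams(c=NEG_INF)
        results = truncated_abs_correlation_all(
            small_cp, "g000", small_cp.gene_ids, params
        )
        x = small_cp.row("g000")
        for res in results:
            expected = stats.pearsonr(x, small_cp.row(res.gene_id)).statistic
            assert res.r == pytest.approx(expected, abs=1e-13)
            assert res.n_used == small_cp.n_samples

    def test_matches_bruteforce_on_random_compendium(self, rng):
        cp = random_compendium(rng, 50, 30)
        results = truncated_abs_correlation_all(
            cp, "g000", cp.gene_ids, TruncationParams(c=0.5)
        )
        x = cp.row("g000")
        for res in results:
            expected, n = oracle_truncated(x, cp.row(res.gene_id), 0.5)
            assert res.n_used == n
            if expected is None:
                assert not res.valid
            else:
                assert res.r == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("c_pair", [(NEG_INF, -1.0), (-1.0, 0.0), (0.0, 1.0)])
    def test_n_used_non_increasing_in_c(self, small_cp, c_pair):
        lo, hi = c_pair
        r_lo = truncated_correlation(small_cp, "g000", "g005", TruncationParams(c=lo))
        r_hi = truncated_correlation(small_cp, "g000", "g005", TruncationParams(c=hi))
        assert r_hi.n_used <= r_lo.n_used

    def test_abs_correlation_invariant_under_sign_flip(self, rng):
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        cp = make_compendium_raw(["tf", "y", "yneg"], [x, y, -y])
        res = truncated_abs_correlation_all(cp, "tf", ["y", "yneg"], TruncationParams(c=0.0))
        assert res[0].a == pytest.approx(res[1].a, abs=1e-15)
        assert res[0].r == pytest.approx(-res[1].r, abs=1e-15)

    def test_min_samples_below_three_rejected(self):
        with pytest.raises(ValueError, match="min_samples"):
            TruncationParams(min_samples=2)


class TestCorrelationZscore:
    def test_gene_at_null_mean_has_zero_z(self, rng):
        cp = random_compendium(rng, 40, 25)
        params = TruncationParams(c=NEG_INF)
        results = truncated_abs_correlation_all(cp, "g000", cp.gene_ids, params)
        rs = np.array([r.r for r in results if r.valid])
        closest = min(
            (r for r in results if r.valid), key=lambda r: abs(r.r - rs.mean())
        )
        z = correlation_zscore(cp, "g000", closest.gene_id, params)
        expected = (closest.r - rs.mean()) / rs.std(ddof=1)
        assert z == pytest.approx(expected, abs=1e-12)
        assert abs(z) == min(
            abs(correlation_zscore(cp, "g000", g.gene_id, params))
            for g in results if g.valid
        )

    def test_planted_target_has_maximal_z(self, rng):
        n = 60
        x = rng.standard_normal(n)
        rows = [x] + [rng.standard_normal(n) for _ in range(99)]
        rows[37] = 0.95 * x + 0.05 * rng.standard_normal(n)
        ids = ["tf"] + [f"g{i:03d}" for i in range(99)]
        cp = make_compendium_raw(ids, rows)
        params = TruncationParams(c=NEG_INF)
        target = ids[37]
        z_target = correlation_zscore(cp, "tf", target, params)
        others = [g for g in ids if g not in ("tf", target)]
        assert z_target > max(correlation_zscore(cp, "tf", g, params) for g in others)

    def test_small_null_errors(self):
        cp = make_compendium_raw(
            [f"g{i}" for i in range(4)], np.random.default_rng(0).standard_normal((4, 8))
        )
        with pytest.raises(ValueError, match="null distribution too small"):
            correlation_zscore(cp, "g0", "g1")

    def test_degenerate_null_errors(self):
        # every gene identical to the TF: all correlations are exactly 1
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 7.0])
        cp = make_compendium_raw([f"g{i}" for i in range(12)], [x] * 12)
        with pytest.raises(ValueError, match="zero variance"):
            correlation_zscore(cp, "g0", "g1", TruncationParams(c=NEG_INF))


class TestTFDiagnostics:
    def test_minimum_variance_gene_gets_strong_warning(self, rng):
        vals = rng.standard_normal((30, 10)) + 5
        vals[3] *= 0.01  # smallest variance by far
        from chipxpress.compendium import GeneMatrix, standardize

        cp = standardize(GeneMatrix([f"g{i}" for i in range(30)],
                                    [f"s{i}" for i in range(10)], vals))
        diag = tf_diagnostics(cp, "g3")
        assert diag.warnings["variance"] == "strong"

    def test_median_gene_unflagged(self, rng):
        cp = random_compendium(rng, 101, 10)
        meta = cp.gene_meta
        median_gene = (meta["mu"] - meta["mu"].median()).abs().idxmin()
        diag = tf_diagnostics(cp, median_gene)
        assert diag.warnings["mean"] == "none"
        assert 0.3 < diag.quantile_position["mean"] < 0.7

    def test_tenth_percentile_mean_is_mild(self, rng):
        vals = rng.standard_normal((100, 10))
        vals += np.arange(100)[:, None]  # gene k has mean ~k
        from chipxpress.compendium import GeneMatrix, standardize

        cp = standardize(GeneMatrix([f"g{i:03d}" for i in range(100)],
                                    [f"s{i}" for i in range(10)], vals))
        diag = tf_diagnostics(cp, "g010")
        assert diag.warnings["mean"] == "mild"
        assert diag.quantile_position["mean"] == pytest.approx(0.10, abs=0.02)

    def test_absent_tf_errors(self, small_cp):
        with pytest.raises(KeyError):
            tf_diagnostics(small_cp, "nope")
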