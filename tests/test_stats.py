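"""Validation statistics against independent brute-force oracles, plus
degenerate-input and reproducibility contracts."""

import math

import numpy as np
import pytest

from gfrval.stats import (
    ComparisonReport,
    GFRPair,
    bias,
    bland_altman,
    bootstrap_ci,
    compare_bias_wilcoxon,
    compare_models,
    compare_p30_mcnemar,
    compare_precision_bootstrap,
    correlation_and_regression,
    p30,
    precision,
)
from conftest import make_pairs

# ---------------------------------------------------------------------------
# independent oracles (pure-python / direct formula implementations)


def brute_quantile(values, q):
    """Linear-interpolation quantile from first principles."""
    v = sorted(values)
    h = (len(v) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def brute_bias(pairs):
    return brute_quantile([p.egfr - p.mgfr for p in pairs], 0.5)


def brute_precision(pairs):
    d = [p.egfr - p.mgfr for p in pairs]
    return brute_quantile(d, 0.75) - brute_quantile(d, 0.25)


def brute_p30(pairs):
    hits = sum(1 for p in pairs if abs(p.egfr - p.mgfr) <= 0.30 * p.mgfr + 1e-9)
    return 100.0 * hits / len(pairs)


def brute_ols(pairs):
    """Normal equations by hand."""
    x = [p.mgfr for p in pairs]
    y = [p.egfr for p in pairs]
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    return slope, (sy - slope * sx) / n


def brute_spearman(pairs):
    def avg_ranks(values):
        order = sorted(range(len(values)), key=lambda i: values[i])
        ranks = [0.0] * len(values)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx = avg_ranks([p.mgfr for p in pairs])
    ry = avg_ranks([p.egfr for p in pairs])
    mx, my = np.mean(rx), np.mean(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


def brute_mcnemar_exact(b, c):
    """Two-sided exact binomial p over the discordant margin."""
    n = b + c
    k = min(b, c)
    tail = sum(math.comb(n, i) for i in range(0, k + 1)) / 2**n
    return min(1.0, 2.0 * tail)


# ---------------------------------------------------------------------------


class TestTriadBasics:
    def test_bias_constant_shift(self):
        mgfr = np.array([30.0, 50.0, 70.0])
        assert bias(make_pairs(mgfr + 4.2, mgfr)) == pytest.approx(4.2)

    def test_bias_median_rules(self):
        mgfr = np.full(3, 50.0)
        assert bias(make_pairs(mgfr + np.array([-1, 0, 5]), mgfr)) == 0.0
        mgfr = np.full(4, 50.0)
        assert bias(make_pairs(mgfr + np.array([1, 2, 3, 10]), mgfr)) == 2.5

    def test_precision_known_values(self):
        mgfr = np.full(4, 50.0)
        assert precision(make_pairs(mgfr + 7.0, mgfr)) == 0.0
        mgfr = np.full(100, 50.0)
        diffs = np.arange(1.0, 101.0)
        assert precision(make_pairs(mgfr + diffs, mgfr)) == pytest.approx(49.5)

    def test_precision_shift_invariant(self, random_pairs):
        shifted = [GFRPair(p.patient_id, p.egfr + 11.0, p.mgfr) for p in random_pairs]
        assert precision(shifted) == pytest.approx(precision(random_pairs))

    def test_p30_exact_and_boundary(self):
        mgfr = np.array([20.0, 50.0, 80.0, 120.0])
        assert p30(make_pairs(mgfr.copy(), mgfr)) == 100.0
        assert p30(make_pairs(1.30 * mgfr, mgfr)) == 100.0  # inclusive boundary
        egfr = mgfr.copy()
        egfr[0] = 2.0 * mgfr[0]
        assert p30(make_pairs(egfr, mgfr)) == 75.0

    def test_p30_requires_positive_mgfr(self):
        with pytest.raises(ValueError, match="mgfr > 0"):
            p30([GFRPair("a", 10.0, 0.0)])

    def test_small_sample_preconditions(self):
        with pytest.raises(ValueError):
            bias([])
        with pytest.raises(ValueError):
            precision(make_pairs([1.0, 2.0], [1.0, 2.0]))

    def test_triad_matches_brute_force_on_random_fixtures(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 40))
            mgfr = rng.uniform(5, 150, n)
            egfr = mgfr * np.exp(rng.normal(0, 0.3, n))
            pairs = make_pairs(egfr, mgfr)
            assert bias(pairs) == pytest.approx(brute_bias(pairs), rel=1e-12)
            assert precision(pairs) == pytest.approx(brute_precision(pairs), rel=1e-9)
            assert p30(pairs) == pytest.approx(brute_p30(pairs))


class TestBlandAltman:
    def test_degenerate_spread(self):
        mgfr = np.array([30.0, 50.0, 70.0])
        ba = bland_altman(make_pairs(mgfr + 3.0, mgfr), sign="egfr_minus_mgfr")
        assert ba.mean_diff == pytest.approx(3.0)
        assert ba.loa_low == pytest.approx(ba.loa_high) == pytest.approx(3.0)
        assert ba.width == pytest.approx(0.0)

    def test_sign_flip_symmetry(self, random_pairs):
        fwd = bland_altman(random_pairs, sign="egfr_minus_mgfr")
        rev = bland_altman(random_pairs, sign="mgfr_minus_egfr")
        assert rev.mean_diff == pytest.approx(-fwd.mean_diff)
        assert rev.loa_low == pytest.approx(-fwd.loa_high)
        assert rev.width == pytest.approx(fwd.width)

    def test_limits_span_from_constructed_spread(self):
        # four diffs with sample SD s give limits mean ± 1.96 s, span 3.92 s;
        # s chosen so the span is 52.6
        s = 52.6 / 3.92
        a = s * math.sqrt(3.0) / 2.0
        mean = (21.4 - 31.2) / 2
        diffs = np.array([mean - a, mean - a, mean + a, mean + a])
        mgfr = np.full(4, 60.0)
        ba = bland_altman(make_pairs(mgfr + diffs, mgfr), sign="egfr_minus_mgfr")
        assert ba.width == pytest.approx(52.6, abs=1e-9)
        assert ba.loa_low == pytest.approx(-31.2, abs=1e-9)
        assert ba.loa_high == pytest.approx(21.4, abs=1e-9)

    def test_sample_sd_uses_n_minus_1(self):
        mgfr = np.full(3, 50.0)
        diffs = np.array([-1.0, 0.0, 1.0])
        ba = bland_altman(make_pairs(mgfr + diffs, mgfr), sign="egfr_minus_mgfr")
        assert ba.sd == pytest.approx(1.0)

    def test_minimum_n(self):
        with pytest.raises(ValueError):
            bland_altman(make_pairs([1.0, 2.0], [1.0, 2.0]))


class TestCorrelationRegression:
    def test_exact_line(self):
        mgfr = np.linspace(10, 100, 20)
        r, slope, intercept = correlation_and_regression(
            make_pairs(2 * mgfr + 5, mgfr)
        )
        assert (r, slope, intercept) == pytest.approx((1.0, 2.0, 5.0))

    def test_rank_invariance(self, rng):
        mgfr = rng.uniform(10, 150, 30)
        r, _, _ = correlation_and_regression(make_pairs(np.sqrt(mgfr) + 3, mgfr))
        assert r == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            mgfr = rng.uniform(40, 150, 5)
            egfr = np.maximum(mgfr + rng.normal(0, 10, 5), 0.0)
            pairs = make_pairs(egfr, mgfr)
            r, slope, intercept = correlation_and_regression(pairs)
            bs, bi = brute_ols(pairs)
            assert slope == pytest.approx(bs, rel=1e-9)
            assert intercept == pytest.approx(bi, rel=1e-9)
            assert r == pytest.approx(brute_spearman(pairs), rel=1e-9)


class TestBootstrapCI:
    def test_degenerate_data_collapses_to_point(self):
        pairs = make_pairs(np.full(20, 55.0), np.full(20, 50.0))
        for stat in ("bias", "precision", "p30"):
            lo, hi = bootstrap_ci(stat, pairs, B=300, seed=1)
            assert lo == hi

    def test_same_seed_same_interval(self, random_pairs):
        assert bootstrap_ci("bias", random_pairs, B=400, seed=9) == bootstrap_ci(
            "bias", random_pairs, B=400, seed=9
        )

    def test_callable_statistic_agrees_with_named_path(self, random_pairs):
        named = bootstrap_ci("bias", random_pairs, B=300, seed=4)
        called = bootstrap_ci(bias, random_pairs, B=300, seed=4)
        assert named == pytest.approx(called)

    def test_interval_brackets_point_estimate(self, random_pairs):
        for stat, fn in (("bias", bias), ("precision", precision), ("p30", p30)):
            lo, hi = bootstrap_ci(stat, random_pairs, B=500, seed=2)
            assert lo <= fn(random_pairs) <= hi

    def test_rejects_tiny_replicate_count(self, random_pairs):
        with pytest.raises(ValueError):
            bootstrap_ci("bias", random_pairs, B=50, seed=0)


class TestBetweenModelTests:
    def test_wilcoxon_identical_models_degenerate(self, random_pairs):
        with pytest.warns(UserWarning, match="degenerate"):
            assert compare_bias_wilcoxon(random_pairs, random_pairs) == 1.0

    def test_wilcoxon_detects_constant_shift(self, rng):
        mgfr = rng.uniform(20, 120, 40)
        noise = rng.normal(0, 3, 40)
        pairs_a = make_pairs(mgfr + noise + 5.0, mgfr)
        pairs_b = make_pairs(mgfr + noise, mgfr)
        assert compare_bias_wilcoxon(pairs_a, pairs_b) < 1e-6

    def test_wilcoxon_requires_matched_patients(self, rng):
        mgfr = rng.uniform(20, 120, 10)
        pairs_a = make_pairs(mgfr, mgfr, prefix="A")
        pairs_b = make_pairs(mgfr, mgfr, prefix="B")
        with pytest.raises(ValueError, match="same patients"):
            compare_bias_wilcoxon(pairs_a, pairs_b)

    @pytest.mark.parametrize("method", ["label_swap", "percentile"])
    def test_precision_bootstrap_identical_is_one(self, random_pairs, method):
        assert (
            compare_precision_bootstrap(
                random_pairs, random_pairs, B=400, seed=0, method=method
            )
            == 1.0
        )

    def test_precision_bootstrap_detects_tripled_spread(self, rng):
        mgfr = rng.uniform(20, 120, 200)
        noise = rng.normal(0, 5, 200)
        pairs_a = make_pairs(np.maximum(mgfr + 3 * noise, 0.0), mgfr)
        pairs_b = make_pairs(np.maximum(mgfr + noise, 0.0), mgfr)
        p = compare_precision_bootstrap(pairs_a, pairs_b, B=2000, seed=3)
        assert p < 0.01

    def test_precision_bootstrap_deterministic(self, random_pairs, rng):
        other = [
            GFRPair(p.patient_id, p.egfr * 1.3, p.mgfr) for p in random_pairs
        ]
        args = (random_pairs, other)
        assert compare_precision_bootstrap(
            *args, B=500, seed=7
        ) == compare_precision_bootstrap(*args, B=500, seed=7)

    def _indicator_pairs(self, in_a, in_b):
        """Pair sets realizing given within-30% indicator vectors."""
        pairs_a, pairs_b = [], []
        for i, (a, b) in enumerate(zip(in_a, in_b)):
            m = 50.0
            pairs_a.append(GFRPair(f"P{i}", m if a else 2 * m, m))
            pairs_b.append(GFRPair(f"P{i}", m if b else 2 * m, m))
        return pairs_a, pairs_b

    def test_mcnemar_no_discordance_degenerate(self):
        pairs_a, pairs_b = self._indicator_pairs([1] * 8 + [0] * 2, [1] * 8 + [0] * 2)
        with pytest.warns(UserWarning, match="degenerate"):
            assert compare_p30_mcnemar(pairs_a, pairs_b) == 1.0

    def test_mcnemar_symmetric_discordance(self):
        in_a = [1] * 5 + [0] * 5 + [1] * 5
        in_b = [0] * 5 + [1] * 5 + [1] * 5
        pairs_a, pairs_b = self._indicator_pairs(in_a, in_b)
        assert compare_p30_mcnemar(pairs_a, pairs_b) == pytest.approx(1.0)

    def test_mcnemar_exact_matches_binomial_sum(self):
        in_a = [1] * 15 + [0] * 3 + [1] * 10
        in_b = [0] * 15 + [1] * 3 + [1] * 10
        pairs_a, pairs_b = self._indicator_pairs(in_a, in_b)
        p = compare_p30_mcnemar(pairs_a, pairs_b)
        assert p == pytest.approx(brute_mcnemar_exact(15, 3), rel=1e-12)
        assert p == pytest.approx(0.007537841796875, rel=1e-12)

    def test_mcnemar_large_margin_uses_corrected_chi_square(self):
        in_a = [1] * 30 + [0] * 10
        in_b = [0] * 30 + [1] * 10
        pairs_a, pairs_b = self._indicator_pairs(in_a, in_b)
        # continuity-corrected chi-square: (|30-10|-1)^2 / 40
        from scipy.stats import chi2

        expected = float(chi2.sf((abs(30 - 10) - 1) ** 2 / 40.0, 1))
        assert compare_p30_mcnemar(pairs_a, pairs_b) == pytest.approx(expected)


class TestComparisonReport:
    def build(self, rng, n=80, seed=5, B=300):
        mgfr = rng.lognormal(3.9, 0.8, n)
        pairs_a = make_pairs(mgfr * np.exp(rng.normal(0.1, 0.3, n)), mgfr)
        pairs_b = make_pairs(mgfr * np.exp(rng.normal(0.0, 0.2, n)), mgfr)
        return compare_models(
            pairs_a, pairs_b, name_a="m_a", name_b="m_b", bootstrap_reps=B, seed=seed
        )

    def test_json_round_trip_lossless(self, rng):
        report = self.build(rng)
        clone = ComparisonReport.from_json(report.to_json())
        assert clone.to_dict() == report.to_dict()

    def test_invariants_on_random_cohorts(self, rng):
        for _ in range(15):
            report = self.build(rng, n=int(rng.integers(20, 120)))
            for perf in (report.model_a, report.model_b):
                assert perf.ba_loa_low < perf.ba_loa_high
                assert perf.ba_loa_width == pytest.approx(
                    perf.ba_loa_high - perf.ba_loa_low
                )
                assert 0.0 <= perf.p30 <= 100.0
                for ci in (perf.bias_ci, perf.precision_ci, perf.p30_ci):
                    assert ci[0] <= ci[1]
            for p in (
                report.p_bias_wilcoxon,
                report.p_precision_bootstrap,
                report.p_p30_mcnemar,
            ):
                assert 0.0 <= p <= 1.0

    def test_location_frame_consistency(self, rng):
        mgfr = rng.lognormal(3.9, 0.7, 60)
        egfr = mgfr * np.exp(rng.normal(0, 0.25, 60))
        pairs = make_pairs(egfr, mgfr)
        shifted = make_pairs(egfr + 7.0, mgfr)
        assert bias(shifted) == pytest.approx(bias(pairs) + 7.0)
        assert precision(shifted) == pytest.approx(precision(pairs))
        ba0 = bland_altman(pairs, sign="egfr_minus_mgfr")
        ba1 = bland_altman(shifted, sign="egfr_minus_mgfr")
        assert ba1.mean_diff == pytest.approx(ba0.mean_diff + 7.0)
        assert ba1.width == pytest.approx(ba0.width)

    def test_small_cohort_degrades_to_null_cells(self):
        mgfr = np.array([40.0, 60.0])
        pairs = make_pairs(mgfr * 1.1, mgfr)
        report = compare_models(pairs, pairs, bootstrap_reps=300, seed=0)
        assert report.model_a.bias is not None
        assert report.model_a.precision is None
        assert report.model_a.ba_mean_diff is None
        assert report.p_bias_wilcoxon is None
        assert any("precision" in k for k in report.null_reasons)
        assert "n/a" in report.to_text()

    def test_text_table_mentions_all_blocks(self, rng):
        text = self.build(rng).to_text()
        for token in ("Bias", "Precision", "P30", "Limits of agreement", "Wilcoxon"):
            assert token in text
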