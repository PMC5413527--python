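"""Histogram metrics against exhaustive / closed-form oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spectsync import metrics as M


def brute_force_bandwidth(phases, coverage=0.95):
    """O(n^2) oracle: for every sample as arc start, the width reaching
    the ceil(coverage*n)-th sample; the minimum over starts."""
    p = np.asarray(phases, dtype=float) % 360.0
    n = p.size
    m = int(math.ceil(coverage * n))
    best = 360.0
    for start in p:
        rel = np.sort((p - start) % 360.0)
        best = min(best, rel[m - 1])
    return best


class TestHistogram:
    def test_single_bin(self):
        h = M.build_histogram([50.2] * 100, bin_deg=1.0)
        assert h.n_bins == 360
        assert h.freq[50] == pytest.approx(1.0)
        assert np.count_nonzero(h.freq) == 1

    def test_uniform_integers(self):
        h = M.build_histogram(np.arange(360.0), bin_deg=1.0)
        assert np.allclose(h.freq, 1.0 / 360.0)

    def test_bin_edge_is_lower_inclusive(self):
        h = M.build_histogram([10.0], bin_deg=1.0)
        assert h.freq[10] == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(M.MetricInputError):
            M.build_histogram([])

    def test_bin_must_tile_circle(self):
        with pytest.raises(M.MetricInputError):
            M.build_histogram([1.0], bin_deg=7.0)


class TestPsd:
    def test_identical_phases(self):
        assert M.psd([42.0, 42.0, 42.0]) == pytest.approx(0.0, abs=1e-12)

    def test_direct_formula(self):
        assert M.psd([100.0, 110.0, 120.0]) == pytest.approx(
            math.sqrt(200.0 / 3.0), abs=1e-9)

    def test_wrap_pair(self):
        assert M.psd([350.0, 10.0]) == pytest.approx(10.0, abs=1e-9)

    def test_minimal_dispersion_oracle_on_wrap_sets(self):
        # brute force over all recenterings: PSD equals the minimal linear SD
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = (rng.normal(0.0, 25.0, size=40)) % 360.0
            best = min(np.std((p + d) % 360.0) for d in np.arange(0.0, 360.0, 0.25))
            assert M.psd(p) == pytest.approx(best, abs=0.05)

    @given(st.lists(st.floats(0.0, 179.0), min_size=2, max_size=200))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_wrap_free_equals_plain_sd(self, phases):
        assert M.psd(phases) == pytest.approx(float(np.std(phases)), abs=1e-9)

    def test_too_few_samples(self):
        with pytest.raises(M.MetricInputError):
            M.psd([10.0])


class TestBandwidth:
    def test_identical_samples(self):
        assert M.bandwidth95([180.0] * 50) == pytest.approx(0.0)

    def test_integer_run(self):
        # 95 consecutive integers span 94 degrees
        assert M.bandwidth95(np.arange(1.0, 101.0)) == pytest.approx(94.0)

    def test_outliers_excluded_exactly(self):
        p = np.concatenate([np.full(95, 180.0), np.zeros(5)])
        assert M.bandwidth95(p) == pytest.approx(0.0)

    def test_small_n_flagged_full_range(self):
        with pytest.warns(UserWarning):
            w = M.bandwidth95([10.0, 20.0, 350.0])
        assert w == pytest.approx(30.0)  # shortest arc covering all three

    @given(st.integers(0, 2**31 - 1), st.integers(20, 1000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_exhaustive_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        mix = rng.choice([0, 1], size=n)
        p = np.where(mix, rng.uniform(0, 360, n), rng.normal(200, 30, n) % 360)
        assert M.bandwidth95(p) == pytest.approx(brute_force_bandwidth(p), abs=1e-9)

    def test_trim_tails_mode_close_to_arc_on_unimodal(self):
        rng = np.random.default_rng(2)
        p = rng.normal(180.0, 10.0, size=500)
        arc = M.bandwidth95(p)
        trim = M.bandwidth95(p, mode="trim_tails")
        assert abs(arc - trim) < 10.0


class TestEntropy:
    def test_delta_is_zero(self):
        h = M.build_histogram([123.0] * 100)
        assert M.entropy(h) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_is_one(self):
        h = M.PhaseHistogram(bin_deg=1.0, start_deg=0.0,
                             freq=np.full(360, 1.0 / 360.0), n_samples=360)
        assert M.entropy(h) == pytest.approx(1.0, abs=1e-12)

    def test_two_bin_split(self):
        freq = np.zeros(360)
        freq[[10, 200]] = 0.5
        h = M.PhaseHistogram(bin_deg=1.0, start_deg=0.0, freq=freq, n_samples=100)
        assert M.entropy(h) == pytest.approx(math.log(2) / math.log(360), abs=1e-12)

    def test_uniform_maximizes_over_random_histograms(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            f = rng.dirichlet(np.ones(360))
            h = M.PhaseHistogram(bin_deg=1.0, start_deg=0.0,
                                 freq=f / f.sum(), n_samples=100)
            assert M.entropy(h) <= 1.0 + 1e-12


class TestRotationInvariance:
    @pytest.mark.parametrize("delta", [13.0, 90.0, 187.5, 311.0])
    def test_metrics_invariant_under_global_rotation(self, delta):
        rng = np.random.default_rng(17)
        p = rng.normal(200.0, 20.0, size=300) % 360.0
        q = (p + delta) % 360.0
        assert M.psd(q) == pytest.approx(M.psd(p), abs=1e-6)
        assert M.bandwidth95(q) == pytest.approx(M.bandwidth95(p), abs=1e-6)
        e_p = M.entropy(M.build_histogram(p))
        e_q = M.entropy(M.build_histogram(q))
        # entropy shifts bins: exact invariance only for integer-degree deltas
        assert abs(e_p - e_q) < 0.02


class TestTesMetrics:
    def test_all_equal(self):
        t = M.tes_metrics([90.0] * 17)
        assert (t.mdtes_pct, t.sdtes_pct, t.dtes_ls_pct) == (0.0, 0.0, 0.0)

    def test_single_outlier_segment(self):
        tes = [90.0] * 17
        tes[0] = 126.0
        assert M.tes_metrics(tes).mdtes_pct == pytest.approx(10.0, abs=1e-9)

    def test_lateral_septal_contrast(self):
        tes = [90.0] * 17
        for s in M.LATERAL_SEGMENTS:
            tes[s - 1] = 100.8
        t = M.tes_metrics(tes)
        assert t.dtes_ls_pct == pytest.approx(3.0, abs=1e-9)

    def test_sign_flips_when_sets_swap(self):
        rng = np.random.default_rng(4)
        tes = (170.0 + rng.normal(0, 10, 17)) % 360.0
        a = M.tes_metrics(tes)
        b = M.tes_metrics(tes, lateral_ids=M.SEPTAL_SEGMENTS,
                          septal_ids=M.LATERAL_SEGMENTS)
        assert a.dtes_ls_pct == pytest.approx(-b.dtes_ls_pct, abs=1e-9)
        assert a.mdtes_pct == pytest.approx(b.mdtes_pct)

    def test_relabeling_invariance_of_spread(self):
        rng = np.random.default_rng(9)
        tes = (170.0 + rng.normal(0, 12, 17)) % 360.0
        perm = rng.permutation(17)
        a, b = M.tes_metrics(tes), M.tes_metrics(tes[perm])
        assert a.mdtes_pct == pytest.approx(b.mdtes_pct, abs=1e-9)
        assert a.sdtes_pct == pytest.approx(b.sdtes_pct, abs=1e-9)

    def test_wrap_safe_alignment(self):
        tes = [359.0] * 8 + [1.0] * 9
        assert M.tes_metrics(tes).mdtes_pct == pytest.approx(2.0 / 3.6, abs=1e-6)

    def test_missing_segment_rejected(self):
        with pytest.raises(M.MetricInputError):
            M.tes_metrics({s: 90.0 for s in range(1, 17)})


class TestNormalLimits:
    def test_table_style_row(self):
        # a 24.0 +/- 8.3 metric prints limits 7.4 / 40.6
        nl = M.NormalLimits(24.0, 8.3, 24.0 - 16.6, 24.0 + 16.6)
        rng = np.random.default_rng(0)
        v = rng.normal(0, 1, 200)
        v = (v - v.mean()) / v.std(ddof=1) * 8.3 + 24.0
        got = M.normal_limits(v)
        assert got.mean == pytest.approx(nl.mean, abs=1e-9)
        assert got.sd == pytest.approx(nl.sd, abs=1e-9)
        assert got.lower == pytest.approx(7.4, abs=1e-9)
        assert got.upper == pytest.approx(40.6, abs=1e-9)

    def test_constant_list(self):
        nl = M.normal_limits([3.0, 3.0, 3.0])
        assert (nl.mean, nl.sd, nl.lower, nl.upper) == (3.0, 0.0, 3.0, 3.0)

    def test_two_values(self):
        nl = M.normal_limits([0.0, 4.0])
        assert nl.sd == pytest.approx(math.sqrt(8.0), abs=1e-12)
        assert nl.lower == pytest.approx(2.0 - 2 * math.sqrt(8.0), abs=1e-12)
        assert nl.upper == pytest.approx(2.0 + 2 * math.sqrt(8.0), abs=1e-12)

    def test_needs_two(self):
        with pytest.raises(M.MetricInputError):
            M.normal_limits([1.0])
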