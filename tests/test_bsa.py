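"""Tests of the pooled-segregant Δf mapping statistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from flm_sweepmap.bsa import (
    DeltaFProfile,
    SmoothedProfile,
    SnpPoolRecord,
    analyze_pools,
    bootstrap_band,
    call_mapping_interval,
    compute_delta_f,
    compute_pool_frequency,
    filter_snps,
    loess_smooth,
    marker_frequency_scan,
)


def brute_force_loess(x, y, span=0.75, degree=2):
    """Independent tricube weighted-least-squares reference.

    Plain loops and numpy.polyfit on the (x - x0)-shifted predictor: for each
    point, take q = max(degree+1, ceil(span*n)) nearest neighbors, weight by
    tricube(d / d_q) (zero at and beyond the q-th distance), fit a degree-p
    polynomial by weighted least squares, evaluate at the point.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    q = min(n, max(degree + 1, int(np.ceil(span * n))))
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        dq = np.sort(d)[q - 1]
        if dq > 0:
            w = np.where(d < dq, (1 - (d / dq) ** 3) ** 3, 0.0)
        else:
            w = (d <= dq).astype(float)
        # polyfit minimizes sum (w_i * (y_i - f(x_i)))^2, so pass sqrt weights
        coeffs = np.polyfit(x - x[i], y, deg=degree, w=np.sqrt(w))
        out[i] = coeffs[-1]
    return out


def _toy_table(**overrides):
    base = dict(
        chrom="chr1", pos=100, ref="C", alt="T",
        depth_early=60, alt_early=30, depth_late=60, alt_late=30,
        parental_alt_freq=1.0, called_in_both=True,
    )
    base.update(overrides)
    return base


class TestPoolFrequency:
    def test_basic_division(self):
        table = pd.DataFrame([_toy_table(alt_early=30, depth_early=60)])
        fe, fl = compute_pool_frequency(table)
        assert fe[0] == 0.5

    def test_bounds(self):
        table = pd.DataFrame([
            _toy_table(alt_early=0, alt_late=60),
        ])
        fe, fl = compute_pool_frequency(table)
        assert fe[0] == 0.0 and fl[0] == 1.0

    def test_matches_elementwise_division(self, rng):
        depths = rng.integers(1, 100, size=20)
        alts = rng.integers(0, depths + 1)
        table = pd.DataFrame([
            _toy_table(pos=i, depth_early=int(d), alt_early=int(a))
            for i, (d, a) in enumerate(zip(depths, alts))
        ])
        fe, _ = compute_pool_frequency(table)
        np.testing.assert_allclose(fe, alts / depths)

    def test_zero_depth_raises(self):
        table = pd.DataFrame([_toy_table(depth_early=0, alt_early=0)])
        with pytest.raises(ValueError):
            compute_pool_frequency(table)


class TestRecordInvariants:
    def test_alt_exceeding_depth_rejected(self):
        with pytest.raises(ValueError):
            SnpPoolRecord("chr1", 1, "C", "T", 10, 11, 10, 5, 1.0, True)

    def test_parental_freq_bounds(self):
        with pytest.raises(ValueError):
            SnpPoolRecord("chr1", 1, "C", "T", 10, 5, 10, 5, 1.2, True)


class TestFilterSnps:
    def test_engineered_table_rejections(self):
        """Six records each violating one rule plus one clean record: one
        survivor, rejection counts (2 coverage, 1 frequency, 1 presence,
        1 parental) — hand enumeration."""
        rows = [
            _toy_table(pos=1, depth_early=29),                  # below coverage
            _toy_table(pos=2, depth_late=121),                  # above coverage
            _toy_table(pos=3, alt_early=10, alt_late=10),       # f = 1/6 both pools
            _toy_table(pos=4, called_in_both=False),            # presence
            _toy_table(pos=5, parental_alt_freq=0.5),           # parental
            _toy_table(pos=6),                                  # clean
        ]
        table = pd.DataFrame(rows)
        kept, report = filter_snps(table)
        assert len(kept) == 1 and kept["pos"].iloc[0] == 6
        assert report.counts == {"coverage": 2, "frequency": 1, "presence": 1, "parental": 1}
        assert report.first_failure[0] == "coverage"

    def test_boundaries_inclusive(self):
        table = pd.DataFrame([
            _toy_table(pos=1, depth_early=30, depth_late=120, alt_early=15, alt_late=60),
        ])
        kept, _ = filter_snps(table)
        assert len(kept) == 1

    def test_empty_input(self):
        kept, report = filter_snps(pd.DataFrame(columns=pd.DataFrame([_toy_table()]).columns))
        assert len(kept) == 0 and report.n_input == 0

    def test_idempotent_and_order_independent(self, rng):
        rows = [
            _toy_table(
                pos=i,
                depth_early=int(rng.integers(20, 140)),
                depth_late=int(rng.integers(20, 140)),
                alt_early=0, alt_late=0,
                called_in_both=bool(rng.integers(0, 2)),
                parental_alt_freq=float(rng.random()),
            )
            for i in range(30)
        ]
        for r in rows:
            r["alt_early"] = int(rng.integers(0, r["depth_early"] + 1))
            r["alt_late"] = int(rng.integers(0, r["depth_late"] + 1))
        table = pd.DataFrame(rows)
        once, _ = filter_snps(table)
        twice, rep2 = filter_snps(once)
        pd.testing.assert_frame_equal(once, twice)
        assert all(v == 0 for v in rep2.counts.values())
        shuffled = table.sample(frac=1, random_state=0)
        kept_shuffled, _ = filter_snps(shuffled)
        assert set(kept_shuffled["pos"]) == set(once["pos"])


class TestLoess:
    def test_constant_input_reproduced(self):
        x = np.arange(20.0)
        out = loess_smooth(x, np.full(20, 0.5))
        np.testing.assert_allclose(out, 0.5, atol=1e-12)

    @pytest.mark.parametrize("span", [0.3, 0.75, 1.0])
    def test_collinear_input_reproduced(self, span):
        x = np.linspace(0, 10, 30)
        y = 0.2 + 0.03 * x
        out = loess_smooth(x, y, span=span, degree=2)
        np.testing.assert_allclose(out, y, atol=1e-10)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 100))
            x = np.sort(rng.uniform(0, 100, size=n))
            y = rng.random(n)
            span = float(rng.uniform(0.3, 1.0))
            ours = loess_smooth(x, y, span=span, degree=2)
            ref = brute_force_loess(x, y, span=span, degree=2)
            np.testing.assert_allclose(ours, ref, atol=1e-8)

    @given(st.integers(0, 1000))
    def test_oracle_equivalence_property(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(8, 60))
        x = np.sort(r.uniform(0, 50, size=n))
        y = r.random(n)
        np.testing.assert_allclose(
            loess_smooth(x, y, span=0.5, degree=2),
            brute_force_loess(x, y, span=0.5, degree=2),
            atol=1e-8,
        )

    def test_duplicate_positions_allowed(self):
        x = np.array([0.0, 1.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([0.0, 1.0, 1.0, 2.0, 3.0, 4.0]) / 4
        out = loess_smooth(x, y, span=0.9, degree=1)
        assert np.all(np.isfinite(out))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            loess_smooth(np.array([1.0, 2.0]), np.array([0.1, 0.2]), degree=2)


class TestBootstrapBand:
    def test_zero_variance_gives_zero_width(self):
        x = np.arange(30.0)
        lo, hi = bootstrap_band(x, np.full(30, 0.4), n_boot=50, seed=1)
        np.testing.assert_allclose(lo, 0.4, atol=1e-12)
        np.testing.assert_allclose(hi, 0.4, atol=1e-12)

    def test_band_brackets_point_estimate(self, rng):
        x = np.sort(rng.uniform(0, 10, 40))
        y = 0.5 + 0.1 * np.sin(x) + rng.normal(0, 0.05, 40)
        fit = loess_smooth(x, y, span=0.6)
        lo, hi = bootstrap_band(x, y, span=0.6, n_boot=200, seed=2)
        inside = (lo - 1e-9 <= fit) & (fit <= hi + 1e-9)
        assert inside.mean() >= 0.95

    def test_nominal_coverage_of_true_curve(self):
        """A quadratic truth (reproduced exactly by degree-2 LOESS, so no
        smoothing bias) must fall inside the 95% band at >= 90% of positions
        on average over Monte-Carlo replications."""
        r = np.random.default_rng(99)
        x = np.linspace(0, 1, 50)
        truth = 0.4 + 0.3 * x - 0.2 * x**2
        hits = []
        for rep in range(40):
            y = truth + r.normal(0, 0.05, x.size)
            lo, hi = bootstrap_band(x, y, span=0.7, n_boot=100, seed=rep)
            hits.append(((lo <= truth) & (truth <= hi)).mean())
        assert np.mean(hits) >= 0.90

    def test_small_n_boot_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_band(np.arange(10.0), np.arange(10.0), n_boot=10)


class TestDeltaF:
    def _profile(self, pos, f):
        return SmoothedProfile(positions=np.asarray(pos, float), raw_f=np.asarray(f, float),
                               smooth_f=np.asarray(f, float))

    def test_identical_profiles_zero(self):
        p = self._profile([1, 2, 3], [0.3, 0.4, 0.5])
        q = self._profile([1, 2, 3], [0.3, 0.4, 0.5])
        np.testing.assert_allclose(compute_delta_f(p, q).delta_f, 0.0)

    def test_elementwise_subtraction(self, rng):
        pos = np.arange(25)
        a, b = rng.random(25), rng.random(25)
        d = compute_delta_f(self._profile(pos, a), self._profile(pos, b))
        np.testing.assert_allclose(d.delta_f, a - b)
        assert np.all(np.abs(d.delta_f) <= 1.0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_delta_f(self._profile([1, 2], [0.1, 0.2]), self._profile([1, 3], [0.1, 0.2]))


class TestIntervalCalling:
    def test_nothing_above_threshold(self):
        prof = DeltaFProfile(np.array([10, 20, 30]), np.array([0.1, 0.2, 0.25]))
        assert call_mapping_interval(prof, threshold=0.25) == []

    def test_single_run_with_peak(self):
        prof = DeltaFProfile(
            positions=np.array([10, 20, 30, 40, 50]),
            delta_f=np.array([0.1, 0.3, 0.4, 0.3, 0.1]),
        )
        (iv,) = call_mapping_interval(prof, threshold=0.25)
        assert (iv.start, iv.end, iv.peak_pos) == (20, 41, 30)
        assert iv.peak_delta == pytest.approx(0.4)

    def test_two_separate_runs_ordered(self):
        prof = DeltaFProfile(
            positions=np.arange(0, 90, 10),
            delta_f=np.array([0.3, 0.4, 0.1, 0.1, 0.5, 0.5, 0.1, 0.3, 0.2]),
        )
        ivs = call_mapping_interval(prof, threshold=0.25)
        assert [(iv.start, iv.end) for iv in ivs] == [(0, 11), (40, 51), (70, 71)]
        # leftmost tie-break for the flat 0.5 run
        assert ivs[1].peak_pos == 40


class TestMarkerScan:
    def test_fixed_group_frequency(self):
        ge = np.full((5, 3), 2)
        gl = np.zeros((5, 3), dtype=int)
        res = marker_frequency_scan(ge, gl, positions=[10, 20, 30])
        assert np.all(res["freq_early"] == 1.0)
        assert np.all(res["freq_late"] == 0.0)

    def test_identical_groups_p_one(self):
        g = np.tile([0, 1, 2, 1], (1, 1)).T @ np.ones((1, 2), dtype=int)
        res = marker_frequency_scan(g, g, positions=[1, 2])
        assert np.all(res["p_value"] == 1.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        """2x2 table (20,0 / 10,10): two-sided Fisher p from exhaustive
        hypergeometric enumeration of tables with the same margins."""
        ge = np.full((10, 1), 2)  # 20 alt, 0 ref
        gl = np.repeat([[2], [0]], [5, 5], axis=0)  # 10 alt, 10 ref
        res = marker_frequency_scan(ge, gl, positions=[0])
        # enumeration: margins rows (20,20), cols (30,10); feasible a in [10, 20]
        p_obs = stats.hypergeom.pmf(20, 40, 30, 20)
        p_exact = sum(
            stats.hypergeom.pmf(a, 40, 30, 20)
            for a in range(10, 21)
            if stats.hypergeom.pmf(a, 40, 30, 20) <= p_obs * (1 + 1e-9)
        )
        assert res["p_value"].iloc[0] == pytest.approx(p_exact, rel=1e-6)


class TestEndToEndScan:
    def test_peak_near_causal_locus(self):
        from flm_sweepmap.simulate import F2SimConfig, pool_and_count, simulate_f2_population

        cfg = F2SimConfig(seed=42)
        truth = simulate_f2_population(cfg)
        table = pool_and_count(truth, cfg)
        result = analyze_pools(table, prefiltered=True)
        assert result.intervals, "expected at least one interval at these conditions"
        best = max(result.intervals, key=lambda iv: iv.peak_delta)
        assert abs(best.peak_pos - truth.causal_pos) < 150_000
        assert np.all(np.abs(result.delta.delta_f) <= 1.0)
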