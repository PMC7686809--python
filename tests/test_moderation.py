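"""Moderated regression, simple slopes, Johnson-Neyman and BH-FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from msmod.datasets import creativity_moderation_family
from msmod.moderation import (
    BATTERY_ORDER,
    bh_adjust,
    correlation_table,
    exclude_outliers,
    johnson_neyman,
    moderated_regression,
    run_moderation_battery,
    simple_slopes,
)


def _cohort(n=200, b1=0.5, b2=1.0, b3=-0.4, sigma=5.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(80, 12, n)
    w = rng.normal(28.4, 2.8, n)
    sex = rng.integers(0, 2, n)
    age = rng.normal(18.3, 0.84, n)
    xc, wc = x - x.mean(), w - w.mean()
    y = 100 + b1 * xc + b2 * wc + b3 * xc * wc + 0.5 * sex + 0.2 * age
    y = y + rng.normal(0, sigma, n)
    cov = pd.DataFrame({"sex": sex, "age": age})
    return y, x, w, cov


class TestExcludeOutliers:
    def _table(self, wcts, rses):
        n = len(wcts)
        return pd.DataFrame(
            {
                "subject_id": [f"S{i:03d}" for i in range(n)],
                "wcts_total": wcts,
                "rses": rses,
            }
        )

    def test_planted_outlier_removed(self):
        rng = np.random.default_rng(0)
        wcts = rng.normal(100, 10, 101)
        wcts[100] = wcts[:100].mean() + 4 * wcts[:100].std()
        rses = rng.normal(28, 3, 101)
        kept, excluded = exclude_outliers(self._table(wcts, rses))
        assert excluded == ["S100"]
        assert len(kept) == 100

    def test_no_outliers_noop(self):
        rng = np.random.default_rng(1)
        table = self._table(rng.uniform(90, 110, 50), rng.uniform(25, 31, 50))
        kept, excluded = exclude_outliers(table)
        assert excluded == []
        pd.testing.assert_frame_equal(kept, table)

    def test_hand_arithmetic_on_small_table(self):
        wcts = [100.0, 102, 98, 101, 99, 100, 103, 97, 100, 101, 99, 160]
        rses = [28.0] * 11 + [29.0]
        arr = np.array(wcts)
        assert abs(160 - arr.mean()) > 3 * arr.std(ddof=1)  # the planted one
        kept, excluded = exclude_outliers(self._table(wcts, rses + []))
        assert excluded == ["S011"]
        assert len(kept) == 11

    def test_too_few_rows_after_exclusion(self):
        table = self._table([100.0] * 5 + [200.0], [28.0] * 6)
        with pytest.raises(ValueError):
            exclude_outliers(table)


class TestCorrelationTable:
    def test_perfect_linearity(self):
        x = np.arange(20, dtype=float)
        table = pd.DataFrame(
            {"rses": x, "wcts_total": 2 * x, "risk_taking": x, "curiosity": x,
             "imagination": x, "challenge": x}
        )
        out = correlation_table(table)
        assert np.allclose(out["r"], 1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(2, 50))
        t1 = pd.DataFrame({"rses": a, "wcts_total": b})
        t2 = pd.DataFrame({"rses": b, "wcts_total": a})
        r1 = correlation_table(t1, x_cols=("wcts_total",))["r"][0]
        r2 = correlation_table(t2, x_cols=("wcts_total",))["r"][0]
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_independent_draws_near_zero(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(
            {"rses": rng.normal(size=10_000), "wcts_total": rng.normal(size=10_000)}
        )
        out = correlation_table(table, x_cols=("wcts_total",))
        assert abs(out["r"][0]) < 0.05

    def test_zero_variance_rejected(self):
        table = pd.DataFrame({"rses": np.ones(10), "wcts_total": np.arange(10.0)})
        with pytest.raises(ValueError):
            correlation_table(table, x_cols=("wcts_total",))


def _normal_equations_oracle(y, x, w, cov):
    """Independent brute-force OLS via the normal equations."""
    xc, wc = x - x.mean(), w - w.mean()
    X = np.column_stack([np.ones(y.size), xc, wc, xc * wc, *cov.to_numpy().T])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    df = y.size - X.shape[1]
    sigma2 = resid @ resid / df
    covb = sigma2 * np.linalg.inv(X.T @ X)
    tss = np.sum((y - y.mean()) ** 2)
    r2 = 1 - resid @ resid / tss
    return beta, covb, r2


class TestModeratedRegression:
    def test_matches_normal_equations_oracle(self):
        for seed in range(30):
            y, x, w, cov = _cohort(n=80, seed=seed)
            res = moderated_regression(y, x, w, cov)
            beta, covb, r2 = _normal_equations_oracle(y, x, w, cov)
            np.testing.assert_allclose(res.params, beta, atol=1e-8)
            np.testing.assert_allclose(res.cov, covb, atol=1e-8)
            assert res.r2_full == pytest.approx(r2, abs=1e-10)

    def test_noiseless_coefficients_recovered_exactly(self):
        y, x, w, cov = _cohort(n=60, b1=0.7, b2=-1.2, b3=0.25, sigma=0.0, seed=4)
        res = moderated_regression(y, x, w, cov)
        np.testing.assert_allclose(
            res.params[1:4], [0.7, -1.2, 0.25], atol=1e-8
        )
        assert res.r2_full == pytest.approx(1.0, abs=1e-10)

    def test_f_delta_r2_identity(self):
        y, x, w, cov = _cohort(seed=5)
        res = moderated_regression(y, x, w, cov)
        assert res.delta_r2 == pytest.approx(res.r2_full - res.r2_reduced, abs=1e-12)
        assert res.delta_r2 >= 0
        assert res.f_value == pytest.approx(
            res.delta_r2 * res.df2 / (1 - res.r2_full), abs=1e-10
        )
        assert res.df2 == res.n - 6

    def test_null_interaction_delta_r2_small(self):
        y, x, w, cov = _cohort(n=5000, b3=0.0, seed=6)
        res = moderated_regression(y, x, w, cov)
        assert res.delta_r2 < 0.01

    def test_rank_deficient_design_named(self):
        y, x, w, cov = _cohort(n=50, seed=7)
        cov = cov.copy()
        cov["dup"] = cov["age"]
        with pytest.raises(ValueError, match="age|dup"):
            moderated_regression(y, x, w, cov)


class TestSimpleSlopes:
    def test_no_interaction_constant_slope(self):
        y, x, w, cov = _cohort(n=500, b3=0.0, sigma=0.0, seed=8)
        res = moderated_regression(y, x, w, cov)
        slopes = simple_slopes(res, probe_points=np.array([-3.0, 0.0, 3.0]))
        vals = [s.slope for s in slopes]
        assert np.allclose(vals, vals[0], atol=1e-8)

    def test_slope_arithmetic(self):
        y, x, w, cov = _cohort(seed=9)
        res = moderated_regression(y, x, w, cov)
        res.params[1], res.params[3] = 0.5, 0.2
        s = simple_slopes(res, probe_points=np.array([2.0]))[0]
        assert s.slope == pytest.approx(0.5 + 0.2 * 2.0)

    def test_se_matches_recentering_oracle(self):
        """SE at a probe equals the X-coefficient SE after re-centering W
        at that probe and refitting."""
        import statsmodels.api as sm

        y, x, w, cov = _cohort(n=120, seed=10)
        res = moderated_regression(y, x, w, cov)
        for probe in (-2.8, 0.0, 2.8):
            slopes = simple_slopes(res, probe_points=np.array([probe]))
            xc = x - x.mean()
            wshift = (w - w.mean()) - probe
            X = np.column_stack(
                [np.ones(y.size), xc, wshift, xc * wshift, *cov.to_numpy().T]
            )
            fit = sm.OLS(y, X).fit()
            assert slopes[0].slope == pytest.approx(fit.params[1], abs=1e-8)
            assert slopes[0].se == pytest.approx(fit.bse[1], abs=1e-8)

    def test_default_probes_are_plus_minus_one_sd(self):
        y, x, w, cov = _cohort(seed=11)
        res = moderated_regression(y, x, w, cov)
        slopes = simple_slopes(res)
        assert slopes[0].w_centered == pytest.approx(-res.w_sd)
        assert slopes[1].w_centered == pytest.approx(res.w_sd)


def _grid_oracle(res, n_grid=10_001):
    """Significance mask of the simple slope on a dense moderator grid."""
    from scipy import stats as sstats

    lo, hi = res.w_values.min() - res.w_mean, res.w_values.max() - res.w_mean
    grid = np.linspace(lo, hi, n_grid)
    b1, b3 = res.params[1], res.params[3]
    s11, s13, s33 = res.cov[1, 1], res.cov[1, 3], res.cov[3, 3]
    slope = b1 + b3 * grid
    se = np.sqrt(s11 + 2 * grid * s13 + grid**2 * s33)
    t_crit = sstats.t.ppf(1 - res.alpha / 2, res.df2)
    sig = np.abs(slope / se) > t_crit
    changes = np.flatnonzero(np.diff(sig.astype(int)))
    return grid, sig, grid[changes]  # boundary between grid[i], grid[i+1]


class TestJohnsonNeyman:
    def test_no_interaction_significant_b1_everywhere(self):
        y, x, w, cov = _cohort(n=400, b1=2.0, b3=0.0, sigma=1.0, seed=12)
        res = moderated_regression(y, x, w, cov)
        res.params[3] = 0.0  # exact null interaction
        jn = johnson_neyman(res)
        assert jn.region == "everywhere"

    def test_no_interaction_null_b1_nowhere(self):
        y, x, w, cov = _cohort(n=400, b1=0.0, b3=0.0, sigma=50.0, seed=13)
        res = moderated_regression(y, x, w, cov)
        res.params[1] = 0.0
        res.params[3] = 0.0
        jn = johnson_neyman(res)
        assert jn.region == "nowhere"

    def test_boundaries_match_grid_oracle(self):
        rng = np.random.default_rng(14)
        n_checked = 0
        for trial in range(100):
            y, x, w, cov = _cohort(
                n=150,
                b1=rng.normal(0, 0.3),
                b3=rng.normal(0, 0.15),
                sigma=rng.uniform(3, 12),
                seed=1000 + trial,
            )
            res = moderated_regression(y, x, w, cov)
            jn = johnson_neyman(res)
            grid, sig, crossings = _grid_oracle(res)
            step = grid[1] - grid[0]
            analytic = [
                b - res.w_mean
                for b in (jn.lower, jn.upper)
                if b is not None
            ]
            assert len(analytic) == len(crossings)
            for a, g in zip(sorted(analytic), crossings):
                assert abs(a - g) <= step
            n_checked += len(crossings)
        assert n_checked > 0  # the sweep actually exercised boundaries

    def test_boundaries_invariant_to_w_centering(self):
        y, x, w, cov = _cohort(n=300, b1=0.1, b3=-0.3, sigma=4.0, seed=15)
        res_raw = moderated_regression(y, x, w, cov)
        res_cen = moderated_regression(y, x, w - w.mean(), cov)
        jn_raw = johnson_neyman(res_raw)
        jn_cen = johnson_neyman(res_cen)
        for a, b in [(jn_raw.lower, jn_cen.lower), (jn_raw.upper, jn_cen.upper)]:
            if a is None:
                assert b is None
            else:
                assert a == pytest.approx(b + w.mean(), abs=1e-8)

    def test_boundary_satisfies_critical_t(self):
        from scipy import stats as sstats

        y, x, w, cov = _cohort(n=300, b1=0.1, b3=-0.3, sigma=4.0, seed=16)
        res = moderated_regression(y, x, w, cov)
        jn = johnson_neyman(res)
        t_crit = sstats.t.ppf(1 - res.alpha / 2, res.df2)
        for bound in (jn.lower, jn.upper):
            if bound is None:
                continue
            wc = bound - res.w_mean
            b1, b3 = res.params[1], res.params[3]
            se = np.sqrt(
                res.cov[1, 1] + 2 * wc * res.cov[1, 3] + wc**2 * res.cov[3, 3]
            )
            assert abs(abs(b1 + b3 * wc) / se - t_crit) < 1e-8


def _bh_brute_force(p):
    """Direct step-up definition: adjusted_(i) = min_{j>=i} p_(j)*m/j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj = np.empty(m)
    for i in range(m):
        adj[i] = min(min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


class TestBHAdjust:
    def test_published_family_reproduced(self):
        fam = creativity_moderation_family()
        adj = bh_adjust(fam["p_uncorrected"].to_numpy())
        got = dict(zip(fam["parameter"], np.round(adj, 3)))
        assert got["contribution_ms2"] == pytest.approx(0.024)
        assert got["occurrence_ms3"] == pytest.approx(0.030)
        assert got["transition_ms2_ms4"] == pytest.approx(0.030)
        assert got["occurrence_ms1"] == pytest.approx(0.082)

    def test_all_equal_p_unchanged(self):
        p = np.full(24, 0.03)
        assert np.allclose(bh_adjust(p), 0.03)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 30))
        np.testing.assert_allclose(bh_adjust(p), _bh_brute_force(p), atol=1e-12)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            p = rng.uniform(size=24)
            ours = bh_adjust(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _battery_tables(n=300, b3=-0.06, seed=0):
    from msmod.config import CohortConfig, SimulationConfig
    from msmod.synthetic import simulate_cohort

    sim = SimulationConfig(n_channels=8, sampling_rate=100.0, record_duration=10.0)
    cohort = CohortConfig(
        n_subjects=n, effect_map=[("duration_ms2", 0.0, 1.0, b3)], seed=seed
    )
    beh, _, truth = simulate_cohort(sim, cohort, with_eeg=False)
    return truth.subject_parameters, beh


class TestBattery:
    def test_report_shape_and_order(self):
        stats, beh = _battery_tables(n=60)
        report, results = run_moderation_battery(stats, beh)
        assert len(report) == 24
        assert report["parameter"].tolist() == BATTERY_ORDER
        assert len(results) == 24

    def test_planted_interaction_detected(self):
        stats, beh = _battery_tables(n=335, b3=-0.1, seed=3)
        report, results = run_moderation_battery(stats, beh)
        row = report[report["parameter"] == "duration_ms2"].iloc[0]
        assert row["p_fdr"] < 0.05
        res = results["duration_ms2"]
        assert res.slopes and res.jn is not None

    def test_disordinal_crossover_slope_signs(self):
        """Negative planted b3 with null main effect: positive simple slope
        at low self-esteem, negative at high."""
        stats, beh = _battery_tables(n=335, b3=-0.15, seed=4)
        _, results = run_moderation_battery(stats, beh)
        res = results["duration_ms2"]
        lo, hi = res.slopes
        assert lo.slope > 0 > hi.slope
        assert lo.p < 0.05 and hi.p < 0.05
        assert res.jn.slope_sign_below == 1
        assert res.jn.slope_sign_above == -1

    def test_misaligned_ids_rejected(self):
        stats, beh = _battery_tables(n=30)
        beh = beh.copy()
        beh.loc[0, "subject_id"] = "WRONG"
        with pytest.raises(ValueError, match="subject ids"):
            run_moderation_battery(stats, beh)
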