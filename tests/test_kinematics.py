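import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from flukeprints.errors import (
    DegenerateFitError,
    InsufficientDataError,
    InvalidInputError,
)
from flukeprints.kinematics import (
    FlukeprintSequence,
    TrackedPositions,
    agreement_stats,
    deming_regression,
    icc_a1,
    pair_events,
    rgb_track_speed,
    tir_spacing_speed,
)


def track(t, x, y, wid="w0", eid=0):
    return TrackedPositions(wid, eid, np.asarray(t), np.asarray(x), np.asarray(y))


def seq(pid, t, x, y, wid="w0", eid=0):
    return FlukeprintSequence(
        wid, eid, np.asarray(pid), np.asarray(t), np.asarray(x), np.asarray(y)
    )


def pairs_frame(rgb, tir):
    return pd.DataFrame(
        {
            "whale_id": [f"w{i}" for i in range(len(rgb))],
            "event_id": 0,
            "rgb_speed_m_s": rgb,
            "tir_speed_m_s": tir,
        }
    )


class TestTrackSpeed:
    def test_three_four_five_triangle(self):
        est = rgb_track_speed(track([0.0, 1.0], [0.0, 3.0], [0.0, 4.0]))
        assert est.mean_speed_m_s == pytest.approx(5.0)
        assert est.n_increments == 1

    def test_stationary_track(self):
        est = rgb_track_speed(track([0, 1, 2], [1, 1, 1], [2, 2, 2]))
        assert est.mean_speed_m_s == 0.0

    def test_constant_speed_reference_vessel(self):
        # A straight 4.1 m/s track sampled at 30 Hz recovers exactly 4.1.
        t = np.arange(90) / 30.0
        est = rgb_track_speed(track(t, 4.1 * t * math.cos(0.3), 4.1 * t * math.sin(0.3)))
        assert est.mean_speed_m_s == pytest.approx(4.1, rel=1e-9)

    def test_too_few_positions(self):
        with pytest.raises(InsufficientDataError):
            rgb_track_speed(track([0.0], [0.0], [0.0]))

    def test_rigid_motion_invariance(self):
        t = [0.0, 0.7, 1.9]
        x = np.array([0.0, 1.0, 2.5])
        y = np.array([0.0, 0.4, 1.1])
        base = rgb_track_speed(track(t, x, y)).mean_speed_m_s
        th = 1.1
        xr = 5.0 + x * math.cos(th) - y * math.sin(th)
        yr = -3.0 + x * math.sin(th) + y * math.cos(th)
        assert rgb_track_speed(track(t, xr, yr)).mean_speed_m_s == pytest.approx(
            base, rel=1e-12
        )


class TestSpacingSpeed:
    def test_single_increment(self):
        est = tir_spacing_speed(seq([0, 1], [0.0, 5.0], [0.0, 10.0], [0.0, 0.0]))
        assert est.mean_speed_m_s == pytest.approx(2.0)
        assert est.mean_spacing_m == pytest.approx(10.0)

    def test_mean_over_increments(self):
        est = tir_spacing_speed(
            seq([0, 1, 2], [0.0, 5.0, 10.0], [0.0, 8.0, 20.0], [0.0, 0.0, 0.0])
        )
        assert est.mean_speed_m_s == pytest.approx(2.0)  # (8/5 + 12/5) / 2
        assert est.mean_spacing_m == pytest.approx(10.0)
        assert est.n_increments == 2

    def test_gap_in_print_ids_excluded(self):
        est = tir_spacing_speed(
            seq([0, 1, 5], [0.0, 5.0, 30.0], [0.0, 8.0, 100.0], [0.0, 0.0, 0.0])
        )
        assert est.n_increments == 1
        assert est.mean_speed_m_s == pytest.approx(8.0 / 5.0)

    def test_too_few_prints_and_bad_timestamps(self):
        with pytest.raises(InsufficientDataError):
            tir_spacing_speed(seq([0], [0.0], [0.0], [0.0]))
        with pytest.raises(InvalidInputError):
            tir_spacing_speed(seq([0, 1], [5.0, 5.0], [0.0, 8.0], [0.0, 0.0]))


class TestPairing:
    def test_inner_join_on_shared_keys(self):
        rgb = [
            rgb_track_speed(track([0, 1], [0, 1], [0, 0], wid=w, eid=e))
            for w, e in [("a", 0), ("a", 1), ("b", 0), ("c", 0), ("d", 0)]
        ]
        tir = [
            tir_spacing_speed(seq([0, 1], [0, 5], [0, 10], [0, 0], wid=w, eid=e))
            for w, e in [("a", 0), ("a", 1), ("b", 0), ("x", 0), ("y", 0)]
        ]
        assert len(pair_events(rgb, tir)) == 3

    def test_duplicate_keys_rejected(self):
        est = rgb_track_speed(track([0, 1], [0, 1], [0, 0]))
        tir = tir_spacing_speed(seq([0, 1], [0, 5], [0, 10], [0, 0]))
        with pytest.raises(InvalidInputError):
            pair_events([est, est], [tir])

    def test_disjoint_keys_give_empty_table(self):
        rgb = [rgb_track_speed(track([0, 1], [0, 1], [0, 0], wid="a"))]
        tir = [tir_spacing_speed(seq([0, 1], [0, 5], [0, 10], [0, 0], wid="b"))]
        assert len(pair_events(rgb, tir)) == 0


class TestAgreement:
    def test_identical_pairs(self):
        v = [1.1, 1.5, 0.9, 1.3]
        rep = agreement_stats(pairs_frame(v, v))
        assert rep.bias_m_s == 0.0
        assert rep.loa_low == rep.loa_high == 0.0
        assert rep.rmse_m_s == 0.0
        assert rep.icc_a1 == pytest.approx(1.0)
        assert rep.pct_within_half == 100.0
        assert rep.pct_within_one == 100.0

    def test_constant_offset_penalised_by_absolute_agreement(self):
        rgb = np.array([1.0, 1.5, 2.0, 2.5])
        tir = rgb - 0.5
        rep = agreement_stats(pairs_frame(rgb, tir))
        assert rep.bias_m_s == pytest.approx(0.5)
        assert rep.loa_low == pytest.approx(rep.loa_high)  # zero-SD differences
        assert rep.icc_a1 < 1.0
        # Hand-computed two-way ANOVA oracle for ICC(A,1).
        data = np.column_stack([rgb, tir])
        n, k = data.shape
        msr = k * np.sum((data.mean(1) - data.mean()) ** 2) / (n - 1)
        msc = n * np.sum((data.mean(0) - data.mean()) ** 2) / (k - 1)
        mse = (
            np.sum((data - data.mean(1)[:, None] - data.mean(0)[None, :] + data.mean()) ** 2)
            / ((n - 1) * (k - 1))
        )
        expected = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
        assert rep.icc_a1 == pytest.approx(expected, abs=1e-12)

    def test_small_table_against_spreadsheet_recomputation(self):
        rgb = np.array([1.0, 2.0, 1.5])
        tir = np.array([1.2, 1.9, 1.4])
        rep = agreement_stats(pairs_frame(rgb, tir))
        d = rgb - tir
        assert rep.bias_m_s == pytest.approx(d.mean())
        sd = d.std(ddof=1)
        assert rep.loa_low == pytest.approx(d.mean() - 1.96 * sd)
        assert rep.loa_high == pytest.approx(d.mean() + 1.96 * sd)
        assert rep.rmse_m_s == pytest.approx(np.sqrt(np.mean(d**2)))
        assert rep.mae_m_s == pytest.approx(np.mean(np.abs(d)))
        assert rep.nrmse == pytest.approx(np.sqrt(np.mean(d**2)) / rgb.mean())
        ape = np.abs(d / rgb) * 100
        assert rep.mape_pct == pytest.approx(ape.mean())
        assert rep.median_mape_pct == pytest.approx(np.median(ape))
        t, p = stats.ttest_rel(rgb, tir)
        assert rep.paired_t == pytest.approx(t)
        assert rep.paired_t_p == pytest.approx(p)
        lr = stats.linregress((rgb + tir) / 2, d)
        assert rep.prop_bias_slope == pytest.approx(lr.slope)

    def test_role_swap_symmetry(self):
        rng = np.random.default_rng(0)
        rgb = rng.uniform(0.8, 1.6, 12)
        tir = rgb + rng.normal(0, 0.2, 12)
        a = agreement_stats(pairs_frame(rgb, tir))
        b = agreement_stats(pairs_frame(tir, rgb))
        assert b.bias_m_s == pytest.approx(-a.bias_m_s)
        assert b.prop_bias_slope == pytest.approx(-a.prop_bias_slope)
        assert b.rmse_m_s == pytest.approx(a.rmse_m_s)
        assert b.mae_m_s == pytest.approx(a.mae_m_s)
        assert b.icc_a1 == pytest.approx(a.icc_a1)

    def test_mae_never_exceeds_rmse(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            rgb = rng.uniform(0.5, 2.0, 8)
            tir = rgb + rng.normal(0, 0.3, 8)
            rep = agreement_stats(pairs_frame(rgb, tir))
            assert rep.mae_m_s <= rep.rmse_m_s + 1e-12


class TestICCOracle:
    def test_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        x = rng.uniform(0.8, 1.6, 15)
        y = x + rng.normal(0, 0.2, 15)
        icc, ci = icc_a1(x, y)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(15), 2),
                "rater": np.tile(["A", "B"], 15),
                "score": np.column_stack([x, y]).ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        row = ref.loc["ICC(A,1)"]
        assert icc == pytest.approx(row["ICC"], abs=1e-9)
        lo, hi = row["CI95"]  # pingouin rounds its CI to two decimals
        assert ci[0] == pytest.approx(lo, abs=6e-3)
        assert ci[1] == pytest.approx(hi, abs=6e-3)


class TestDeming:
    def test_identity_line(self):
        x = np.array([0.5, 1.0, 1.5, 2.0, 2.5])
        fit = deming_regression(x, x)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_affine_line(self):
        x = np.array([0.5, 1.0, 1.5, 2.0, 2.5])
        fit = deming_regression(x, 2.0 * x + 1.0)
        assert fit.slope == pytest.approx(2.0, abs=1e-10)
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)

    def test_zero_covariance_degenerate(self):
        x = np.array([1.0, 1.0, 2.0, 2.0])
        y = np.array([1.0, 2.0, 1.0, 2.0])
        with pytest.raises(DegenerateFitError):
            deming_regression(x, y)

    def test_matches_orthogonal_distance_grid_search(self):
        rng = np.random.default_rng(3)
        true = rng.uniform(1, 3, 40)
        x = true + rng.normal(0, 0.15, 40)
        y = 1.3 * true + 0.2 + rng.normal(0, 0.15, 40)
        fit = deming_regression(x, y, lam=1.0)

        def loss(b):
            a = y.mean() - b * x.mean()  # intercept profiled out at fixed slope
            return np.sum((y - a - b * x) ** 2) / (1.0 + b**2)

        grid = np.linspace(fit.slope - 0.5, fit.slope + 0.5, 20001)
        best = grid[int(np.argmin([loss(b) for b in grid]))]
        assert fit.slope == pytest.approx(best, abs=1e-3)
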