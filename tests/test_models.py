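import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.signal import lfilter

import mobilegam
from mobilegam import geometry
from mobilegam.models import (ARStructure, _series_groups, fit_additive,
                              fit_ar, fit_discretized, fit_timetrend,
                              predict_distance_curve, select_ar_order,
                              sensitivity_suite)
from mobilegam.smoothers import build_univariate_basis, fit_penalized


def _ar_series(rng, phi, n, sd=1.0):
    phi = np.atleast_1d(phi)
    e = rng.normal(0, sd, n + 200)
    return lfilter([1.0], np.concatenate([[1.0], -phi]), e)[200:]


class TestARStructure:
    def test_stationarity_enforced(self):
        with pytest.raises(ValueError, match="stationary"):
            ARStructure(1, [1.01], 1.0)

    def test_phi_length_checked(self):
        with pytest.raises(ValueError, match="length"):
            ARStructure(2, [0.5], 1.0)


class TestSelectAROrder:
    def _groups(self, rng, phi, n_groups=15, length=330):
        return [_ar_series(rng, phi, length) for _ in range(n_groups)]

    def test_white_noise_selects_order_zero(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            ar = select_ar_order(self._groups(rng, []), p_max=5)
            hits += ar.order == 0
        assert hits >= 27  # >= 90% of seeds at n ~ 5,000

    def test_ar1_recovered_with_phi(self):
        rng = np.random.default_rng(1)
        ar = select_ar_order(self._groups(rng, [0.6]), p_max=5)
        assert ar.order == 1
        assert ar.phi[0] == pytest.approx(0.6, abs=0.05)

    def test_ar3_preset_structure_recovered(self):
        phi = np.array([0.35, 0.20, 0.15])  # the fine-particle preset truth
        rng = np.random.default_rng(2)
        ar = select_ar_order(self._groups(rng, phi), p_max=5)
        assert ar.order == 3
        assert np.allclose(ar.phi, phi, atol=0.07)

    def test_short_series_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="shorter"):
            select_ar_order([rng.normal(size=8)], p_max=5)

    def test_innovation_variance_positive(self):
        rng = np.random.default_rng(4)
        ar = select_ar_order(self._groups(rng, [0.5]), p_max=3)
        assert ar.sigma2 > 0


class TestAdditive:
    def test_null_decay_gives_flat_curves_on_average(self):
        """No distance effect in truth: per-campaign estimates scatter
        around zero and their mean is near zero."""
        cfg = mobilegam.preset("null_decay")
        cfg.n_shifts = 3
        vals = []
        for seed in [21, 22, 23]:
            c = mobilegam.generate_campaign(cfg, seed=seed)
            frame, _ = mobilegam.assemble_frame(
                c.observations, c.traffic, c.weather, c.sessions, c.roads,
                "ufp")
            res = fit_ar(frame)
            vals += [res.curves[rid].pct_decrease_100m for rid in ["bqe", "wb"]]
        assert np.all(np.abs(vals) < 14.0)
        assert abs(np.mean(vals)) < 5.0

    def test_single_day_drops_day_dummies(self, small_ufp_frame):
        mask = (small_ufp_frame.data["day_id"] ==
                small_ufp_frame.data["day_id"].iloc[0]).to_numpy()
        res = fit_additive(small_ufp_frame.subset(mask))
        assert not any(n.startswith("day[") for n in res.fit.param_names)

    def test_table_covers_model_terms(self, small_ufp_frame):
        res = fit_additive(small_ufp_frame)
        terms = set(res.table["term"])
        assert {"traffic_wb", "traffic_bqe", "wind_speed", "temperature",
                "rh", "f_wb", "f_bqe", "f_s", "r2"} <= terms


class TestFitAR:
    def test_recovers_injected_ar1(self, midsize_ufp):
        _, frame = midsize_ufp
        res = fit_ar(frame)
        assert res.ar.order == 1
        assert res.ar.phi[0] == pytest.approx(0.6, abs=0.08)

    def test_independent_noise_matches_additive_within_one_se(self):
        cfg = mobilegam.preset("ufp_default")
        cfg.n_shifts = 3
        cfg.ar_phi = ()
        c = mobilegam.generate_campaign(cfg, seed=31)
        frame, _ = mobilegam.assemble_frame(
            c.observations, c.traffic, c.weather, c.sessions, c.roads, "ufp")
        r_add = fit_additive(frame)
        r_ar = fit_ar(frame)
        for name in ["wind_speed", "temperature", "rh"]:
            est_a, lo_a, hi_a = r_add.coefficient_ci(name)
            est_r, _, _ = r_ar.coefficient_ci(name)
            se = (hi_a - lo_a) / (2 * 1.96)
            assert abs(est_a - est_r) < se

    def test_wind_coefficient_recovery(self, midsize_ufp):
        c, frame = midsize_ufp
        res = fit_ar(frame)
        truth = c.truth["betas"]["wind_speed"]
        est, lo, hi = res.coefficient_ci("wind_speed")
        assert abs(est - truth) < 3 * (hi - lo) / (2 * 1.96)


class TestTimetrend:
    def test_single_shift_rejected(self, small_ufp_frame):
        mask = (small_ufp_frame.data["shift_id"] ==
                small_ufp_frame.data["shift_id"].iloc[0]).to_numpy()
        with pytest.raises(ValueError, match="2 shifts"):
            fit_timetrend(small_ufp_frame.subset(mask))

    def test_no_trend_truth_agrees_with_ar_model(self):
        cfg = mobilegam.preset("ufp_default")
        cfg.n_shifts = 3
        cfg.trend_amplitude = 0.0
        c = mobilegam.generate_campaign(cfg, seed=41)
        frame, _ = mobilegam.assemble_frame(
            c.observations, c.traffic, c.weather, c.sessions, c.roads, "ufp")
        r_ar = fit_ar(frame)
        r_tt = fit_timetrend(frame)
        est_a, lo, hi = r_ar.coefficient_ci("wind_speed")
        se = (hi - lo) / (2 * 1.96)
        assert abs(r_tt.coefficient("wind_speed") - est_a) < 2 * se
        assert any(n.startswith("shift[") for n in r_tt.fit.param_names)

    def test_shift_effects_replace_day_dummies(self, small_ufp_frame):
        res = fit_timetrend(small_ufp_frame)
        assert not any(n.startswith("day[") for n in res.fit.param_names)
        assert "f_t" in res.fit.slices


class TestDiscretized:
    def test_single_segment_reduces_to_point_source_smooth(self, small_ufp_frame):
        frame = small_ufp_frame
        seg = geometry.SegmentedSource(
            "bqe", midpoints=np.array([[0.0, 400.0]]), lengths=np.array([10.0]),
            heights=np.array([0.0]), weights=np.array([1.0]))
        res = fit_discretized(frame, segmented={"bqe": seg})
        # direct fit: same mean structure with a distance smooth to the point
        d = np.hypot(frame.data["easting"] - 0.0, frame.data["northing"] - 400.0)
        y = frame.data["y"].to_numpy()
        from mobilegam.models import _parametric_design
        from mobilegam.smoothers import build_spatial_basis
        X, names = _parametric_design(frame)
        sm = build_univariate_basis(d.to_numpy(), k=10, name="g",
                                    transform="log")
        fs = build_spatial_basis(frame.coords, k=30, name="f_s", affine="shrink")
        direct = fit_penalized(y, X, [sm, fs], param_names=names,
                               lambdas=res.fit.lambdas)
        assert np.abs(direct.beta - res.fit.beta).max() < 1e-6

    def test_doubling_weights_leaves_fit_invariant(self, small_ufp_frame):
        road = geometry.RoadSource("bqe", [(0, -100), (0, 900)], [0, 0])
        seg = geometry.discretize_road(road, 10.0)
        s1 = seg.with_weights(np.ones(seg.n_segments))
        s2 = seg.with_weights(2.0 * np.ones(seg.n_segments))
        r1 = fit_discretized(small_ufp_frame, segmented={"bqe": s1})
        r2 = fit_discretized(small_ufp_frame, segmented={"bqe": s2})
        assert np.allclose(r1.fit.fitted, r2.fit.fitted, atol=1e-8)

    def test_zero_weights_drops_pooled_term(self, small_ufp_frame):
        road = geometry.RoadSource("bqe", [(0, -100), (0, 900)], [0, 0])
        seg = geometry.discretize_road(road, 10.0)
        with pytest.warns(UserWarning, match="zero"):
            res = fit_discretized(small_ufp_frame,
                                  segmented={"bqe": seg})
        assert "g" not in res.fit.slices


class TestDistanceCurve:
    def test_flat_smooth_gives_zero_percent(self, small_ufp_frame):
        res = fit_additive(small_ufp_frame)
        sl = res.fit.slices["f_bqe"]
        res.fit.beta[sl] = 0.0
        for sm in res.fit.smooths:
            if sm.name == "f_bqe":
                sm.coef = np.zeros_like(sm.coef)
        curve = predict_distance_curve(res, "bqe")
        assert curve.pct_decrease_100m == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(curve.eta, 0.0)

    def test_log08_maps_to_twenty_percent(self):
        # algebraic identity of the percent-decrease definition
        eta_diff = np.log(0.8)
        assert 100 * (1 - np.exp(eta_diff)) == pytest.approx(20.0)

    def test_reference_point_is_zero_and_ci_contains_eta(self, small_ufp_frame):
        res = fit_additive(small_ufp_frame)
        curve = res.curves["bqe"]
        assert curve.eta[0] == 0.0
        assert np.all(curve.lo95 <= curve.eta + 1e-12)
        assert np.all(curve.hi95 >= curve.eta - 1e-12)

    def test_out_of_range_grid_truncated(self, small_ufp_frame):
        res = fit_additive(small_ufp_frame)
        with pytest.warns(UserWarning, match="truncated"):
            curve = predict_distance_curve(res, "bqe",
                                           grid=np.array([1e4, 2e4, 50.0, 100.0]))
        assert curve.grid.max() <= small_ufp_frame.data["d_bqe"].max() + 1e-9


class TestSensitivity:
    def test_vehicle_class_leaves_r2_close(self, midsize_ufp):
        _, frame = midsize_ufp
        base = fit_ar(frame)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = sensitivity_suite(frame, which="vehicle_class")
        assert abs(out["fits"]["vehicle_class"].r2 - base.r2) < 0.02

    def test_single_road_models_fit(self, midsize_ufp):
        _, frame = midsize_ufp
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = sensitivity_suite(frame, which="single_road")
        assert {"single_bqe", "single_wb"} <= set(out["fits"])
        comp = out["comparison"]
        assert {"pct_decrease_100m", "distance_p", "r2"} <= set(comp.columns)

    def test_small_stratum_skipped_with_warning(self, small_ufp_frame):
        with pytest.warns(UserWarning, match="skipped"):
            out = sensitivity_suite(small_ufp_frame, which="traffic",
                                    min_rows=10**6)
        assert not out["fits"]

    def test_downwind_only_decay_detected_downwind(self):
        """With decay present only under downwind conditions, the stratified
        refits find a significant highway distance term downwind but not
        upwind (majority over three campaigns)."""
        cfg = mobilegam.preset("sector_decay")
        cfg.n_shifts = 5
        down_sig, up_ns = 0, 0
        for seed in [12, 13, 14]:
            c = mobilegam.generate_campaign(cfg, seed=seed)
            frame, _ = mobilegam.assemble_frame(
                c.observations, c.traffic, c.weather, c.sessions, c.roads,
                "ufp")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = sensitivity_suite(frame, which="wind")
            t = out["comparison"]
            row = t[(t.analysis == "bqe_downwind") & (t.road_id == "bqe")]
            down_sig += float(row["distance_p"].iloc[0]) < 0.05
            row = t[(t.analysis == "bqe_upwind") & (t.road_id == "bqe")]
            up_ns += float(row["distance_p"].iloc[0]) > 0.05
        assert down_sig >= 2
        assert up_ns >= 2


def test_series_groups_are_contiguous_per_backpack(small_ufp_frame):
    groups = _series_groups(small_ufp_frame)
    df = small_ufp_frame.data
    total = sum(len(g) for g in groups)
    assert total == len(df)
    for g in groups:
        assert df["shift_id"].iloc[g].nunique() == 1
        assert df["operator_id"].iloc[g].nunique() == 1
        ts = df["timestamp"].iloc[g]
        assert ts.is_monotonic_increasing
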