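"""Composition GLMs, spectral/velocity/MSD summaries and the power harness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from meiomove.segmentation import SegmentationParams
from meiomove.stats import (COMPOSITION_MODELS, assess_power,
                            ensemble_spectrogram, fit_composition_models, msd,
                            periodogram, spectral_density_test, spectrogram,
                            velocity_density, velocity_u_test)
from meiomove.synthetic import SyntheticConfig, null_config
from meiomove.io import derive_velocities
from meiomove import segment_dataset
from conftest import make_tracks


def synthetic_segments(rng, n_per_group=60, cluster_probs=((0.9, 0.1), (0.1, 0.9)),
                       shift_times=False):
    """Hand-built two-group segment table with controllable composition."""
    rows = []
    for gi, (g, probs) in enumerate(zip(("A", "B"), cluster_probs)):
        for s in range(n_per_group):
            start = rng.uniform(-170, -60)
            if shift_times and gi == 1:
                start += 60
            dur = rng.uniform(20, 50)
            rows.append({
                "group_id": g, "particle_id": f"{g}{s//4}",
                "cluster": rng.choice(len(probs), p=probs),
                "start_time": start, "end_time": start + dur,
                "duration": dur, "proportion": dur / 180.0,
            })
    return pd.DataFrame(rows)


class TestCompositionModels:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        seg_a = synthetic_segments(rng, cluster_probs=((0.5, 0.5), (0.5, 0.5)))
        seg_a = seg_a[seg_a.group_id == "A"]
        seg_b = seg_a.copy()
        seg_b["group_id"] = "B"
        tests = fit_composition_models(pd.concat([seg_a, seg_b]), "A", "B")
        assert all(t.p_value > 0.99 for t in tests.values())

    def test_label_permutation_type_I_control(self):
        rng = np.random.default_rng(1)
        seg = synthetic_segments(rng, cluster_probs=((0.5, 0.5), (0.5, 0.5)))
        high = 0
        n_perm = 40
        for _ in range(n_perm):
            perm = seg.copy()
            perm["group_id"] = rng.permutation(perm["group_id"].to_numpy())
            p = fit_composition_models(perm, "A", "B",
                                       models=("cluster",))["cluster"].p_value
            high += p > 0.05
        assert high >= 0.9 * n_perm

    def test_strong_cluster_imbalance_detected(self):
        rng = np.random.default_rng(2)
        seg = synthetic_segments(rng, n_per_group=60)
        tests = fit_composition_models(seg, "A", "B")
        assert tests["cluster"].p_value < 1e-3
        # agrees with the 2x2 contingency log-odds chi-squared to first order
        ct = pd.crosstab(seg["group_id"], seg["cluster"])
        chi2 = sps.chi2_contingency(ct, correction=False)
        assert tests["cluster"].p_value < 10 * max(chi2.pvalue, 1e-300)

    def test_time_shift_detected_by_headline_model(self):
        rng = np.random.default_rng(3)
        seg = synthetic_segments(rng, cluster_probs=((0.5, 0.5), (0.5, 0.5)),
                                 shift_times=True)
        tests = fit_composition_models(seg, "A", "B")
        assert tests["cluster_x_start_x_end"].p_value < 1e-6

    def test_model_family_and_deviance_ordering(self):
        rng = np.random.default_rng(4)
        seg = synthetic_segments(rng)
        tests = fit_composition_models(seg, "A", "B")
        assert tuple(tests) == COMPOSITION_MODELS
        for t in tests.values():
            assert t.deviance <= t.null_deviance + 1e-9
            assert 0.0 <= t.p_value <= 1.0
        assert tests["intercept_only"].p_value == 1.0

    def test_chisq_and_lrt_share_deviance(self):
        rng = np.random.default_rng(5)
        seg = synthetic_segments(rng)
        a = fit_composition_models(seg, "A", "B", test="chisq")["cluster"]
        b = fit_composition_models(seg, "A", "B", test="LRT")["cluster"]
        assert a.deviance == b.deviance and a.p_value == b.p_value


class TestPeriodogram:
    def test_constant_series_zero_power(self):
        _, power = periodogram(np.full(64, 3.0))
        assert np.allclose(power, 0.0)

    def test_sine_peak_at_period_six(self):
        t = np.arange(180.0)
        periods, power = periodogram(np.sin(2 * np.pi * t / 6))
        assert periods[np.argmax(power)] == pytest.approx(6.0)

    def test_parseval_total_power_equals_variance(self):
        rng = np.random.default_rng(0)
        for n in (64, 101, 180):
            x = rng.normal(size=n)
            _, power = periodogram(x)
            assert power.sum() == pytest.approx(np.var(x), abs=1e-8)

    def test_white_noise_has_no_dominant_bin(self):
        # a pure tone concentrates ~all power in one bin (fraction ~1);
        # for m iid exponential bins the top bin holds ~ln(m)/m of the total,
        # far below 0.3 for m = 128 — so 0.3 cleanly separates the cases
        hits = 0
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=256)
            _, power = periodogram(x)
            hits += power.max() / power.sum() < 0.3
        assert hits >= 18


class TestSpectrogram:
    def test_chirp_switch_detected(self):
        t = np.arange(240.0)
        x = np.where(t < 120, np.sin(2 * np.pi * t / 6), np.sin(2 * np.pi * t / 12))
        times, periods, S = spectrogram(x, window=30.0)
        dom = periods[np.argmax(S, axis=0)]
        early = dom[times < 90]
        late = dom[times > 150]
        assert np.median(early) == pytest.approx(6.0, abs=1.0)
        assert np.median(late) == pytest.approx(12.0, abs=2.0)

    def test_stationary_sine_constant_trace(self):
        t = np.arange(180.0)
        times, periods, S = spectrogram(np.sin(2 * np.pi * t / 6), window=30.0)
        dom = periods[np.argmax(S, axis=0)]
        assert np.all(np.abs(dom - 6.0) < 1.0)

    def test_zero_signal_zero_matrix(self):
        _, _, S = spectrogram(np.zeros(100), window=30.0)
        assert np.allclose(S, 0.0)

    def test_window_too_long_raises(self):
        with pytest.raises(ValueError, match="window"):
            spectrogram(np.zeros(20), window=30.0)

    def test_ensemble_slice_normalised(self, small_dataset):
        table, _ = small_dataset
        out = ensemble_spectrogram(table, "x", window=30.0, hop=5)
        for group in ("TypeI", "TypeII"):
            S = out[group]["S"]
            assert S.min() >= 0 and S.max() <= 1.0 + 1e-12


class TestSpectralDensityTest:
    @staticmethod
    def sine_group(period, n, seed, group):
        rng = np.random.default_rng(seed)
        t = np.arange(180.0)
        return make_tracks(
            {f"{group}{i}": (np.sin(2 * np.pi * t / period + rng.uniform(0, 6))
                             + rng.normal(0, 0.2, 180), np.zeros(180))
             for i in range(n)}, group=group)

    def test_separated_periods_detected(self):
        tab = pd.concat([self.sine_group(6, 30, 0, "g6"),
                         self.sine_group(12, 30, 1, "g12")])
        assert spectral_density_test(tab, "g6", "g12") < 0.01

    def test_identical_periods_null(self):
        high = 0
        for seed in range(10):
            tab = pd.concat([self.sine_group(6, 10, seed, "a"),
                             self.sine_group(6, 10, 100 + seed, "b")])
            high += spectral_density_test(tab, "a", "b") > 0.05
        assert high >= 8

    def test_single_particle_rejected(self):
        tab = pd.concat([self.sine_group(6, 1, 0, "a"),
                         self.sine_group(6, 5, 1, "b")])
        with pytest.raises(ValueError, match="2 particles"):
            spectral_density_test(tab, "a", "b")


class TestVelocityDensity:
    def test_point_mass(self):
        t = np.arange(50.0)
        tab = make_tracks({"p1": (2.0 * t, np.zeros(50))})  # constant speed 2
        tab = derive_velocities(tab)
        out = velocity_density(tab)
        assert out["g1"]["kde"] is None and out["g1"]["point_mass"] == 2.0

    def test_shifted_strata_modes(self):
        rng = np.random.default_rng(0)
        slow = np.cumsum(rng.normal(1.0, 0.05, 200))
        fast = np.cumsum(rng.normal(3.0, 0.05, 200))
        tab = pd.concat([
            make_tracks({"s": (slow, np.zeros(200))}, group="slow"),
            make_tracks({"f": (fast, np.zeros(200))}, group="fast"),
        ])
        out = velocity_density(derive_velocities(tab))
        grid = np.linspace(0, 4, 400)
        mode_slow = grid[np.argmax(out["slow"]["kde"](grid))]
        mode_fast = grid[np.argmax(out["fast"]["kde"](grid))]
        assert mode_slow == pytest.approx(1.0, abs=0.2)
        assert mode_fast == pytest.approx(3.0, abs=0.2)

    def test_over_time_columns_integrate_to_one(self, velocity_dataset):
        table, _ = velocity_dataset
        out = velocity_density(table, over_time=True, grid_size=30)
        for entry in out.values():
            D = entry["density"]
            widths = np.diff(entry["velocity_edges"])
            mass = (D * widths).sum(axis=1)
            nz = mass > 0
            assert np.allclose(mass[nz], 1.0, atol=1e-9)


class TestVelocityUTest:
    def test_identical_samples(self, velocity_dataset):
        table, _ = velocity_dataset
        one = table[table.group_id == "TypeI"].copy()
        other = one.copy()
        other["group_id"] = "copy"
        assert velocity_u_test(pd.concat([one, other]), "TypeI", "copy") > 0.99

    def test_location_shift_detected(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 100)
        b = rng.normal(2, 1, 100)
        tab = pd.concat([
            make_tracks({"p": (np.zeros(100), np.zeros(100))}, group="A"),
            make_tracks({"p": (np.zeros(100), np.zeros(100))}, group="B"),
        ])
        tab["linear_velocity"] = np.concatenate([a, b])
        assert velocity_u_test(tab, "A", "B") < 1e-6


class TestMSD:
    def test_stationary_zero(self):
        tab = make_tracks({"p1": (np.ones(50), np.ones(50))})
        curve = msd(tab)
        assert np.allclose(curve["msd"], 0.0)

    def test_ballistic_quadratic(self):
        t = np.arange(60.0)
        tab = make_tracks({"p1": (t, np.zeros(60))})
        curve = msd(tab, max_lag=20)
        assert np.allclose(curve["msd"], curve["lag_min"] ** 2)

    def test_diffusive_slope(self):
        rng = np.random.default_rng(0)
        sigma = 0.5
        frames = {f"p{i}": (np.cumsum(rng.normal(0, sigma, 180)),
                            np.cumsum(rng.normal(0, sigma, 180)))
                  for i in range(200)}
        curve = msd(make_tracks(frames), max_lag=20)
        slope = np.polyfit(curve["lag_min"], curve["msd"], 1)[0]
        assert slope == pytest.approx(2 * sigma**2, rel=0.1)

    def test_cluster_curves_conserve_global(self, velocity_dataset):
        table, _ = velocity_dataset
        res = segment_dataset(table, ["x"], random_state=0)
        g = msd(table, max_lag=10)
        per = msd(table, max_lag=10, scope="cluster", result=res)
        for lag, sub in per[per.lag_min > 0].groupby("lag_min"):
            weighted = (sub["msd"] * sub["n_pairs"]).sum() / sub["n_pairs"].sum()
            expected = g.loc[g.lag_min == lag, "msd"].iloc[0]
            assert weighted == pytest.approx(expected, rel=1e-9)


class TestPower:
    def test_null_rejection_rate_near_alpha(self):
        cfg = null_config(SyntheticConfig(seed=77))
        res = assess_power(cfg, n_per_group=40, n_replicates=60, alpha=0.05,
                           test="global_velocity", seed=5)
        tol = 2 * np.sqrt(0.05 * 0.95 / 60)
        assert res.power <= 0.05 + tol

    def test_power_recomputable_from_stored_pvalues(self):
        cfg = null_config(SyntheticConfig(seed=77))
        res = assess_power(cfg, n_per_group=10, n_replicates=5,
                           test="global_velocity", seed=1)
        assert res.power == np.mean(res.p_values < res.alpha)
        assert len(res.seeds) == 5

    def test_power_monotone_in_sample_size(self):
        powers = []
        for n in (10, 30, 60):
            res = assess_power(n_per_group=n, n_replicates=15, alpha=0.05,
                               test="composition", seed=9,
                               params=SegmentationParams())
            powers.append(res.power)
        assert powers[1] >= powers[0] - 0.15
        assert powers[2] >= powers[1] - 0.15
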