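import numpy as np
import pytest

from phenoscreen.growth_metrics import lag_time
from phenoscreen.pipeline import bundle_curves, summarize_all
from phenoscreen.simulate import (
    EMPTY_WELLS,
    GrowthParams,
    SimConfig,
    SimStrainSpec,
    apply_archetype,
    control_specs,
    linear_auc_profile,
    logistic_curve,
    noiseless_signal,
    simulate_library,
    simulate_plate,
    write_bundle,
)

DOSES = (0.0, 0.004, 0.008, 0.012, 0.016)


class TestLogisticCurve:
    def test_midpoint_is_half_amplitude(self):
        p = GrowthParams(baseline=0.05, amplitude=1.0, rate=0.5, midpoint=24.0)
        assert logistic_curve(p, [24.0])[0] == pytest.approx(0.55)

    def test_approaches_asymptote(self):
        p = GrowthParams(baseline=0.05, amplitude=1.0, rate=0.5, midpoint=24.0)
        assert logistic_curve(p, [500.0])[0] == pytest.approx(1.05, abs=1e-9)

    def test_matches_direct_formula_on_grid(self):
        p = GrowthParams(baseline=0.03, amplitude=0.9, rate=0.35, midpoint=20.0)
        t = np.arange(12.0, 49.0, 4.0)
        want = 0.03 + 0.9 / (1 + np.exp(-0.35 * (t - 20.0)))
        np.testing.assert_allclose(logistic_curve(p, t), want, rtol=1e-14)


class TestLinearAucProfile:
    @pytest.mark.parametrize(
        "gi50,expected",
        [
            (0.01, [1, 0.8, 0.6, 0.4, 0.2]),
            (0.008, [1, 0.75, 0.5, 0.25, 0.0]),
        ],
    )
    def test_unclipped_factors(self, gi50, expected):
        np.testing.assert_allclose(linear_auc_profile(gi50, DOSES), expected)

    def test_clipped_truth_warns(self):
        with pytest.warns(UserWarning, match="clipped"):
            g = linear_auc_profile(0.003, DOSES)
        np.testing.assert_allclose(g, [1, 1 / 3, 0, 0, 0])


class TestApplyArchetype:
    def test_dose_zero_returns_untreated_parameters(self):
        spec = SimStrainSpec("x", 0.0067, "class_i")
        assert apply_archetype(spec, 0.0) == spec.growth

    def test_class_i_scales_amplitude_only(self):
        spec = SimStrainSpec("x", 0.01, "class_i")
        p = apply_archetype(spec, 0.008)
        assert p.amplitude == pytest.approx(spec.growth.amplitude * 0.6)
        assert (p.rate, p.midpoint) == (spec.growth.rate, spec.growth.midpoint)

    def test_class_iii_no_visible_growth_at_max_dose(self):
        # a severely sensitive long-lag strain shows no visible growth
        # (blank-corrected OD < 0.2) anywhere in the window at the top dose
        spec = SimStrainSpec("x", 0.005, "class_iii")
        times = np.arange(12.0, 49.0, 4.0)
        signal = noiseless_signal(spec, 0.016, times, DOSES) - spec.growth.baseline
        assert np.all(signal < 0.2)

    def test_class_iii_midpoint_delayed_with_dose(self):
        spec = SimStrainSpec("x", 0.012, "class_iii")
        mids = [apply_archetype(spec, d).midpoint for d in DOSES]
        assert mids == sorted(mids) and mids[-1] > mids[0]

    def test_class_ii_rate_monotone_decreasing_in_dose(self):
        spec = SimStrainSpec("x", 0.009, "class_ii")
        rates = [apply_archetype(spec, d).rate for d in DOSES[1:]]
        assert rates == sorted(rates, reverse=True)

    def test_wt_like_keeps_plateau_and_delays_midpoint(self):
        spec = SimStrainSpec("x", 0.01, "wt_like")
        p = apply_archetype(spec, 0.008)
        assert p.amplitude == spec.growth.amplitude
        assert p.midpoint > spec.growth.midpoint

    def test_grid_auc_calibration_reproduces_linear_target(self):
        # kinetic archetypes hit the same normalized grid AUC as plain scaling
        times = np.arange(12.0, 49.0, 4.0)
        for arche in ("wt_like", "class_ii", "class_iii"):
            spec = SimStrainSpec("x", 0.012, arche)
            auc0 = np.trapezoid(
                noiseless_signal(spec, 0.0, times, DOSES) - spec.growth.baseline, times
            )
            auc = np.trapezoid(
                noiseless_signal(spec, 0.008, times, DOSES) - spec.growth.baseline, times
            )
            target = 1 - 0.008 / (2 * 0.012)
            assert auc / auc0 == pytest.approx(target, rel=1e-9), arche


class TestSimulatePlate:
    def test_fixed_control_and_blank_positions(self):
        cfg = SimConfig(noise_sigma_mult=0.0, noise_sd_add=0.0, seed=0)
        layout, plates = simulate_plate([SimStrainSpec("q1", 0.01)], cfg)
        by_role = {}
        for rec in layout:
            by_role.setdefault(rec.role, []).append(rec.well)
        assert sorted(by_role["wt_control"]) == ["B11", "D3", "F5"]
        assert by_role["control_rad14"] == ["B12"]
        assert by_role["control_rev1"] == ["D4"]
        assert by_role["control_mag1"] == ["G5"]
        assert sorted(by_role["empty"]) == sorted(EMPTY_WELLS)
        assert len(plates) == len(cfg.doses)

    def test_noiseless_output_equals_model_values(self):
        cfg = SimConfig(noise_sigma_mult=0.0, noise_sd_add=0.0, seed=0)
        spec = SimStrainSpec("q1", 0.01)
        layout, plates = simulate_plate([spec], cfg)
        plate0 = next(p for p in plates if p.dose == 0.0)
        well = next(r.well for r in layout if r.strain_id == "q1")
        np.testing.assert_allclose(
            plate0.readings[well], logistic_curve(spec.growth, plate0.times)
        )

    def test_same_seed_identical_output(self):
        cfg = SimConfig(seed=77)
        _, a = simulate_plate([SimStrainSpec("q1", 0.01)], cfg)
        _, b = simulate_plate([SimStrainSpec("q1", 0.01)], cfg)
        for pa, pb in zip(a, b):
            for w in pa.readings:
                np.testing.assert_array_equal(pa.readings[w], pb.readings[w])

    def test_too_many_query_strains_rejected(self):
        cfg = SimConfig()
        specs = [SimStrainSpec(f"q{i}", 0.01) for i in range(89)]
        with pytest.raises(ValueError, match="at most"):
            simulate_plate(specs, cfg)


class TestSimulateLibrary:
    MIX = {"class_i": 1 / 3, "class_ii": 1 / 3, "class_iii": 1 / 3}

    def test_mixture_allocation_exact(self):
        cfg = SimConfig(n_replicates=1, seed=5)
        bundle = simulate_library(90, self.MIX, cfg)
        counts = bundle.truth["archetype"].value_counts()
        assert counts.to_dict() == {"class_i": 30, "class_ii": 30, "class_iii": 30}

    def test_slow_growers_constructed_with_long_untreated_lag(self):
        cfg = SimConfig(n_replicates=1, noise_sigma_mult=0.0, noise_sd_add=0.0, seed=9)
        bundle = simulate_library(60, self.MIX, cfg, slow_grower_fraction=0.5)
        curves = bundle_curves(bundle)
        slow_ids = set(bundle.truth.loc[bundle.truth.slow_grower, "strain_id"])
        assert slow_ids  # fraction 0.5 of 60 draws must hit some
        for c in curves:
            if c.strain_id in slow_ids and c.dose == 0.0:
                lag = lag_time(c.times, c.od)
                assert (not lag.is_finite) or lag.hours > 20

    def test_blanks_average_to_baseline(self):
        cfg = SimConfig(n_replicates=2, seed=21)
        bundle = simulate_library(10, self.MIX, cfg)
        blanks = [r.well for r in bundle.layout if r.role == "empty"]
        vals = np.concatenate(
            [p.readings[w] for p in bundle.plates for w in blanks if w in p.readings]
        )
        assert vals.mean() == pytest.approx(0.05, abs=0.01)

    def test_rerun_byte_identical(self, tmp_path):
        cfg = SimConfig(n_replicates=2, seed=33)
        for d in ("a", "b"):
            paths = write_bundle(simulate_library(12, self.MIX, cfg), tmp_path / d)
        for name in ("layout.tsv", "readings.csv", "ground_truth.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError):
            simulate_library(10, {"class_i": 0.7}, SimConfig())

    def test_noiseless_unclipped_bundle_recovers_truth_through_pipeline(self):
        cfg = SimConfig(n_replicates=2, noise_sigma_mult=0.0, noise_sd_add=0.0, seed=2)
        tds = {a: (0.012, 0.001) for a in self.MIX}
        bundle = simulate_library(15, self.MIX, cfg, slow_grower_fraction=0.0,
                                  truth_distributions=tds)
        _, summaries = summarize_all(bundle_curves(bundle))
        truth = dict(zip(bundle.truth.strain_id, bundle.truth.true_gi50))
        checked = 0
        for sid, t in truth.items():
            if t >= 0.008:  # unclipped regime
                assert summaries[sid].gi50_mean == pytest.approx(t, rel=1e-8)
                checked += 1
        assert checked >= 10


class TestControlSpecs:
    def test_printed_control_truths(self):
        specs = control_specs()
        assert specs["WT"].true_gi50 == 0.01
        assert specs["rad14"].true_gi50 == 0.008
        assert specs["rev1"].true_gi50 == 0.006
        assert specs["mag1"].true_gi50 == 0.003

    def test_severe_control_profiles_are_valid_dose_profiles(self):
        for name in ("rev1", "mag1"):
            spec = control_specs()[name]
            assert spec.profile[0] == 1.0
            assert all(0 <= v <= 1 for v in spec.profile)
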