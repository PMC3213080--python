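import numpy as np
import pytest

from conftest import NOISELESS, simulate_replicates
from phenoscreen.dose_response import (
    DoseResponseFit,
    fit_replicate,
    gi50_concordance,
    gi50_from_slope,
    normalize_aucs,
    ols_fit,
    replicate_qc,
    subsample_timepoints,
    summarize_strain,
)
from phenoscreen.pipeline import summarize_all
from phenoscreen.simulate import SimStrainSpec

DOSES = (0.0, 0.004, 0.008, 0.012, 0.016)


def normal_equations_oracle(x, y):
    """Independent OLS oracle: solve X'X b = X'y directly."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_tot = ((y - y.mean()) ** 2).sum()
    return beta[1], beta[0], 1 - (resid @ resid) / ss_tot


class TestNormalizeAucs:
    def test_divides_by_untreated(self):
        aucs = dict(zip(DOSES, [20, 16, 12, 8, 4]))
        norm = normalize_aucs(aucs)
        assert [norm[d] for d in DOSES] == pytest.approx([1, 0.8, 0.6, 0.4, 0.2])
        assert norm[0.0] == 1.0  # exact, not approximate

    def test_flat_response_all_ones(self):
        norm = normalize_aucs(dict(zip(DOSES, [20] * 5)))
        assert set(norm.values()) == {1.0}

    def test_no_untreated_growth_flagged_unusable(self):
        assert normalize_aucs(dict(zip(DOSES, [0, 1, 1, 1, 1]))) is None

    def test_requires_dose_zero(self):
        with pytest.raises(ValueError):
            normalize_aucs({0.004: 1.0, 0.008: 0.5, 0.016: 0.2})


class TestOlsFit:
    def test_exact_line(self):
        slope, intercept, r2 = ols_fit(DOSES, [1, 0.8, 0.6, 0.4, 0.2])
        assert slope == pytest.approx(-50.0)
        assert intercept == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_clipped_profile_closed_form(self):
        # severe responder clipped at zero: the regression flattens and
        # the fitted slope underestimates the steepness
        slope, _, r2 = ols_fit(DOSES, [1, 1 / 3, 0, 0, 0])
        assert slope == pytest.approx(-58.333333333, abs=1e-6)
        assert r2 == pytest.approx(0.7205882353, abs=1e-9)

    def test_flat_response_r2_undefined(self):
        slope, intercept, r2 = ols_fit(DOSES, [1.0] * 5)
        assert r2 is None and slope == pytest.approx(0.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            x = np.sort(rng.uniform(0, 0.02, size=rng.integers(3, 8)))
            y = rng.uniform(0, 1.2, size=x.size)
            got = ols_fit(x, y)
            want = normal_equations_oracle(x, y)
            assert got[0] == pytest.approx(want[0], rel=1e-10, abs=1e-12)
            assert got[1] == pytest.approx(want[1], rel=1e-10, abs=1e-12)
            assert got[2] == pytest.approx(want[2], rel=1e-10, abs=1e-12)

    def test_requires_three_points(self):
        with pytest.raises(ValueError):
            ols_fit([0, 0.004], [1, 0.5])


class TestGi50FromSlope:
    @pytest.mark.parametrize("slope,expected", [(-50, 0.01), (-62.5, 0.008)])
    def test_negative_slope(self, slope, expected):
        assert gi50_from_slope(slope) == pytest.approx(expected)

    def test_non_negative_slope_undefined(self):
        assert gi50_from_slope(10.0) is None
        assert gi50_from_slope(0.0) is None

    def test_intercept_adjusted_variant(self):
        # (intercept - 0.5) / (-slope)
        assert gi50_from_slope(-50, intercept=0.9, intercept_adjusted=True) == \
            pytest.approx(0.008)


class TestReplicateQc:
    def make_fit(self, r2, gi50=0.01):
        return DoseResponseFit("S", "R1", DOSES, (), -50.0, 1.0, r2, gi50, False)

    @pytest.mark.parametrize("r2,expected", [(0.72, True), (0.7, False), (0.69, False)])
    def test_threshold_strict(self, r2, expected):
        assert replicate_qc(self.make_fit(r2)) is expected

    def test_fails_without_gi50(self):
        assert replicate_qc(self.make_fit(0.95, gi50=None)) is False


class TestSummarizeStrain:
    def make_fit(self, gi50, qc=True, n_tp=50):
        return DoseResponseFit("S", "R", DOSES, (), -50.0, 1.0, 0.9, gi50, qc,
                               n_timepoints=n_tp)

    def test_mean_and_sem(self):
        s = summarize_strain([self.make_fit(0.009), self.make_fit(0.011)])
        assert s.gi50_mean == pytest.approx(0.010)
        assert s.gi50_sem == pytest.approx(0.001)
        assert s.status == "ok"

    def test_single_passing_replicate_insufficient(self):
        s = summarize_strain(
            [self.make_fit(0.01), self.make_fit(0.01, qc=False), self.make_fit(0.01, qc=False)]
        )
        assert s.status == "insufficient_data" and s.gi50_mean is None
        assert (s.n_pass, s.n_total) == (1, 3)

    def test_measurement_accounting(self):
        # 3 passing replicates x 5 doses x 10 time points
        s = summarize_strain([self.make_fit(0.01, n_tp=50) for _ in range(3)])
        assert s.n_measurements == 150


class TestFitReplicate:
    def test_full_path_recovers_wild_type_value(self):
        aucs = dict(zip(DOSES, [20.0, 16.0, 12.0, 8.0, 4.0]))
        fit = fit_replicate("WT", "R1", aucs)
        assert fit.gi50 == pytest.approx(0.01)
        assert fit.qc_pass

    def test_resistant_replicate_flows_to_flag_not_error(self):
        aucs = dict(zip(DOSES, [10.0, 10.5, 11.0, 11.5, 12.0]))
        fit = fit_replicate("RES", "R1", aucs)
        assert fit.gi50 is None and not fit.qc_pass
        assert "non_responsive" in fit.flags


class TestSubsampleTimepoints:
    def test_identity_on_full_grid(self):
        curves = simulate_replicates([SimStrainSpec("A", 0.01)], 1, **NOISELESS)
        same = subsample_timepoints(curves, curves[0].times)
        np.testing.assert_array_equal(same[0].od, curves[0].od)

    def test_restricts_to_kept_times(self):
        curves = simulate_replicates([SimStrainSpec("A", 0.01)], 1, **NOISELESS)
        keep = [12, 20, 28, 36, 44, 48]
        sub = subsample_timepoints(curves, keep)
        assert all(c.times.tolist() == keep for c in sub)

    def test_rejects_off_grid_and_singleton(self):
        curves = simulate_replicates([SimStrainSpec("A", 0.01)], 1, **NOISELESS)
        with pytest.raises(ValueError):
            subsample_timepoints(curves, [12, 21])
        with pytest.raises(ValueError):
            subsample_timepoints(curves, [24])


class TestPipelineExactness:
    """Noiseless linear-AUC simulations are an analytic fixed point of the
    whole chain: blank correction, AUC, normalization, OLS, -0.5/slope."""

    TRUTHS = [0.008, 0.009, 0.01, 0.012, 0.016]

    def fitted_summaries(self):
        specs = [SimStrainSpec(f"S{i}", g) for i, g in enumerate(self.TRUTHS)]
        curves = simulate_replicates(specs, 2, **NOISELESS)
        _, summaries = summarize_all(curves)
        return summaries

    def test_gi50_equals_truth_in_unclipped_regime(self):
        summaries = self.fitted_summaries()
        for i, truth in enumerate(self.TRUTHS):
            assert summaries[f"S{i}"].gi50_mean == pytest.approx(truth, rel=1e-9)

    def test_r_squared_is_one(self):
        specs = [SimStrainSpec("A", 0.01)]
        curves = simulate_replicates(specs, 1, **NOISELESS)
        from phenoscreen.dose_response import fits_from_curves

        (fit,) = [f for f in fits_from_curves(curves) if f.strain_id == "A"]
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_ten_vs_six_point_concordance_exact(self):
        specs = [SimStrainSpec(f"S{i}", g) for i, g in enumerate(self.TRUTHS)]
        curves = simulate_replicates(specs, 2, **NOISELESS)
        _, s10 = summarize_all(curves)
        _, s6 = summarize_all(subsample_timepoints(curves, [12, 20, 28, 36, 44, 48]))
        assert gi50_concordance(s10, s6) == pytest.approx(1.0, abs=1e-12)


class TestGi50Concordance:
    def test_identical_summaries_give_one(self):
        specs = [SimStrainSpec(f"S{i}", g) for i, g in enumerate([0.008, 0.01, 0.012])]
        curves = simulate_replicates(specs, 2, **NOISELESS)
        _, s = summarize_all(curves)
        assert gi50_concordance(s, s) == pytest.approx(1.0)

    def test_disjoint_strain_sets_error(self):
        specs_a = [SimStrainSpec(f"A{i}", g) for i, g in enumerate([0.008, 0.01, 0.012])]
        specs_b = [SimStrainSpec(f"B{i}", g) for i, g in enumerate([0.008, 0.01, 0.012])]
        _, sa = summarize_all(simulate_replicates(specs_a, 2, **NOISELESS))
        _, sb = summarize_all(simulate_replicates(specs_b, 2, **NOISELESS))
        sa = {k: v for k, v in sa.items() if k.startswith("A")}
        sb = {k: v for k, v in sb.items() if k.startswith("B")}
        with pytest.raises(ValueError):
            gi50_concordance(sa, sb)


def test_noisy_gi50_estimator_unbiased_in_mean():
    """Multiplicative OD noise perturbs but does not bias the GI50 in the
    unclipped regime: 100 seeded simulations straddle the truth within 3 sem."""
    truth = 0.01
    estimates = []
    for seed in range(1, 101):
        curves = simulate_replicates(
            [], n_replicates=3, seed=seed, noise_sigma_mult=0.05, noise_sd_add=0.005
        )
        _, summaries = summarize_all(curves)
        if summaries["WT"].gi50_mean is not None:
            estimates.append(summaries["WT"].gi50_mean)
    est = np.array(estimates)
    sem = est.std(ddof=1) / np.sqrt(est.size)
    assert est.size >= 95
    assert abs(est.mean() - truth) < 3 * sem
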