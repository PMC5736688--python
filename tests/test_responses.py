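"""Response mapping, summaries, inhibitors, significance, chi-square, folds."""

import numpy as np
import pytest

from vegfrsim import (
    CellResponseTrace,
    ConfigurationError,
    ParameterValidationError,
    ResponseSummary,
    UnknownEntityError,
    apply_inhibitor,
    chi2_gof,
    compute_responses,
    generate_fixture_parameters,
    is_significant,
    percent_reduction,
    phospho_trace,
    receptor_fold,
    run_model,
    significance_band,
    summarize,
)

T_SHORT = 1200.0
N_SHORT = 241


def run_and_trace(params, variant="specific"):
    result = run_model(params, variant, t_end=T_SHORT, n_points=N_SHORT)
    return result, compute_responses(result, params)


class TestComputeResponses:
    def test_weighted_sum(self, mini_params):
        result, trace = run_and_trace(mini_params)
        expected_mig = sum(
            a.weights["migration"] * phospho_trace(result, a.name)
            for a in mini_params.adapters
        )
        assert np.allclose(trace.migration, expected_mig, rtol=0, atol=1e-12)

    def test_all_zero_weights_zero_responses(self, mini_params):
        params = mini_params.copy()
        for a in params.adapters:
            a.weights = {"migration": 0.0, "proliferation": 0.0}
        _, trace = run_and_trace(params)
        assert np.all(trace.migration == 0.0)
        assert np.all(trace.proliferation == 0.0)

    def test_missing_weight_rejected(self, mini_params):
        params = mini_params.copy()
        del params.adapters[0].weights["migration"]
        result = run_model(params, "specific", t_end=T_SHORT, n_points=N_SHORT)
        with pytest.raises(ConfigurationError, match="migration"):
            compute_responses(result, params)

    def test_degradation_is_ccbl_trace_bit_identical(self, mini_params):
        params = mini_params.copy()
        params.degradation_adapter = "A2"
        result, trace = run_and_trace(params)
        assert np.array_equal(trace.degradation, phospho_trace(result, "A2"))

    def test_degradation_zero_without_degradation_adapter(self, mini_params):
        _, trace = run_and_trace(mini_params)  # no adapter named cCbl
        assert np.all(trace.degradation == 0.0)


class TestSummarize:
    def test_constant_trace(self):
        t = np.linspace(0.0, 10.0, 11)
        trace = CellResponseTrace(t, np.ones(11), np.zeros(11), np.zeros(11))
        s = summarize(trace)
        assert s.integrated["migration"] == pytest.approx(10.0)
        assert s.amplitude["migration"] == 1.0
        assert s.relative_integrated["migration"] == 1.0

    def test_exponential_auc_closed_form(self):
        t = np.linspace(0.0, 10.0, 2001)
        trace = CellResponseTrace(t, np.exp(-t), np.zeros_like(t), np.zeros_like(t))
        s = summarize(trace)
        assert s.integrated["migration"] == pytest.approx(1 - np.exp(-10), rel=1e-3)

    def test_relative_fractions(self):
        t = np.linspace(0.0, 1.0, 3)
        trace = CellResponseTrace(t, 3 * np.ones(3), np.ones(3), np.zeros(3))
        s = summarize(trace)
        assert s.relative_integrated["migration"] == pytest.approx(0.75)
        assert s.relative_integrated["proliferation"] == pytest.approx(0.25)
        assert s.relative_integrated["degradation"] == 0.0
        assert sum(s.relative_integrated.values()) == pytest.approx(1.0)

    def test_degenerate_grid_rejected(self):
        t = np.array([0.0])
        trace = CellResponseTrace(t, np.ones(1), np.ones(1), np.ones(1))
        with pytest.raises(ConfigurationError):
            summarize(trace)

    def test_monotone_under_pointwise_domination(self, mini_params):
        _, trace = run_and_trace(mini_params)
        boosted = CellResponseTrace(
            trace.times, 2 * trace.migration + 1.0, trace.proliferation, trace.degradation
        )
        lo, hi = summarize(trace), summarize(boosted)
        assert hi.integrated["migration"] > lo.integrated["migration"]
        assert hi.amplitude["migration"] > lo.amplitude["migration"]


class TestInhibitors:
    def test_inhibited_adapter_trace_is_zero(self, mini_params):
        treated = apply_inhibitor(mini_params, "A1")
        result = run_model(treated, "specific", t_end=T_SHORT, n_points=N_SHORT)
        assert np.all(phospho_trace(result, "A1") == 0.0)

    def test_binding_competition_persists_under_kp_block(self, mini_params):
        """The kp-mode inhibitor keeps the target bound, so others still compete."""
        treated = apply_inhibitor(mini_params, "A1", mode="kp")
        depleted = apply_inhibitor(mini_params, "A1", mode="deplete")
        r_kp = run_model(treated, "specific", t_end=T_SHORT, n_points=N_SHORT)
        r_dep = run_model(depleted, "specific", t_end=T_SHORT, n_points=N_SHORT)
        # removing the competitor entirely frees sites: A2 does strictly better
        auc_kp = np.trapezoid(phospho_trace(r_kp, "A2"), r_kp.times)
        auc_dep = np.trapezoid(phospho_trace(r_dep, "A2"), r_dep.times)
        assert auc_dep > auc_kp

    def test_inhibiting_every_weighted_adapter_kills_responses(self, mini_params):
        params = mini_params
        for a in params.adapters:
            params = apply_inhibitor(params, a.name)
        _, trace = run_and_trace(params)
        s = summarize(trace)
        assert s.integrated["migration"] == 0.0
        assert s.integrated["proliferation"] == 0.0

    def test_inhibitor_never_increases_target_trace(self, mini_params):
        base = run_model(mini_params, "specific", t_end=T_SHORT, n_points=N_SHORT)
        treated = apply_inhibitor(mini_params, "A2")
        after = run_model(treated, "specific", t_end=T_SHORT, n_points=N_SHORT)
        assert np.all(
            phospho_trace(after, "A2") <= phospho_trace(base, "A2") + 1e-12
        )

    def test_unknown_adapter_raises(self, mini_params):
        with pytest.raises(UnknownEntityError):
            apply_inhibitor(mini_params, "nope")


class TestPercentReductionAndBand:
    def summary(self, mig):
        return ResponseSummary(
            integrated={"migration": mig, "proliferation": 1.0, "degradation": 0.0}
        )

    @pytest.mark.parametrize(
        "base, treated, expected",
        [(4.0, 4.0, 0.0), (4.0, 0.0, 100.0), (4.0, 1.0, 75.0)],
    )
    def test_arithmetic(self, base, treated, expected):
        assert percent_reduction(self.summary(base), self.summary(treated), "migration") == (
            pytest.approx(expected)
        )

    def test_invariant_under_common_rescaling(self):
        a = percent_reduction(self.summary(5.0), self.summary(2.0), "migration")
        b = percent_reduction(self.summary(500.0), self.summary(200.0), "migration")
        assert a == pytest.approx(b)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ParameterValidationError):
            percent_reduction(self.summary(0.0), self.summary(0.0), "migration")

    def test_band_and_significance(self):
        band = significance_band(self.summary(100.0), "migration")
        assert band == (pytest.approx(90.0), pytest.approx(110.0))
        assert is_significant(89.0, band)
        assert not is_significant(110.0, band)  # inclusive bound
        assert not is_significant(95.0, band)


class TestChi2:
    def test_perfect_fit(self):
        pred = np.array([1.0, 2.0, 3.0])
        report = chi2_gof(pred, pred, sem=np.ones(3))
        assert report.chi2 == 0.0
        assert report.passed

    def test_unit_residuals(self):
        pred = np.zeros(4)
        obs = np.ones(4)
        report = chi2_gof(pred, obs, sem=np.ones(4))
        assert report.chi2 == pytest.approx(4.0)
        assert report.dof == 3

    def test_critical_value_dof_4(self):
        """chi2 threshold at dof=4, alpha=0.05 is 9.488 (standard table value)."""
        report = chi2_gof(np.zeros(5), np.zeros(5), sem=np.ones(5))
        assert report.critical == pytest.approx(9.488, abs=5e-3)

    def test_pearson_variant(self):
        pred = np.array([4.0, 9.0])
        obs = np.array([6.0, 6.0])
        report = chi2_gof(pred, obs, pearson=True)
        assert report.chi2 == pytest.approx((2**2) / 4 + (3**2) / 9)

    def test_bad_inputs(self):
        with pytest.raises(ConfigurationError):
            chi2_gof(np.zeros(3), np.zeros(2), sem=np.ones(2))
        with pytest.raises(ConfigurationError):
            chi2_gof(np.zeros(3), np.zeros(3), sem=np.array([1.0, 0.0, 1.0]))


class TestReceptorFold:
    def test_symmetric_receptors_fold_one(self):
        params = generate_fixture_parameters(seed=9, n_adapters=2, n_sites=2)
        r1, r2 = params.receptors
        r2.concentration = r1.concentration
        r2.kon_vegf, r2.koff_vegf = r1.kon_vegf, r1.koff_vegf
        r2.sites, r2.aa_spacing = r1.sites, r1.aa_spacing
        for a in params.adapters:
            a.site_names[r2.name] = a.site_names[r1.name]
        params.validate()
        fold = receptor_fold(params, "migration", t_end=T_SHORT, n_points=N_SHORT)
        assert fold == pytest.approx(1.0, rel=1e-6)

    def test_fold_increases_with_first_receptor_abundance(self):
        params = generate_fixture_parameters(seed=9, n_adapters=2, n_sites=2)
        base = receptor_fold(params, "migration", t_end=T_SHORT, n_points=N_SHORT)
        boosted = params.copy()
        boosted.receptor(boosted.receptors[0].name).concentration *= 2
        assert receptor_fold(boosted, "migration", t_end=T_SHORT, n_points=N_SHORT) > base

    def test_zero_denominator_flagged(self):
        params = generate_fixture_parameters(seed=9, n_adapters=2, n_sites=2)
        params.receptors[1].concentration = 0.0
        with pytest.raises(ParameterValidationError, match="degenerate"):
            receptor_fold(params, "migration", t_end=T_SHORT, n_points=N_SHORT)

    def test_requires_two_receptors(self, mini_params):
        with pytest.raises(ConfigurationError):
            receptor_fold(mini_params, "migration")
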