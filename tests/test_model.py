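"""Model fitting: chi-square, bookkeeping, recovery, profile likelihood."""

import numpy as np
import pytest

from npcassembly import (FitSpec, MixingParams, NupAssemblyModel, NupKinetics,
                         REFERENCE_PANEL, RegionTraces, SimulationConfig,
                         chi_square, compare_bic,
                         profile_interval_from_function,
                         simulate_region_traces)
from npcassembly.model import ComparisonError, WeightingError


class TestChiSquare:
    def test_zero_for_perfect_model(self, noiseless_traces):
        config = SimulationConfig(seed=0, noise_sd=0.0)
        kinetics = {k.nup_id: k for k in config.kinetics}
        assert chi_square(kinetics, config.mixing, noiseless_traces,
                          sigma_floor=1e-3) == pytest.approx(0.0, abs=1e-20)

    def test_single_point_two_sigma_residual(self):
        t = np.array([10.0])
        kin = NupKinetics("x", 2.0, 5.0, 2.0, 5.0)
        mix = MixingParams(1.0, 0.0, d_c=0.0)
        # model value at t=10: pm = ip = 0.8 in both regions
        model_val = 0.8
        sigma = 0.05
        tr = RegionTraces(t, np.array([model_val + 2 * sigma]),
                          np.array([model_val]), np.array([sigma]),
                          np.array([sigma]))
        assert chi_square({"x": kin}, mix, {"x": tr}) == pytest.approx(4.0)

    def test_perturbation_increases_chi2(self, noiseless_traces):
        config = SimulationConfig(seed=0, noise_sd=0.0)
        kinetics = {k.nup_id: k for k in config.kinetics}
        base = chi_square(kinetics, config.mixing, noiseless_traces, 1e-3)
        bumped = dict(kinetics)
        k0 = kinetics["Nup107"]
        bumped["Nup107"] = NupKinetics("Nup107", k0.n_p, k0.K_p * 1.05,
                                       k0.n_i, k0.K_i)
        assert chi_square(bumped, config.mixing, noiseless_traces, 1e-3) > base

    def test_zero_sigma_without_floor_raises(self, noiseless_traces):
        config = SimulationConfig(seed=0, noise_sd=0.0)
        kinetics = {k.nup_id: k for k in config.kinetics}
        with pytest.raises(WeightingError):
            chi_square(kinetics, config.mixing, noiseless_traces,
                       sigma_floor=0.0)


class TestBookkeeping:
    @pytest.mark.parametrize("P", [1, 3, 10])
    def test_free_parameter_counts(self, noisy_traces, P):
        subset = {nup: noisy_traces[nup] for nup in list(noisy_traces)[:P]}
        assert NupAssemblyModel(subset, mode="reduced").n_params == 4 * P + 3
        assert NupAssemblyModel(subset, mode="full").n_params == 6 * P + 1

    def test_n_obs_counts_both_regions(self, noisy_traces):
        model = NupAssemblyModel(noisy_traces)
        assert model.n_obs == 2 * 10 * 241

    def test_fitspec_validation(self):
        with pytest.raises(ValueError):
            FitSpec(mode="other")
        with pytest.raises(ValueError):
            FitSpec(dc_grid=())
        with pytest.raises(ValueError):
            FitSpec(multistart=0)


class TestFitting:
    def test_noiseless_self_consistency(self, noiseless_traces):
        """Refitting model-generated data recovers every parameter."""
        subset = {n: noiseless_traces[n]
                  for n in ("Nup107", "Nup93", "Tpr", "Nup358")}
        res = NupAssemblyModel(subset, mode="reduced").fit(multistart=1,
                                                           seed=0)
        assert res.chi2 < 1e-6
        assert res.d_c == 2.0
        assert res.mixing.f_n == pytest.approx(0.857, abs=1e-3)
        assert res.mixing.f_c == pytest.approx(0.295, abs=1e-3)
        for nup, kin in res.kinetics.items():
            true = next(k for k in REFERENCE_PANEL if k.nup_id == nup)
            for attr in ("n_p", "K_p", "n_i", "K_i"):
                assert getattr(kin, attr) == pytest.approx(
                    getattr(true, attr), rel=1e-3)

    def test_noisy_fit_quality(self, reduced_fit):
        assert reduced_fit.r2 > 0.99
        assert reduced_fit.d_c == 2.0
        assert reduced_fit.mixing.f_n == pytest.approx(0.857, abs=0.05)
        assert reduced_fit.mixing.f_c == pytest.approx(0.295, abs=0.05)
        assert set(reduced_fit.dc_chi2) == {0, 1, 2, 3, 4, 5, 6}
        assert min(reduced_fit.dc_chi2, key=reduced_fit.dc_chi2.get) == 2.0

    def test_fit_deterministic_given_seed(self, noisy_traces):
        subset = {n: noisy_traces[n] for n in ("Nup107", "Tpr")}
        model = NupAssemblyModel(subset, dc_grid=(2.0,))
        a = model.fit(multistart=2, seed=11)
        b = model.fit(multistart=2, seed=11)
        np.testing.assert_array_equal(a.x, b.x)

    def test_summary_reports_key_quantities(self, reduced_fit):
        text = reduced_fit.summary()
        assert "f_n" in text and "BIC" in text
        for nup in reduced_fit.kinetics:
            assert nup in text

    def test_from_dataframe_constructor(self, noisy_traces):
        from npcassembly.traces import traces_to_frame
        model = NupAssemblyModel.from_dataframe(traces_to_frame(noisy_traces))
        assert model.n_nups == 10


class TestProfileLikelihood:
    def test_gaussian_limit_reproduces_wald_interval(self):
        sigma = 0.37
        est = 1.2
        iv = profile_interval_from_function(
            lambda v: ((v - est) / sigma) ** 2, est, 0.0, level=0.95)
        assert iv.lower == pytest.approx(est - 1.959964 * sigma, abs=1e-3)
        assert iv.upper == pytest.approx(est + 1.959964 * sigma, abs=1e-3)
        assert not iv.one_sided

    def test_bounded_profile_is_one_sided(self):
        iv = profile_interval_from_function(
            lambda v: ((v - 0.99) / 0.05) ** 2, 0.99, 0.0, bounds=(0.0, 1.0))
        assert iv.upper_at_bound and iv.upper == 1.0
        assert not iv.lower_at_bound

    def test_interval_contains_estimate_on_fit(self, reduced_fit):
        iv = reduced_fit.profile_ci("f_n")
        assert iv.lower < reduced_fit.mixing.f_n < iv.upper
        assert iv.upper - iv.lower < 0.05

    def test_coverage_of_true_fraction(self):
        """Profile intervals for f_n cover the generating value in most
        replicates (small-scale coverage check)."""
        hits = 0
        n_rep = 8
        for seed in range(n_rep):
            config = SimulationConfig(seed=seed,
                                      kinetics=REFERENCE_PANEL[:4])
            traces = simulate_region_traces(config)
            res = NupAssemblyModel(traces, dc_grid=(2.0,)).fit(
                multistart=1, seed=0)
            iv = res.profile_ci("f_n")
            hits += iv.lower <= 0.857 <= iv.upper
        assert hits >= n_rep - 2


class TestModelComparison:
    def test_identical_fits_have_zero_delta(self, reduced_fit):
        assert compare_bic(reduced_fit, reduced_fit) == 0.0

    def test_mismatched_data_rejected(self, reduced_fit, noiseless_traces):
        other = NupAssemblyModel(noiseless_traces).fit(multistart=1, seed=0)
        with pytest.raises(ComparisonError):
            compare_bic(reduced_fit, other)
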