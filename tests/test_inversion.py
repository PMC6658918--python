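"""Variational-Laplace inversion: priors, optimisation behaviour, recovery."""

import dataclasses

import numpy as np
import pytest

from valdcm.design import InputMatrix
from valdcm.inversion import (
    InversionConfig,
    log_evidence,
    make_priors,
    variational_laplace,
)
from valdcm.modelspace import make_model_spec, reduced_space
from valdcm.simulate import (
    RegionTimeSeries,
    default_ground_truth,
    simulate_subject,
)


class TestMakePriors:
    def test_no_modulation_model_has_no_b_entries(self, inversion_config):
        priors = make_priors(make_model_spec(0), inversion_config)
        assert not any(k == "B" for k in priors.layout.kinds)

    def test_full_model_has_eight_b_entries(self, full_model_priors):
        assert sum(k == "B" for k in full_model_priors.layout.kinds) == 8

    def test_exactly_one_driving_entry(self, inversion_config):
        for mid in (0, 17, 255):
            priors = make_priors(make_model_spec(mid), inversion_config)
            assert sum(k == "C" for k in priors.layout.kinds) == 1

    def test_class_variances_applied(self, full_model_priors, inversion_config):
        layout = full_model_priors.layout
        var = dict(zip(layout.kinds, full_model_priors.variance))
        assert var["A"] == inversion_config.prior_var_a
        assert var["B"] == inversion_config.prior_var_b
        assert var["self"] == inversion_config.prior_var_self

    def test_structural_zeros_absent_from_vector(self, inversion_config):
        priors = make_priors(make_model_spec(0), inversion_config)
        # 10 A + 1 C + 4 self + 4 tau
        assert priors.layout.n_params == 19
        assert all("FFA → MPFC" not in n for n in priors.layout.names)


@pytest.fixture(scope="module")
def quiet_subject(ground_truth, default_design):
    """Nearly noise-free subject simulated from the group-mean parameters."""
    return simulate_subject(
        ground_truth.group_mean_params, default_design, seed=11, noise_sd=0.01
    )


@pytest.fixture(scope="module")
def quiet_fit(quiet_subject, full_model_spec, full_model_priors, default_inputs,
              default_design, inversion_config):
    return variational_laplace(
        quiet_subject.region_ts, full_model_spec, full_model_priors,
        default_inputs, default_design, inversion_config,
    )


class TestVariationalLaplace:
    def test_free_energy_trace_is_monotone(self, quiet_fit):
        assert np.all(np.diff(quiet_fit.f_trace) >= 0)

    def test_posterior_covariance_is_spd(self, quiet_fit):
        cov = quiet_fit.posterior_cov
        np.testing.assert_allclose(cov, cov.T, atol=1e-10)
        assert np.all(np.linalg.eigvalsh(cov) > 0)

    def test_near_noise_free_recovery(self, quiet_fit, ground_truth):
        from valdcm.modelspace import connection_index

        nm = quiet_fit.named_means
        for (src, tgt), truth_val in (
            (("LPFC", "AMY"), 0.1702),
            (("AMY", "MPFC"), 0.1122),
        ):
            est = nm[f"{src} → {tgt}"]
            assert est == pytest.approx(truth_val, abs=0.03)

    def test_deterministic_given_same_data(self, quiet_fit, quiet_subject,
                                           full_model_spec, full_model_priors,
                                           default_inputs, default_design,
                                           inversion_config):
        again = variational_laplace(
            quiet_subject.region_ts, full_model_spec, full_model_priors,
            default_inputs, default_design, inversion_config,
        )
        assert again.free_energy == quiet_fit.free_energy
        np.testing.assert_array_equal(again.posterior_mean, quiet_fit.posterior_mean)
        assert log_evidence(again) == again.free_energy

    def test_resting_data_leave_self_at_prior_mean(self, default_design,
                                                   full_model_spec,
                                                   full_model_priors,
                                                   default_inputs,
                                                   inversion_config, rng):
        silent_channels = {
            k: np.zeros_like(v) for k, v in default_inputs.channels.items()
        }
        silent = InputMatrix(
            dt=default_inputs.dt, channels=silent_channels,
            n_bins=default_inputs.n_bins,
        )
        y = RegionTimeSeries(y=rng.normal(0, 0.1, size=(175, 4)))
        res = variational_laplace(
            y, full_model_spec, full_model_priors, silent, default_design,
            inversion_config,
        )
        for name, mean in res.named_means.items():
            if "(self)" in name:
                assert mean == pytest.approx(0.0, abs=1e-9)

    def test_tight_prior_shrinks_posterior_to_prior_mean(
        self, quiet_subject, full_model_spec, default_inputs, default_design
    ):
        cfg = InversionConfig(
            prior_var_a=1e-8, prior_var_b=1e-8, prior_var_c=1e-8,
            prior_var_self=1e-8, prior_var_tau=1e-8,
        )
        priors = make_priors(full_model_spec, cfg)
        res = variational_laplace(
            quiet_subject.region_ts, full_model_spec, priors, default_inputs,
            default_design, cfg,
        )
        np.testing.assert_allclose(res.posterior_mean, priors.mean, atol=1e-3)

    def test_complexity_penalises_spurious_modulation(
        self, default_design, default_inputs, inversion_config, ground_truth
    ):
        """Data from the top-down representative: its own spec out-scores the
        fully modulated spec, whose extra parameters only add complexity."""
        reps = {m.family: m for m in reduced_space("families_4_representatives")}
        td = reps["top_down"]
        full = reps["bidirectional"]
        p = ground_truth.group_mean_params
        masked_B = np.where(td.modulation_masks, p.B, 0.0)
        gen = dataclasses.replace(ground_truth.group_mean_params)
        gen = type(p)(
            A=p.A, B=masked_B, C=p.C, input_names=p.input_names,
            self_log_scale=p.self_log_scale, hemo=p.hemo,
        )
        sub = simulate_subject(gen, default_design, seed=3, noise_sd=0.02)
        fits = {}
        for spec in (td, full):
            priors = make_priors(spec, inversion_config)
            fits[spec.family] = variational_laplace(
                sub.region_ts, spec, priors, default_inputs, default_design,
                inversion_config,
            )
        assert log_evidence(fits["top_down"]) > log_evidence(fits["bidirectional"])

    def test_nonfinite_data_rejected(self, full_model_spec, full_model_priors,
                                     default_inputs, default_design,
                                     inversion_config):
        with pytest.raises(ValueError):
            RegionTimeSeries(y=np.full((175, 4), np.nan))


class TestParameterRecoveryStudy:
    def test_lpfc_to_amy_recovered_across_subjects(self, ground_truth,
                                                   default_design,
                                                   default_inputs,
                                                   full_model_spec,
                                                   full_model_priors,
                                                   inversion_config):
        """True LPFC->AMY coupling (0.1702) lands within +-0.1 for >= 80%
        of seeded subjects at the generator's default noise level."""
        hits = 0
        n_subjects = 20
        rng_seq = np.random.SeedSequence(42).spawn(n_subjects)
        for ss in rng_seq:
            rng = np.random.default_rng(ss)
            # noise-only replicates: every subject carries the group-mean coupling
            sub = simulate_subject(ground_truth.group_mean_params, default_design, rng)
            res = variational_laplace(
                sub.region_ts, full_model_spec, full_model_priors,
                default_inputs, default_design, inversion_config,
            )
            if abs(res.named_means["LPFC → AMY"] - 0.1702) <= 0.1:
                hits += 1
        assert hits >= 0.8 * n_subjects
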