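"""Variational-Laplace engine: exactness on linear models, monotonicity,
self-consistency, and modulatory-parameter recovery."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from emoconn.inversion import (
    DCMForward,
    PriorSpec,
    b_param_name,
    invert,
    log_evidence,
    variational_laplace,
)
from emoconn.model_space import build_modulatory_space, to_dcm_spec, winner_structural_model
from emoconn.synthetic_data import CohortSpec, sample_subject
from emoconn.task_design import parse_block_order


def linear_problem(rng, n=40, p=3, pi=4.0):
    X = rng.normal(size=(n, p))
    prior_var = np.array([0.5, 1.0, 0.25])
    theta_true = rng.normal(0, np.sqrt(prior_var))
    y = X @ theta_true + rng.normal(0, 1 / np.sqrt(pi), n)
    return X, y, prior_var, pi


class TestLinearGaussianReduction:
    def test_free_energy_matches_closed_form_evidence(self, rng):
        X, y, prior_var, pi = linear_problem(rng)
        res = variational_laplace(
            lambda th: X @ th,
            y,
            np.zeros(3),
            prior_var,
            fixed_noise_precision=pi,
        )
        closed = multivariate_normal.logpdf(
            y, mean=np.zeros(len(y)), cov=X @ np.diag(prior_var) @ X.T + np.eye(len(y)) / pi
        )
        assert res.free_energy == pytest.approx(closed, abs=0.1)

    def test_posterior_matches_conjugate_solution(self, rng):
        X, y, prior_var, pi = linear_problem(rng)
        res = variational_laplace(
            lambda th: X @ th, y, np.zeros(3), prior_var,
            fixed_noise_precision=pi,
        )
        H = pi * X.T @ X + np.diag(1 / prior_var)
        mean = np.linalg.solve(H, pi * X.T @ y)
        np.testing.assert_allclose(res.posterior_mean, mean, atol=1e-6)
        np.testing.assert_allclose(res.posterior_cov, np.linalg.inv(H), atol=1e-6)

    def test_posterior_variance_never_exceeds_prior_variance(self, rng):
        X, y, prior_var, pi = linear_problem(rng, n=60)
        res = variational_laplace(
            lambda th: X @ th, y, np.zeros(3), prior_var,
            fixed_noise_precision=pi,
        )
        assert np.all(np.diag(res.posterior_cov) <= prior_var + 1e-10)

    def test_joint_scaling_of_data_noise_and_prior(self, rng):
        X, y, prior_var, pi = linear_problem(rng)
        res = variational_laplace(
            lambda th: X @ th, y, np.zeros(3), prior_var,
            fixed_noise_precision=pi,
        )
        c = 3.0
        res_scaled = variational_laplace(
            lambda th: X @ th, c * y, np.zeros(3), c**2 * prior_var,
            fixed_noise_precision=pi / c**2,
        )
        np.testing.assert_allclose(
            res_scaled.posterior_mean, c * res.posterior_mean, atol=1e-6
        )

    def test_zero_prior_variance_pins_parameter(self, rng):
        X, y, prior_var, pi = linear_problem(rng)
        prior_var = prior_var.copy()
        prior_var[1] = 0.0
        res = variational_laplace(
            lambda th: X @ th, y, np.zeros(3), prior_var,
            fixed_noise_precision=pi,
        )
        assert res.posterior_mean[1] == 0.0
        assert res.posterior_cov[1, 1] == 0.0

    def test_em_noise_update_estimates_precision(self, rng):
        X, y, prior_var, pi = linear_problem(rng, n=400, pi=9.0)
        res = variational_laplace(lambda th: X @ th, y, np.zeros(3), prior_var)
        assert res.noise_precision == pytest.approx(9.0, rel=0.35)


@pytest.fixture(scope="module")
def fitted_subject():
    design = parse_block_order("NHSNHSNR", 21.0, n_volumes=76)
    cohort = CohortSpec(
        group="HC", n_subjects=2, truth_by_emotion={"sad": 21},
        seed=77, snr=2.0, weak_ofc_fraction=0.0,
    )
    rec = sample_subject(cohort, design, 0)
    models = {m.id: m for m in build_modulatory_space()}
    spec = to_dcm_spec(winner_structural_model(), models[21], "sad")
    res = invert(spec, rec.bold, design, microtime_bins=8, max_iter=48)
    return design, rec, spec, res


class TestDcmInversion:
    def test_accepted_trace_is_monotone(self, fitted_subject):
        *_, res = fitted_subject
        diffs = np.diff(res.trace)
        assert np.all(diffs >= -1e-3)

    def test_free_energy_finite_and_converged(self, fitted_subject):
        *_, res = fitted_subject
        assert np.isfinite(res.free_energy)
        assert res.converged

    def test_determinism(self, fitted_subject):
        design, rec, spec, res = fitted_subject
        res2 = invert(spec, rec.bold, design, microtime_bins=8, max_iter=48)
        assert res2.free_energy == res.free_energy
        np.testing.assert_array_equal(res2.posterior_mean, res.posterior_mean)
        assert log_evidence(res2) == res2.free_energy

    def test_posterior_covariance_is_psd(self, fitted_subject):
        *_, res = fitted_subject
        eigs = np.linalg.eigvalsh(res.posterior_cov)
        assert eigs.min() >= -1e-10

    def test_modulatory_signs_recovered(self, fitted_subject):
        design, rec, spec, res = fitted_subject
        true_b = rec.true_params.B["sad"]
        regions = spec.regions
        hits = 0
        for src, dst in spec.modulated_edges["sad"]:
            truth = true_b[spec.index(dst), spec.index(src)]
            est = res.mean_of(b_param_name("sad", src, dst))
            hits += np.sign(est) == np.sign(truth)
        assert hits >= 3  # at least 3 of 4 edges carry the right sign

    def test_noiseless_prior_mean_data_returns_prior(self):
        # data simulated at the prior mean (zero coupling, zero drive) are
        # flat; the posterior should stay at the prior mean
        design = parse_block_order("NHSR", 21.0, n_volumes=38)
        models = {m.id: m for m in build_modulatory_space()}
        spec = to_dcm_spec(winner_structural_model(), models[21], "sad")
        fwd = DCMForward(spec, design, PriorSpec(), microtime_bins=8)
        y = fwd.predict(fwd.prior_mean)
        res = invert(spec, y, design, microtime_bins=8, max_iter=16)
        assert np.isfinite(res.free_energy)
        np.testing.assert_allclose(res.posterior_mean, 0.0, atol=5e-2)

    def test_true_model_beats_null_on_modulated_data(self):
        design = parse_block_order("NHSNHSNR", 21.0, n_volumes=76)
        models = {m.id: m for m in build_modulatory_space()}
        wins = 0
        for seed in range(3):
            cohort = CohortSpec(
                group="HC", n_subjects=2, truth_by_emotion={"sad": 21},
                seed=500 + seed, snr=2.0, weak_ofc_fraction=0.0,
            )
            rec = sample_subject(cohort, design, 0)
            spec_true = to_dcm_spec(winner_structural_model(), models[21], "sad")
            spec_null = to_dcm_spec(winner_structural_model(), None)
            f_true = invert(spec_true, rec.bold, design, microtime_bins=8).free_energy
            f_null = invert(spec_null, rec.bold, design, microtime_bins=8).free_energy
            wins += (f_true - f_null) > 3.0
        assert wins >= 2

    def test_duplicated_parameter_does_not_inflate_evidence(self):
        # splitting one modulated edge across two identical modulators adds
        # redundancy; the complexity penalty must absorb it
        from emoconn.generative_model import DCMSpec
        from emoconn.task_design import build_inputs

        design = parse_block_order("NHSNHSNR", 21.0, n_volumes=76)
        cohort = CohortSpec(
            group="HC", n_subjects=2, truth_by_emotion={"sad": 2},
            seed=88, snr=2.0, weak_ofc_fraction=0.0,
        )
        rec = sample_subject(cohort, design, 0)
        win = winner_structural_model()
        edge = frozenset({("FG", "OFC")})
        spec_one = DCMSpec(
            intrinsic_edges=win.intrinsic_edges,
            modulated_edges={"sad": edge},
            driving_inputs={"faces": frozenset({"V1"})},
        )
        spec_dup = DCMSpec(
            intrinsic_edges=win.intrinsic_edges,
            modulated_edges={"sad": edge, "sad_dup": edge},
            driving_inputs={"faces": frozenset({"V1"})},
        )

        class DupInputs:
            def __init__(self, base):
                self._base = base
                self.dt_s = base.dt_s
                self.time_axis = base.time_axis

            def by_name(self, name):
                return self._base.by_name("sad" if name == "sad_dup" else name)

        from dataclasses import replace

        d8 = replace(design, microtime_bins_per_tr=8)
        inputs = DupInputs(build_inputs(d8))
        from emoconn.generative_model import legendre_drift_basis
        from emoconn.inversion import variational_laplace

        results = {}
        for name, spec in (("one", spec_one), ("dup", spec_dup)):
            fwd = DCMForward(spec, design, PriorSpec(), inputs=inputs, microtime_bins=8)
            res = variational_laplace(
                fwd.predict, rec.bold.data, fwd.prior_mean, fwd.prior_var,
                confounds=legendre_drift_basis(design.n_volumes, 2),
            )
            results[name] = res.free_energy
        assert results["dup"] <= results["one"] + 0.5

    def test_nonfinite_data_rejected(self, fitted_subject):
        design, rec, spec, _ = fitted_subject
        bad = rec.bold.data.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            invert(spec, bad, design)
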