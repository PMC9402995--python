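"""Tests of the Laplace marginal objective and population fitting."""

import math

import numpy as np
import pytest

from neobili import (
    CohortDesign,
    CovariateEffects,
    Covariates,
    PopulationModel,
    StructuralParameters,
    generate_cohort,
)
from neobili.io import Measurement, NeonateRecord
from neobili.model import (
    PARAM_NAMES,
    InvalidInputError,
    trajectory_batch,
)
from neobili.population import (
    FitConfig,
    evaluate_covariate,
    fit_population,
    marginal_objective,
)

COV = Covariates(268.0, 3100.0, "vaginal")
THETA = StructuralParameters(
    b0=45.0, p_ss=1.9, a_p=1.5, t_p=36.0, k_ss=0.035, m_e=0.9, t_e=60.0
)


def model_with(re_names, omegas, sigma=0.10, theta=THETA, beta=None):
    d = len(re_names)
    return PopulationModel(
        theta_pop=theta,
        omega=np.diag(np.asarray(omegas) ** 2) if d else np.zeros((0, 0)),
        beta=beta or CovariateEffects(),
        sigma_prop=sigma,
        random_effect_names=tuple(re_names),
    )


def record(rid, times_values, cov=COV):
    return NeonateRecord(rid, cov, tuple(Measurement(t, v) for t, v in times_values))


def simulated_measurements(model, times, rng):
    """Observations simulated from the model itself (for toy oracle checks)."""
    times = np.asarray(times, dtype=float)
    d = len(model.random_effect_names)
    eta = rng.multivariate_normal(np.zeros(d), model.omega) if d else np.zeros(0)
    base = model.base_theta(COV).copy()
    idx = [PARAM_NAMES.index(n) for n in model.random_effect_names]
    base[idx] *= np.exp(eta)
    f = trajectory_batch(base[None, :], times)[0]
    obs = np.maximum(f * (1.0 + model.sigma_prop * rng.standard_normal(times.size)), 1.0)
    return list(zip(times, obs))


def neg2_joint(model, rec, eta_grid):
    """Independent -2 log joint on an eta grid (direct formula)."""
    base = model.base_theta(rec.covariates)
    idx = [
        list(StructuralParameters.__dataclass_fields__).index(n)
        for n in model.random_effect_names
    ]
    theta = np.tile(base, (eta_grid.shape[0], 1))
    theta[:, idx] *= np.exp(eta_grid)
    f = trajectory_batch(theta, rec.times)
    sd = model.sigma_prop * f
    loglik = (((rec.values[None, :] - f) / sd) ** 2 + np.log(2 * np.pi * sd**2)).sum(
        axis=1
    )
    if eta_grid.shape[1]:
        omega_inv = np.linalg.inv(model.omega)
        _, logdet = np.linalg.slogdet(2 * np.pi * model.omega)
        loglik += np.einsum("md,dk,mk->m", eta_grid, omega_inv, eta_grid) + logdet
    return loglik


def gauss_hermite_neg2_marginal(model, rec, n_nodes=31):
    """Adaptive Gauss-Hermite oracle for the exact -2 log marginal (1-D)."""
    assert len(model.random_effect_names) == 1
    # center/scale at the joint mode (adaptive quadrature)
    grid = np.linspace(-3.0, 3.0, 4001)[:, None]
    vals = neg2_joint(model, rec, grid)
    m = float(grid[np.argmin(vals)][0])
    h = 1e-4
    pts = np.array([[m - h], [m], [m + h]])
    v = neg2_joint(model, rec, pts)
    hess = (v[0] - 2 * v[1] + v[2]) / h**2
    scale = math.sqrt(2.0 / hess)
    z, w = np.polynomial.hermite.hermgauss(n_nodes)
    eta = m + scale * z
    ln_g = -0.5 * neg2_joint(model, rec, eta[:, None])  # log p(w|eta)p(eta)
    log_terms = np.log(w) + z**2 + ln_g
    c = log_terms.max()
    integral = math.log(np.exp(log_terms - c).sum()) + c + math.log(scale)
    return -2.0 * integral


class TestMarginalObjective:
    def test_exact_likelihood_when_no_random_effects(self):
        model = model_with((), [])
        rec = record("a", [(12.0, 90.0), (30.0, 140.0), (50.0, 160.0)])
        got = marginal_objective(model, [rec])
        f = trajectory_batch(model.base_theta(COV)[None, :], rec.times)[0]
        sd = model.sigma_prop * f
        expected = float(
            (((rec.values - f) / sd) ** 2 + np.log(2 * np.pi * sd**2)).sum()
        )
        assert got == pytest.approx(expected, abs=1e-10)

    def test_matches_gauss_hermite_quadrature(self):
        rng = np.random.default_rng(31)
        rel_errs = []
        for _ in range(20):
            model = model_with(
                (rng.choice(["b0", "p_ss", "k_ss"]),),
                [rng.uniform(0.1, 0.4)],
                sigma=rng.uniform(0.05, 0.2),
            )
            rec = record("a", simulated_measurements(model, [rng.uniform(10, 70)], rng))
            laplace = marginal_objective(model, [rec])
            exact = gauss_hermite_neg2_marginal(model, rec)
            rel_errs.append(abs(laplace - exact) / abs(exact))
        assert max(rel_errs) < 0.005

    def test_duplicated_cohort_doubles_ofv(self, truth_model, small_cohort):
        records, _ = small_cohort
        sub = records[:10]
        one = marginal_objective(truth_model, sub)
        two = marginal_objective(truth_model, sub + sub)
        assert two == pytest.approx(2.0 * one, rel=1e-12)

    def test_subject_order_invariance(self, truth_model, small_cohort):
        records, _ = small_cohort
        sub = records[:15]
        a = marginal_objective(truth_model, sub)
        b = marginal_objective(truth_model, sub[::-1])
        assert abs(a - b) < 1e-9

    def test_empty_measurements_rejected(self, truth_model):
        rec = NeonateRecord("a", COV, ())
        with pytest.raises(InvalidInputError):
            marginal_objective(truth_model, [rec])

    def test_compiled_kernel_matches_numpy_reference(self, truth_model, small_cohort):
        """The accelerated per-subject objective agrees with the pure-numpy
        reference implementation to floating-point accuracy."""
        from neobili import _inference as inf

        if not inf._HAVE_NUMBA:
            pytest.skip("numba not installed; only the reference path exists")
        records, _ = small_cohort
        rng = np.random.default_rng(0)
        omega_inv, logdet = truth_model.omega_inverse()
        for rec in records[:8]:
            subj = inf.make_subject_data(
                truth_model.base_theta(rec.covariates),
                truth_model.random_effect_names,
                rec.times,
                rec.values,
            )
            eta = rng.normal(0.0, 0.3, (6, 3))
            try:
                inf._HAVE_NUMBA = True
                fast = inf.neg2_joint_batch(
                    eta, subj, truth_model.sigma_prop, omega_inv, logdet
                )
                inf._HAVE_NUMBA = False
                ref = inf.neg2_joint_batch(
                    eta, subj, truth_model.sigma_prop, omega_inv, logdet
                )
            finally:
                inf._HAVE_NUMBA = True
            assert np.allclose(fast, ref, rtol=1e-12)


class TestFitPopulation:
    def test_descent_property_and_convergence_flag(self, truth_model):
        design = CohortDesign(n_neonates=25, seed=5, measurements_exact=3)
        records, _ = generate_cohort(design, truth_model)
        init = model_with(
            ("b0", "p_ss", "k_ss"),
            [0.3, 0.3, 0.3],
            sigma=0.15,
            theta=THETA.replace(p_ss=1.5, k_ss=0.05),
            beta=truth_model.beta,
        )
        cfg = FitConfig(
            fix=frozenset({"b0", "a_p", "t_p", "m_e", "t_e"}), max_outer_iter=30
        )
        ofv_init = marginal_objective(init, records)
        res = fit_population(records, init, cfg)
        assert res.ofv <= ofv_init + 1e-9
        assert res.n_subjects == 25
        assert np.isfinite(res.ofv)
        assert set(res.eta_modes) == {r.record_id for r in records}

    def test_sigma_recovery_in_no_random_effect_limit(self, truth_model):
        """With all structure known and no random effects, the residual-error
        CV is recovered from 200x4 observations simulated at sigma = 0.10."""
        det = model_with((), [], sigma=0.10, beta=truth_model.beta)
        design = CohortDesign(n_neonates=200, seed=9, measurements_exact=4)
        # generate with no between-subject variability, only residual noise
        gen = PopulationModel(
            theta_pop=THETA,
            omega=np.diag([1e-12, 1e-12, 1e-12]),
            beta=truth_model.beta,
            sigma_prop=0.10,
            random_effect_names=("b0", "p_ss", "k_ss"),
        )
        records, _ = generate_cohort(design, gen)
        cfg = FitConfig(fix=frozenset(StructuralParameters.__dataclass_fields__))
        res = fit_population(records, model_with((), [], sigma=0.15, beta=truth_model.beta), cfg)
        assert 0.08 <= res.model.sigma_prop <= 0.12

    def test_refuses_underdetermined_problem(self, truth_model):
        rec = record("a", [(20.0, 120.0)])
        with pytest.raises(InvalidInputError):
            fit_population([rec], truth_model, FitConfig())

    def test_empty_cohort_rejected(self, truth_model):
        with pytest.raises(InvalidInputError):
            fit_population([], truth_model, FitConfig())


class TestEvaluateCovariate:
    @staticmethod
    def _simulate_and_fit(beta_ga_true, seed, n=50):
        theta = THETA
        gen = PopulationModel(
            theta_pop=theta,
            omega=np.diag([0.2**2]),
            beta=CovariateEffects(beta_ga=beta_ga_true),
            sigma_prop=0.10,
            random_effect_names=("k_ss",),
        )
        design = CohortDesign(n_neonates=n, seed=seed, measurements_exact=3)
        records, _ = generate_cohort(design, gen)
        init = PopulationModel(
            theta_pop=theta,
            omega=np.diag([0.3**2]),
            beta=CovariateEffects(),
            sigma_prop=0.10,
            random_effect_names=("k_ss",),
        )
        cfg = FitConfig(
            fix=frozenset({"b0", "a_p", "t_p", "m_e", "t_e"}), max_outer_iter=60
        )
        base = fit_population(records, init, cfg)
        base.converged = True  # descent-verified base; flag not informative here
        return records, base, cfg

    def test_null_covariate_rarely_significant(self):
        flags = []
        for seed in (101, 202, 303, 404, 505):
            records, base, cfg = self._simulate_and_fit(0.0, seed)
            dec = evaluate_covariate(records, base, "beta_ga", cfg)
            flags.append(dec.significant)
            assert dec.delta_ofv >= -0.5  # nested refit cannot get much worse
        assert sum(flags) <= 1

    def test_strong_covariate_detected(self):
        for seed in (7, 8):
            records, base, cfg = self._simulate_and_fit(3.0, seed)
            dec = evaluate_covariate(records, base, "beta_ga", cfg)
            assert dec.significant
            assert dec.delta_ofv > 3.84
            # explained variability: the k_ss random-effect variance shrinks
            assert dec.delta_random_effect_variance is not None
            assert dec.delta_random_effect_variance > 0

    def test_variance_criterion_not_applicable_without_random_effect(self, truth_model):
        gen = model_with((), [], sigma=0.10, beta=CovariateEffects())
        design = CohortDesign(n_neonates=30, seed=3, measurements_exact=3)
        records, _ = generate_cohort(design, truth_model)
        cfg = FitConfig(fix=frozenset({"b0", "a_p", "t_p", "m_e", "t_e"}))
        base = fit_population(records, gen, cfg)
        base.converged = True
        dec = evaluate_covariate(records, base, "beta_bw", cfg)
        assert dec.delta_random_effect_variance is None
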