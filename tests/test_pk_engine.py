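"""Compartmental predictions, FOCE-I likelihood, fitting and diagnostics."""

import numpy as np
import pandas as pd
import pytest

import pkmoo
from pkmoo.pk_engine import (
    ModelSpec,
    ParameterVector,
    PKDataset,
    _disposition_eig,
    condition_number,
    correlation_flag,
    marginal_neg2loglik,
    neg2loglik,
    predict,
)


class TestStructuralPredictions:
    def test_iv_bolus_initial_concentration_is_dose_over_volume(self):
        spec = ModelSpec(1, "iv_bolus")
        pv = ParameterVector({"CL": 5.0, "V": 50.0}, sigma={"SIG_PROP": 0.01})
        c = predict(spec, pv, {}, [(0.0, 100.0)], [0.0])
        assert c[0] == pytest.approx(100.0 / 50.0)

    def test_oral_matches_bateman_closed_form(self):
        spec = ModelSpec(1, "oral_first_order")
        cl, v, ka, dose = 3.7, 42.0, 1.7, 250.0
        pv = ParameterVector({"CL": cl, "V": v, "KA": ka}, sigma={"SIG_ADD": 1.0})
        rng = np.random.default_rng(2)
        t = np.sort(rng.uniform(0.05, 30, 10))
        k = cl / v
        bateman = dose * ka / (v * (ka - k)) * (np.exp(-k * t) - np.exp(-ka * t))
        got = predict(spec, pv, {}, [(0.0, dose)], t)
        np.testing.assert_allclose(got, bateman, rtol=1e-8)

    def test_dose_superposition(self):
        spec = ModelSpec(2, "oral_first_order")
        pv = ParameterVector(
            {"CL": 5.0, "V": 50.0, "Q2": 8.0, "V2": 120.0, "KA": 1.0},
            sigma={"SIG_ADD": 1.0},
        )
        t = np.linspace(0.5, 36, 20)
        both = predict(spec, pv, {}, [(0.0, 100.0), (12.0, 100.0)], t)
        one = predict(spec, pv, {}, [(0.0, 100.0)], t)
        two = predict(spec, pv, {}, [(12.0, 100.0)], t)
        np.testing.assert_allclose(both, one + two, rtol=1e-10)

    def test_matrix_exponential_path_matches_hand_coded_closed_forms(self):
        """The general eigen/expm engine vs hand-coded 1- and 2-cpt solutions."""
        rng = np.random.default_rng(7)
        t = np.linspace(0.1, 48, 25)
        for _ in range(100):
            cl, v = rng.uniform(1, 20), rng.uniform(10, 200)
            q2, v2 = rng.uniform(1, 20), rng.uniform(20, 400)
            k, k12, k21 = cl / v, q2 / v, q2 / v2
            # 2-compartment IV bolus bi-exponential macro constants
            s = k + k12 + k21
            disc = np.sqrt(s**2 - 4 * k * k21)
            alpha, beta = (s + disc) / 2, (s - disc) / 2
            A = (alpha - k21) / (alpha - beta) / v
            B = (k21 - beta) / (alpha - beta) / v
            closed2 = 100.0 * (A * np.exp(-alpha * t) + B * np.exp(-beta * t))
            got2 = _disposition_eig(
                {"CL": cl, "V": v, "Q2": q2, "V2": v2}, 2, False,
                np.array([0.0]), np.array([100.0]), t,
            )
            np.testing.assert_allclose(got2, closed2, rtol=1e-8)
            closed1 = 100.0 / v * np.exp(-k * t)
            got1 = _disposition_eig(
                {"CL": cl, "V": v}, 1, False, np.array([0.0]), np.array([100.0]), t
            )
            np.testing.assert_allclose(got1, closed1, rtol=1e-8)

    def test_lag_shifts_absorption(self):
        spec = ModelSpec(1, "oral_first_order", lag=True)
        pv = ParameterVector(
            {"CL": 5.0, "V": 50.0, "KA": 1.0, "ALAG": 2.0}, sigma={"SIG_ADD": 1.0}
        )
        nolag = ModelSpec(1, "oral_first_order")
        pv0 = ParameterVector({"CL": 5.0, "V": 50.0, "KA": 1.0}, sigma={"SIG_ADD": 1.0})
        t = np.array([1.0, 3.0, 8.0])
        got = predict(spec, pv, {}, [(0.0, 100.0)], t)
        ref = predict(nolag, pv0, {}, [(2.0, 100.0)], t)
        np.testing.assert_allclose(got, ref, rtol=1e-10)
        assert got[0] == 0.0  # before lag ends

    def test_predictions_nonnegative_and_vanish_at_late_times(self):
        spec = ModelSpec(3, "oral_first_order")
        pv = ParameterVector(
            {"CL": 5, "V": 50, "Q2": 4, "V2": 80, "Q3": 1, "V3": 200, "KA": 0.9},
            sigma={"SIG_ADD": 1.0},
        )
        c = predict(spec, pv, {}, [(0.0, 100.0)], np.linspace(0, 5000, 40))
        assert np.all(c >= 0)
        assert c[-1] < 1e-8

    def test_nonpositive_parameters_rejected(self):
        spec = ModelSpec(1, "iv_bolus")
        pv = ParameterVector({"CL": -1.0, "V": 50.0}, sigma={"SIG_ADD": 1.0})
        with pytest.raises(ValueError):
            predict(spec, pv, {}, [(0.0, 100.0)], [1.0])

    def test_covariate_forms_scale_parameters(self):
        base = ParameterVector(
            {"CL": 5.0, "V": 50.0, "B_CL_WT_power": 0.75}, sigma={"SIG_ADD": 1.0}
        )
        spec = ModelSpec(
            1, "iv_bolus",
            covariate_effects=(pkmoo.CovariateEffect("CL", "WT", "power"),),
        )
        t = np.array([4.0])
        heavy = predict(spec, base, {"WT": 100.0}, [(0.0, 100.0)], t, {"WT": 70.0})
        ref = predict(spec, base, {"WT": 70.0}, [(0.0, 100.0)], t, {"WT": 70.0})
        # higher weight -> higher CL -> lower late concentration
        assert heavy[0] < ref[0]
        scaled = ParameterVector({"CL": 5.0 * (100 / 70) ** 0.75, "V": 50.0},
                                 sigma={"SIG_ADD": 1.0})
        direct = predict(ModelSpec(1, "iv_bolus"), scaled, {}, [(0.0, 100.0)], t)
        np.testing.assert_allclose(heavy, direct, rtol=1e-12)


class TestLikelihood:
    def test_collapses_to_weighted_least_squares_without_random_effects(self):
        sc = pkmoo.rich_oral_scenario(n_subjects=4, rng_seed=1, with_covariates=False)
        ds, _ = pkmoo.generate_dataset(sc)
        spec0 = ModelSpec(1, "oral_first_order", ruv="additive")
        pv = ParameterVector({"CL": 5.0, "V": 50.0, "KA": 1.2}, sigma={"SIG_ADD": 0.3})
        got = neg2loglik(spec0, pv, ds)
        expected = 0.0
        for s in ds.subjects():
            f = predict(spec0, pv, s.covariates,
                        list(zip(s.dose_times, s.dose_amts)), s.obs_times)
            expected += np.sum(np.log(0.3) + (s.y - f) ** 2 / 0.3)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_matches_closed_form_linear_mixed_model(self):
        """FOCE-I is exact when the prediction is linear in eta."""
        rng = np.random.default_rng(11)
        theta, om2, sig2 = 2.0, 0.25, 0.09
        total, closed = 0.0, 0.0
        for _ in range(12):
            t = np.sort(rng.uniform(0.5, 10, 6))
            eta_true = rng.normal(0, np.sqrt(om2))
            y = (theta + eta_true) * t + rng.normal(0, np.sqrt(sig2), len(t))
            val, _ = marginal_neg2loglik(
                y,
                lambda e, _t=t: (theta + e[0]) * _t,
                np.array([om2]),
                lambda pred: np.full_like(pred, sig2),
            )
            total += val
            V = om2 * np.outer(t, t) + sig2 * np.eye(len(t))
            r = y - theta * t
            sign, logdet = np.linalg.slogdet(V)
            closed += logdet + r @ np.linalg.solve(V, r)
        assert total == pytest.approx(closed, rel=1e-6)

    def test_generating_parameters_beat_perturbed_parameters(self):
        wins = 0
        for seed in range(20):
            sc = pkmoo.rich_oral_scenario(
                n_subjects=8, rng_seed=seed, with_covariates=False
            )
            ds, _ = pkmoo.generate_dataset(sc)
            truth = sc.truth_params
            worse = ParameterVector(
                {k: 1.5 * v for k, v in truth.theta.items()},
                dict(truth.omega),
                dict(truth.sigma),
            )
            if neg2loglik(sc.truth_spec, truth, ds) < neg2loglik(
                sc.truth_spec, worse, ds
            ):
                wins += 1
        assert wins >= 18

    def test_invariant_to_subject_ordering(self, rich_small):
        sc, ds = rich_small
        ref = neg2loglik(sc.truth_spec, sc.truth_params, ds)
        ids = ds.df["ID"].unique()
        rng = np.random.default_rng(0)
        order = rng.permutation(ids)
        shuffled = pd.concat(
            [ds.df[ds.df["ID"] == i] for i in order], ignore_index=True
        )
        got = neg2loglik(sc.truth_spec, sc.truth_params, PKDataset(shuffled))
        assert got == pytest.approx(ref, abs=1e-6)

    def test_residual_variance_inflation_worsens_fit(self, rich_small):
        sc, ds = rich_small
        truth = sc.truth_params
        inflated = ParameterVector(
            dict(truth.theta), dict(truth.omega),
            {k: 10 * v for k, v in truth.sigma.items()},
        )
        assert neg2loglik(sc.truth_spec, truth, ds) <= neg2loglik(
            sc.truth_spec, inflated, ds
        )


class TestFit:
    def test_recovers_generating_parameters(self, rich_small, rich_small_fit):
        sc, _ = rich_small
        fr = rich_small_fit
        assert fr.converged
        for name in ("CL", "V", "KA"):
            err = abs(fr.estimates.theta[name] - sc.truth_params.theta[name])
            assert err / sc.truth_params.theta[name] < 0.15

    def test_fit_is_deterministic(self, rich_small, rich_small_fit):
        sc, ds = rich_small
        again = pkmoo.fit(sc.truth_spec, ds)
        assert again.ofv == rich_small_fit.ofv
        assert again.estimates.theta == rich_small_fit.estimates.theta
        assert again.converged == rich_small_fit.converged

    def test_covariance_step_products(self, rich_small_fit):
        fr = rich_small_fit
        assert fr.covariance_ok
        C = fr.correlation_matrix
        np.testing.assert_allclose(np.diag(C), 1.0)
        np.testing.assert_allclose(C, C.T)
        assert fr.condition_number >= 1.0
        assert set(fr.rse) == set(fr.param_names)
        assert all(v > 0 for v in fr.rse.values())


class TestDiagnostics:
    def test_condition_number_identity(self):
        assert condition_number(np.eye(4)) == pytest.approx(1.0)

    def test_condition_number_two_by_two(self):
        C = np.array([[1.0, 0.95], [0.95, 1.0]])
        assert condition_number(C) == pytest.approx(39.0, rel=1e-12)

    def test_condition_number_matches_independent_eigen_routine(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(5, 5))
        cov = A @ A.T + 5 * np.eye(5)
        d = np.sqrt(np.diag(cov))
        C = cov / np.outer(d, d)
        sv = np.linalg.svd(C, compute_uv=False)  # symmetric PSD: sv == eigvals
        assert condition_number(C) == pytest.approx(sv[0] / sv[-1], rel=1e-10)

    def test_condition_number_requires_symmetry(self):
        with pytest.raises(ValueError):
            condition_number(np.array([[1.0, 0.2], [0.4, 1.0]]))

    @pytest.mark.parametrize(
        "off,expected", [(0.96, True), (0.95, False), (0.0, False)]
    )
    def test_correlation_flag_is_strict(self, off, expected):
        C = np.array([[1.0, off], [off, 1.0]])
        assert correlation_flag(C) is expected


class TestDataset:
    def test_csv_round_trip_with_missing_dv(self, tmp_path, rich_small):
        _, ds = rich_small
        path = tmp_path / "data.csv"
        ds.to_csv(str(path))
        txt = path.read_text()
        assert ",.\n" in txt  # dose rows carry '.' in the DV column
        back = PKDataset.from_csv(str(path))
        pd.testing.assert_frame_equal(
            back.df.reset_index(drop=True), ds.df.reset_index(drop=True)
        )

    def test_time_ordering_enforced(self):
        df = pd.DataFrame(
            {
                "ID": [1, 1], "TIME": [5.0, 1.0], "AMT": [100.0, 0.0],
                "EVID": [1, 0], "MDV": [1, 0], "DV": [np.nan, 1.0],
            }
        )
        with pytest.raises(pkmoo.ConfigurationError, match="TIME"):
            PKDataset(df)
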