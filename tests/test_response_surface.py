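"""Quadratic surface fitting: term expansion, transform selection, stepwise."""

import numpy as np
import pytest

from vicombo.design import full_factorial
from vicombo.response_surface import (
    ModelError,
    adjusted_r2,
    boxcox_select,
    expand_terms,
    fit_response_surface,
    inverse_power_transform,
    outlier_scan,
    power_transform,
    stepwise_fit,
)
from vicombo.synthetic import NoiseModel, simulate_design_responses, TrueSurface


class TestExpandTerms:
    def test_basis_size(self, oacd):
        X, terms = expand_terms(oacd)
        assert X.shape[1] == len(terms) == 45  # 1 + 8 + 8 + C(8,2)

    def test_all_l0_row(self):
        X, _ = expand_terms(np.zeros((1, 8), dtype=int))
        assert X[0, 0] == 1.0 and np.all(X[0, 1:] == 0.0)

    def test_bilinear_column_at_l1(self):
        run = np.zeros((1, 8), dtype=int)
        run[0, 2] = run[0, 5] = 1  # coded 0.5 each
        X, terms = expand_terms(run)
        j = next(i for i, t in enumerate(terms) if t.kind == "bilinear" and t.drugs == (2, 5))
        assert X[0, j] == pytest.approx(0.25)


class TestBoxCoxSelect:
    def test_square_law_data_selects_2(self, oacd, coded):
        X, _ = expand_terms(oacd)
        Xo = X[: oacd.n_runs]
        y = np.sqrt(20 + 30 * Xo[:, 1] + 10 * Xo[:, 4])
        lam, shift = boxcox_select(y, Xo, (0.5, 1.0, 2.0))
        assert lam == 2.0 and shift == 0.0

    def test_linear_data_selects_identity(self, oacd):
        X, _ = expand_terms(oacd)
        y = 20 + 30 * X[:, 1]
        lam, _ = boxcox_select(y, X, (0.5, 1.0, 2.0))
        assert lam == 1.0

    def test_constant_responses_return_identity(self, oacd):
        X, _ = expand_terms(oacd)
        lam, _ = boxcox_select(np.full(X.shape[0], 7.0), X, (0.5, 1.0, 2.0))
        assert lam == 1.0

    def test_empty_candidate_list_rejected(self, oacd):
        X, _ = expand_terms(oacd)
        with pytest.raises(ModelError):
            boxcox_select(np.ones(X.shape[0]), X, ())

    def test_nonpositive_responses_shifted(self, oacd):
        X, _ = expand_terms(oacd)
        y = 10 * X[:, 1] - 3.0
        lam, shift = boxcox_select(y, X, (0.5, 1.0, 2.0))
        assert shift == pytest.approx(1.0 - y.min())


class TestStepwise:
    def test_noiseless_sparse_recovery(self, oacd, drugs):
        X, terms = expand_terms(oacd)
        j12 = next(
            i for i, t in enumerate(terms) if t.kind == "bilinear" and t.drugs == (1, 2)
        )
        y = 2.0 + 3.0 * X[:, 1] - 4.0 * X[:, j12]
        model = stepwise_fit(X, y, terms, drugs)
        kinds = {(t.kind, t.drugs) for t in model.terms}
        assert kinds == {("intercept", ()), ("linear", (0,)), ("bilinear", (1, 2))}
        oracle = np.linalg.lstsq(X[:, [0, 1, j12]], y, rcond=None)[0]
        assert np.allclose(np.sort(model.coefficients), np.sort(oracle), atol=1e-6)
        assert model.adj_r2 == pytest.approx(1.0)

    def test_row_order_invariance(self, oacd, drugs):
        X, terms = expand_terms(oacd)
        rng = np.random.default_rng(4)
        y = 5.0 + 10.0 * X[:, 3] + rng.normal(0, 5, X.shape[0])
        m1 = stepwise_fit(X, y, terms, drugs)
        perm = rng.permutation(X.shape[0])
        m2 = stepwise_fit(X[perm], y[perm], terms, drugs)
        assert m1.terms == m2.terms
        assert np.allclose(m1.coefficients, m2.coefficients)

    def test_null_false_selection_rate(self, oacd, drugs):
        # Monte-Carlo null: with 44 candidate terms and p_enter=0.05 the
        # mean number of falsely entered terms over 200 seeds should sit
        # within one per-run binomial SD of 44 * 0.05 = 2.2
        X, terms = expand_terms(oacd)
        rng = np.random.default_rng(0)
        counts = [
            len(stepwise_fit(X, rng.normal(0, 1, X.shape[0]), terms, drugs).terms) - 1
            for _ in range(200)
        ]
        expected = 44 * 0.05
        binom_sd = np.sqrt(44 * 0.05 * 0.95)
        assert abs(np.mean(counts) - expected) <= binom_sd

    def test_p_enter_above_p_remove_rejected(self, oacd, drugs):
        X, terms = expand_terms(oacd)
        with pytest.raises(ModelError):
            stepwise_fit(X, np.ones(X.shape[0]), terms, drugs, p_enter=0.2, p_remove=0.1)


class TestAdjustedR2:
    def test_hand_computed_example(self):
        # n=4, p=2, SSE=2, SST=10 -> 1 - (2/2)/(10/3) = 0.7
        assert adjusted_r2(2.0, 10.0, 4, 2) == pytest.approx(0.7)

    def test_perfect_fit(self):
        assert adjusted_r2(0.0, 10.0, 10, 3) == 1.0

    def test_intercept_only_is_zero(self):
        assert adjusted_r2(10.0, 10.0, 10, 1) == pytest.approx(0.0)


class TestOutlierScan:
    def test_clean_data_empty_report(self, oacd):
        X, _ = expand_terms(oacd)
        rng = np.random.default_rng(1)
        y = 10 + 5 * X[:, 1] + rng.normal(0, 1, X.shape[0])
        rep = outlier_scan(X[:, :10], y)
        assert rep.flagged == ()

    def test_perturbed_run_flagged(self, oacd):
        X, _ = expand_terms(oacd)
        rng = np.random.default_rng(2)
        y = 10 + 5 * X[:, 1] + rng.normal(0, 10, X.shape[0])
        y[17] += 100.0  # +10 well SDs
        rep = outlier_scan(X[:, :10], y)
        assert 17 in rep.flagged

    def test_infinite_threshold_flags_nothing(self, oacd):
        X, _ = expand_terms(oacd)
        y = np.arange(X.shape[0], dtype=float)
        rep = outlier_scan(X[:, :10], y, threshold=np.inf)
        assert rep.flagged == ()

    def test_refit_after_zero_outliers_is_noop(self, oacd, drugs):
        X, terms = expand_terms(oacd)
        rng = np.random.default_rng(0)
        y = 10 + 20 * X[:, 2] + rng.normal(0, 5, X.shape[0])
        m1 = stepwise_fit(X, y, terms, drugs)
        sel = [terms.index(t) for t in m1.terms]
        rep = outlier_scan(X, y, selected_columns=sel)
        assert rep.flagged == ()
        keep = [i for i in range(len(y)) if i not in rep.flagged]
        m2 = stepwise_fit(X[keep], y[keep], terms, drugs)
        assert rep.flagged == ()
        assert m1.terms == m2.terms
        assert np.allclose(m1.coefficients, m2.coefficients)


class TestTransformRoundTrip:
    def test_square_warp_round_trip(self, screen_design, drugs):
        # generator warps through exponent 2; fitting with the same
        # exponent reproduces noiseless training responses to 1e-6
        surf = TrueSurface(
            drugs,
            intercept=25.0,
            linear=(10.0, 0.0, 0.0, 6.0, 0.0, 0.0, 0.0, 0.0),
            quadratic=(0.0,) * 8,
            bilinear={(0, 3): 30.0},
            transform_exponent=2.0,
        )
        tab = simulate_design_responses(surf, screen_design, NoiseModel(0.0, 1, 0))
        y = tab["response_pct"].to_numpy()
        model = fit_response_surface(
            tab[list(drugs)].to_numpy(), y, drugs, candidate_lambdas=(0.5, 1.0, 2.0)
        )
        assert model.transform_lambda == 2.0
        pred = model.predict(screen_design.runs)
        assert np.allclose(pred, y, atol=1e-6)

    def test_power_transform_inverse(self):
        z = np.array([-4.0, 0.0, 9.0])
        back = inverse_power_transform(z, 2.0)
        assert back.tolist() == [0.0, 0.0, 3.0]  # imaginary roots -> 0
        y = np.array([0.5, 2.0, 7.0])
        assert np.allclose(inverse_power_transform(power_transform(y, 0.5), 0.5), y)
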