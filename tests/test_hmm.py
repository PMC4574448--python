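"""HMM machinery: likelihood, EM fitting, decoding, model comparison."""

import math

import numpy as np
import pytest

from conftest import enum_best_path, enum_log_likelihood
from moodregimes import (
    HMMFit,
    HMMParameters,
    ValidationError,
    binomial_log_pmf,
    compare_models,
    count_free_parameters,
    fit_hmm,
    fit_hmm_many,
    forward_backward,
    information_criteria,
    log_likelihood,
    mode_distance,
    simulate_markov_binomial,
    viterbi_path,
)
from moodregimes.series import SymptomSeries


def _params(pi, A, p, m=9):
    return HMMParameters(trials_m=m, initial_pi=pi, transition_A=A, emission_p=p)


def _dummy_fit(K, bic, pid="x", theta=None, m=9):
    p = np.linspace(0.1, 0.8, K)
    params = _params(np.full(K, 1.0 / K), np.full((K, K), 1.0 / K), p, m)
    theta = np.asarray(theta) if theta is not None else m * p
    return HMMFit(
        patient_id=pid,
        params=params,
        logl=-100.0,
        nfree=count_free_parameters(K),
        aic=0.0,
        bic=bic,
        modes_theta=theta,
        mode_distance=float(abs(theta[1] - theta[0])) if K == 2 else None,
        stay_probabilities=np.full(K, 1.0 / K),
        converged=True,
        n_restarts_used=1,
    )


class TestBinomialLogPmf:
    @pytest.mark.parametrize(
        "count,m,p,expected",
        [
            (9, 9, 0.5, 9 * math.log(0.5)),
            (0, 9, 0.0, 0.0),  # certain outcome
            (9, 9, 1.0, 0.0),
            (1, 9, 0.0, -math.inf),  # impossible outcome
        ],
    )
    def test_limits(self, count, m, p, expected):
        assert binomial_log_pmf(count, m, p) == expected

    def test_matches_factorial_arithmetic(self):
        for count, m, p in [(3, 9, 0.3), (7, 9, 0.81), (4, 6, 0.5)]:
            comb = math.factorial(m) // (
                math.factorial(count) * math.factorial(m - count)
            )
            expected = math.log(comb * p**count * (1 - p) ** (m - count))
            assert binomial_log_pmf(count, m, p) == pytest.approx(
                expected, rel=1e-12
            )

    def test_out_of_range_count_rejected(self):
        with pytest.raises(ValidationError):
            binomial_log_pmf(10, 9, 0.5)
        with pytest.raises(ValidationError):
            binomial_log_pmf(-1, 9, 0.5)


class TestLikelihood:
    def test_single_state_reduces_to_iid_sum(self):
        x = np.array([0, 3, 9, 2, 2, 5, 1])
        params = _params([1.0], [[1.0]], [0.37])
        expected = sum(binomial_log_pmf(int(c), 9, 0.37) for c in x)
        assert log_likelihood(x, params) == pytest.approx(expected, rel=1e-12)

    def test_matches_exhaustive_enumeration(self):
        """Forward recursion against brute-force summation over all paths."""
        rng = np.random.default_rng(7)
        for K in (2, 3):
            for _ in range(4):
                T = int(rng.integers(2, 7))
                x = rng.integers(0, 10, size=T)
                pi = rng.dirichlet(np.ones(K))
                A = rng.dirichlet(np.ones(K), size=K)
                p = rng.uniform(0.05, 0.95, size=K)
                params = _params(pi, A, p)
                expected = enum_log_likelihood(x, params)
                assert log_likelihood(x, params) == pytest.approx(
                    expected, abs=1e-10
                )
                logl_fb, gamma, xi = forward_backward(x, params)
                assert logl_fb == pytest.approx(expected, abs=1e-10)
                np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-10)
                # pairwise posteriors marginalise back to the state posteriors
                np.testing.assert_allclose(
                    xi.sum(axis=2), gamma[:-1], atol=1e-8
                )
                np.testing.assert_allclose(xi.sum(axis=1), gamma[1:], atol=1e-8)

    def test_degenerate_chain_equals_single_state(self):
        x = np.array([1, 0, 2, 4, 0, 1])
        two = _params([1.0, 0.0], np.eye(2), [0.2, 0.9])
        one = _params([1.0], [[1.0]], [0.2])
        assert log_likelihood(x, two) == pytest.approx(
            log_likelihood(x, one), rel=1e-12
        )

    def test_label_swap_leaves_likelihood_unchanged(self):
        x = np.array([0, 5, 9, 2, 1, 7, 8, 0])
        pi = np.array([0.3, 0.7])
        A = np.array([[0.8, 0.2], [0.4, 0.6]])
        p = np.array([0.1, 0.7])
        swapped = _params(pi[::-1], A[::-1, ::-1], p[::-1])
        assert log_likelihood(x, _params(pi, A, p)) == pytest.approx(
            log_likelihood(x, swapped), rel=1e-12
        )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError, match="row 1"):
            _params([0.5, 0.5], [[0.9, 0.1], [0.3, 0.3]], [0.1, 0.9])
        with pytest.raises(ValidationError):
            _params([0.5, 0.4], [[0.9, 0.1], [0.3, 0.7]], [0.1, 0.9])


class TestInformationCriteria:
    def test_zero_case(self):
        assert information_criteria(0.0, 0, 10) == (0.0, 0.0)

    def test_formulas(self):
        aic, bic = information_criteria(-123.4, 5, 104)
        assert aic == pytest.approx(-2 * -123.4 + 10)
        assert bic == pytest.approx(-2 * -123.4 + 5 * math.log(104))

    @pytest.mark.parametrize("K,expected", [(1, 1), (2, 5), (3, 11)])
    def test_free_parameter_count(self, K, expected):
        assert count_free_parameters(K) == expected


class TestFitting:
    def test_one_state_em_equals_closed_form(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            x = rng.integers(0, 10, size=104)
            series = SymptomSeries("a", x)
            fit = fit_hmm(series, 1, n_restarts=3, seed=0)
            p_hat = x.sum() / (9.0 * x.size)
            assert fit.params.emission_p[0] == pytest.approx(p_hat, abs=1e-12)
            expected = sum(binomial_log_pmf(int(c), 9, p_hat) for c in x)
            assert fit.logl == pytest.approx(expected, rel=1e-12)

    def test_two_state_on_all_zero_series_degenerates(self):
        series = SymptomSeries("z", np.zeros(60, dtype=int))
        fit2 = fit_hmm(series, 2, n_restarts=3, seed=0)
        fit1 = fit_hmm(series, 1, n_restarts=1, seed=0)
        assert (fit2.params.emission_p <= 1e-6 + 1e-12).all()
        assert fit2.logl == pytest.approx(fit1.logl, abs=1e-6)

    def test_em_loglik_history_monotone(self):
        cohort = simulate_markov_binomial(3, T=104, seed=5)
        flatish = SymptomSeries("f", np.random.default_rng(0).binomial(9, 0.4, 104))
        for s in list(cohort) + [flatish]:
            for K in (1, 2):
                fit = fit_hmm(s, K, n_restarts=3, seed=1, track_history=True)
                diffs = np.diff(fit.logl_history)
                assert (diffs >= -1e-9).all()

    def test_states_relabelled_ascending(self, two_regime_fits):
        _, fits2 = two_regime_fits
        for fit in fits2[:20]:
            assert fit.params.emission_p[0] <= fit.params.emission_p[1]

    def test_batched_fit_matches_per_series_fit(self):
        cohort = simulate_markov_binomial(5, T=80, seed=21)
        batch = fit_hmm_many(cohort, 2, n_restarts=3, seed=9)
        for s, fb in zip(cohort, batch):
            fs = fit_hmm(s, 2, n_restarts=3, seed=9)
            assert fs.logl == pytest.approx(fb.logl, abs=1e-12)
            np.testing.assert_allclose(
                fs.params.emission_p, fb.params.emission_p, atol=1e-12
            )

    def test_too_short_series_rejected(self):
        with pytest.raises(ValidationError):
            fit_hmm(SymptomSeries("s", [3]), 2)


class TestViterbi:
    def test_single_state_path_is_constant(self):
        params = _params([1.0], [[1.0]], [0.4])
        path = viterbi_path(np.array([1, 2, 3, 4]), params)
        assert (path == 0).all()

    def test_matches_enumeration_argmax(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.integers(0, 10, size=5)
            pi = rng.dirichlet(np.ones(2))
            A = rng.dirichlet(np.ones(2), size=2)
            p = rng.uniform(0.05, 0.95, size=2)
            params = _params(pi, A, p)
            _, best = enum_best_path(x, params)
            assert tuple(viterbi_path(x, params)) == best

    def test_ties_break_toward_lower_state(self):
        # identical emissions and symmetric chain: every path is equally
        # probable, so the decoded path must stay in state 0
        params = _params([0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]], [0.4, 0.4])
        path = viterbi_path(np.array([2, 5, 3, 7]), params)
        assert (path == 0).all()

    def test_decodes_well_separated_regimes(self, two_regime_cohort, two_regime_fits):
        _, fits2 = two_regime_fits
        accs = []
        for s, fit in zip(two_regime_cohort[:100], fits2[:100]):
            decoded = viterbi_path(s, fit.params)
            accs.append(np.mean(decoded == s.true_states))
        assert np.median(accs) > 0.90


class TestComparison:
    def test_bic_selection_from_published_style_values(self):
        # strong 1-state case and strong 2-state case
        c = compare_models(_dummy_fit(1, 322.42), _dummy_fit(2, 340.99))
        assert c.selected_K == 1
        c = compare_models(_dummy_fit(1, 298.84), _dummy_fit(2, 167.73))
        assert c.selected_K == 2
        assert c.delta_bic == pytest.approx(298.84 - 167.73)

    def test_tie_prefers_parsimony(self):
        c = compare_models(_dummy_fit(1, 300.0), _dummy_fit(2, 300.0))
        assert c.selected_K == 1

    def test_mismatched_series_rejected(self):
        with pytest.raises(ValidationError):
            compare_models(_dummy_fit(1, 1.0, pid="a"), _dummy_fit(2, 2.0, pid="b"))

    def test_mode_distance(self):
        fit = _dummy_fit(2, 0.0, theta=[0.03, 7.18])
        assert mode_distance(fit) == pytest.approx(7.15)
        assert mode_distance(_dummy_fit(2, 0.0, theta=[4.4, 4.4])) == 0.0
        with pytest.raises(ValidationError):
            mode_distance(_dummy_fit(1, 0.0))

    def test_clamped_extreme_probabilities_span_the_scale(self):
        fit = _dummy_fit(2, 0.0, theta=np.array([9 * 1e-6, 9 * (1 - 1e-6)]))
        # distance is exactly 9 - 2 * 9e-6, so allow a little beyond that
        assert mode_distance(fit) == pytest.approx(9.0, abs=3 * 9 * 1e-6)
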