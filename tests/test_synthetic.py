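"""Synthetic cohort generators: reproducibility, bounds, distributions."""

import numpy as np
import pytest

from moodregimes import (
    ValidationError,
    simulate_cohort,
    simulate_flatline,
    simulate_markov_binomial,
    simulate_network_cohort,
    simulate_smooth_severity,
    simulate_symptom_network,
)


GENERATORS = [
    lambda seed: simulate_markov_binomial(5, T=52, seed=seed),
    lambda seed: simulate_smooth_severity(5, T=52, seed=seed),
    lambda seed: simulate_flatline(5, T=52, emission_p=0.3, seed=seed),
    lambda seed: simulate_network_cohort(5, T=52, seed=seed),
]


@pytest.mark.parametrize("make", GENERATORS)
def test_bounds_length_and_bit_reproducibility(make):
    a = make(123)
    b = make(123)
    c = make(124)
    for s in a:
        assert s.T == 52
        assert s.counts.min() >= 0 and s.counts.max() <= s.trials_m
    assert all((x.counts == y.counts).all() for x, y in zip(a, b))
    assert any((x.counts != y.counts).any() for x, y in zip(a, c))


class TestMarkovBinomial:
    def test_absorbing_degenerate_state_yields_all_zeros(self):
        cohort = simulate_markov_binomial(
            3,
            T=40,
            initial=(1.0, 0.0),
            transition=np.eye(2),
            emission_p=(0.0, 0.9),
            seed=0,
        )
        for s in cohort:
            assert (s.counts == 0).all()
            assert (s.true_states == 0).all()

    def test_single_state_moments_match_binomial(self):
        # >= 10^4 draws: empirical mean/variance near m p and m p (1-p)
        cohort = simulate_markov_binomial(
            100, T=104, initial=[1.0], transition=[[1.0]], emission_p=[0.5], seed=8
        )
        counts = np.concatenate([s.counts for s in cohort])
        n = counts.size
        se_mean = np.sqrt(9 * 0.25 / n)
        assert abs(counts.mean() - 4.5) < 4 * se_mean
        assert counts.var() == pytest.approx(9 * 0.25, rel=0.1)

    def test_non_stochastic_transition_names_offending_row(self):
        with pytest.raises(ValidationError, match="row 1"):
            simulate_markov_binomial(
                1, transition=[[0.9, 0.1], [0.2, 0.2]], seed=0
            )

    def test_state_paths_are_retained(self):
        (s,) = simulate_markov_binomial(1, T=30, seed=4)
        assert s.true_states is not None and s.true_states.size == 30


class TestSmoothSeverity:
    def test_degenerate_latent_process_is_iid_binomial(self):
        cohort = simulate_smooth_severity(
            100, T=104, ar_phi=0.0, innovation_sd=0.0, baseline_logit=0.0, seed=9
        )
        counts = np.concatenate([s.counts for s in cohort])
        se_mean = np.sqrt(9 * 0.25 / counts.size)
        assert abs(counts.mean() - 4.5) < 4 * se_mean

    @pytest.mark.parametrize("phi", [1.0, -1.0, 1.5])
    def test_nonstationary_ar_rejected(self, phi):
        with pytest.raises(ValidationError):
            simulate_smooth_severity(1, ar_phi=phi)

    def test_deeply_negative_baseline_silences_all_symptoms(self):
        # 9 * logistic(-10) ~ 4e-4 expected nonzero weeks per series
        cohort = simulate_smooth_severity(
            20, T=104, ar_phi=0.5, innovation_sd=0.0, baseline_logit=-10.0, seed=2
        )
        assert all((s.counts == 0).all() for s in cohort)


class TestFlatline:
    @pytest.mark.parametrize("p,value", [(0.0, 0), (1.0, 9)])
    def test_degenerate_probabilities_give_constant_series(self, p, value):
        for s in simulate_flatline(2, T=30, emission_p=p, seed=1):
            assert (s.counts == value).all()

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValidationError):
            simulate_flatline(1, emission_p=1.2)


class TestNetwork:
    def test_zero_connectivity_reduces_to_fair_binomial(self):
        series, acts = simulate_symptom_network(
            T=2000, connectivity_c=0.0, stress_b=0.0, gain=1.0, seed=6
        )
        assert acts.shape == (9, 2000)
        np.testing.assert_array_equal(series.counts, acts.sum(axis=0))
        se = np.sqrt(9 * 0.25 / 2000)
        assert abs(series.counts.mean() - 4.5) < 4 * se

    def test_all_active_persists_in_deterministic_limit(self):
        series, _ = simulate_symptom_network(
            T=50,
            connectivity_c=3.0,
            stress_b=0.0,
            gain=50.0,
            initial_active=np.ones(9, dtype=int),
            seed=0,
        )
        assert (series.counts == 9).all()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            simulate_symptom_network(connectivity_c=-0.1)
        with pytest.raises(ValidationError):
            simulate_symptom_network(gain=0.0)


class TestCohortMixture:
    def test_single_component_equals_direct_generator_call(self):
        mix = simulate_cohort(
            [{"kind": "flatline", "proportion": 1.0, "params": {"emission_p": 0.4}}],
            4,
            T=30,
            seed=17,
        )
        direct = simulate_flatline(4, T=30, emission_p=0.4, seed=17, id_prefix="p")
        assert all((a.counts == b.counts).all() for a, b in zip(mix, direct))

    def test_invalid_proportions_rejected(self):
        comps = [
            {"kind": "flatline", "proportion": 0.5, "params": {}},
            {"kind": "flatline", "proportion": 0.6, "params": {}},
        ]
        with pytest.raises(ValidationError):
            simulate_cohort(comps, 10)
        with pytest.raises(ValidationError):
            simulate_cohort([], 10)

    def test_allocation_is_exact_and_labelled(self):
        comps = [
            {"kind": "markov_binomial", "proportion": 0.66, "params": {}},
            {"kind": "smooth_severity", "proportion": 0.34, "params": {}},
        ]
        cohort = simulate_cohort(comps, 178, T=20, seed=3)
        labels = [s.generator for s in cohort]
        assert len(cohort) == 178
        # largest-remainder allocation: 0.66 * 178 = 117.48 -> 117 or 118
        assert labels.count("markov_binomial") in (117, 118)
        assert len({s.patient_id for s in cohort}) == 178

    def test_unknown_generator_kind_rejected(self):
        with pytest.raises(ValidationError, match="unknown generator"):
            simulate_cohort([{"kind": "nope", "proportion": 1.0}], 2)
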