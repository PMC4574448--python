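"""Shared fixtures: seeded Monte-Carlo cohorts and brute-force HMM oracles.

The heavy simulated cohorts (200 replicates of the persistent two-regime
condition and of a one-regime condition, and a 178-patient labelled mixture)
are session-scoped so the EM fits are computed once and shared between the
unit and acceptance tests. All seeds are fixed.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from moodregimes import (
    AnalysisConfig,
    analyze_cohort,
    default_mixture_components,
    fit_hmm_many,
    simulate_cohort,
    simulate_markov_binomial,
)
from moodregimes.hmm import HMMParameters, binomial_log_pmf

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

N_REPLICATES = 200
TWO_REGIME_SEED = 1234
ONE_REGIME_SEED = 5678
FIT_SEED = 3
FIT_RESTARTS = 4
MIXTURE_SEED = 2024


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the forward-backward implementation)


def enum_log_likelihood(x: np.ndarray, params: HMMParameters) -> float:
    """Exhaustive-path log-likelihood: sum over all K**T latent paths."""
    K, T = params.K, len(x)
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        lp = math.log(params.initial_pi[path[0]])
        for t in range(1, T):
            a = params.transition_A[path[t - 1], path[t]]
            if a == 0.0:
                lp = -math.inf
                break
            lp += math.log(a)
        if lp == -math.inf:
            continue
        for t in range(T):
            lp += binomial_log_pmf(int(x[t]), params.trials_m, params.emission_p[path[t]])
        total += math.exp(lp)
    return math.log(total)


def enum_best_path(x: np.ndarray, params: HMMParameters) -> tuple[float, tuple]:
    """Joint-probability argmax over all paths; ties to the lexicographically
    smallest path (which matches tie-breaking toward lower state indices)."""
    K, T = params.K, len(x)
    best_lp, best_path = -math.inf, None
    for path in itertools.product(range(K), repeat=T):
        lp = math.log(params.initial_pi[path[0]]) if params.initial_pi[path[0]] else -math.inf
        for t in range(1, T):
            a = params.transition_A[path[t - 1], path[t]]
            lp += math.log(a) if a else -math.inf
        for t in range(T):
            lp += binomial_log_pmf(int(x[t]), params.trials_m, params.emission_p[path[t]])
        if lp > best_lp + 1e-12:
            best_lp, best_path = lp, path
    return best_lp, best_path


# ---------------------------------------------------------------------------
# seeded Monte-Carlo cohorts


@pytest.fixture(scope="session")
def two_regime_cohort():
    """200 replicates of the persistent two-regime condition:
    emissions (0.05, 0.85), stay probabilities 0.95, T = 104, m = 9."""
    return simulate_markov_binomial(N_REPLICATES, seed=TWO_REGIME_SEED)


@pytest.fixture(scope="session")
def two_regime_fits(two_regime_cohort):
    """(1-state fits, 2-state fits) for the two-regime cohort."""
    fits1 = fit_hmm_many(two_regime_cohort, 1, n_restarts=2, seed=FIT_SEED)
    fits2 = fit_hmm_many(
        two_regime_cohort, 2, n_restarts=FIT_RESTARTS, seed=FIT_SEED
    )
    return fits1, fits2


@pytest.fixture(scope="session")
def one_regime_cohort():
    """200 replicates of a single-regime condition (iid Binomial(9, 0.4))."""
    return simulate_markov_binomial(
        N_REPLICATES,
        seed=ONE_REGIME_SEED,
        initial=[1.0],
        transition=[[1.0]],
        emission_p=[0.4],
    )


@pytest.fixture(scope="session")
def one_regime_fits(one_regime_cohort):
    fits1 = fit_hmm_many(one_regime_cohort, 1, n_restarts=2, seed=FIT_SEED)
    fits2 = fit_hmm_many(
        one_regime_cohort, 2, n_restarts=FIT_RESTARTS, seed=FIT_SEED
    )
    return fits1, fits2


@pytest.fixture(scope="session")
def mixture_cohort():
    """178-patient labelled mixture with a 66 % two-regime design share."""
    return simulate_cohort(default_mixture_components(), 178, seed=MIXTURE_SEED)


@pytest.fixture(scope="session")
def mixture_analysis(mixture_cohort):
    cfg = AnalysisConfig(n_restarts=FIT_RESTARTS, seed=7)
    return analyze_cohort(mixture_cohort, cfg)
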