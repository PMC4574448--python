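"""Synthetic cohorts of weekly symptom-count series.

No patient-level data are deposited with the study this package supports, so
analyses are exercised on synthetic cohorts that emulate the statistical
structures the method is meant to separate:

``markov_binomial``
    Two (or K) persistent latent regimes with binomial counts — the
    generative mirror of the fitted HMM. Defaults reproduce the persistent
    two-regime condition: emission probabilities (0.05, 0.85), stay
    probabilities 0.95, 104 weeks of counts over 9 symptoms.
``smooth_severity``
    A latent severity following a stationary AR(1) on the logit scale, so
    symptoms drift gradually up and down without regime jumps (a constructed
    stand-in for the gradually-varying patients; no mechanistic claim).
``flatline``
    A single regime: iid binomial counts, emulating near-flat series.
``network``
    Nine fully connected binary symptom nodes updated synchronously; with
    high connectivity the network is bistable and produces rectangular
    on-off series, with zero connectivity it reduces to iid binomial counts.

Reproducibility: each patient gets an independent substream derived from
(master seed, patient index), so cohorts are bit-reproducible and invariant
to reordering of the generation calls.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.special import expit

from ._errors import ValidationError
from .series import SymptomSeries

DEFAULT_T = 104
DEFAULT_TRIALS = 9

#: Persistent two-regime condition used throughout: well-separated healthy
#: and depressed states with high stay probabilities.
TWO_REGIME = {
    "initial": (0.5, 0.5),
    "transition": ((0.95, 0.05), (0.05, 0.95)),
    "emission_p": (0.05, 0.85),
}

GENERATOR_KINDS = ("markov_binomial", "smooth_severity", "flatline", "network")


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    """Independent substream for one patient of a cohort."""
    if seed < 0 or index < 0:
        raise ValidationError("seed and patient index must be non-negative")
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(index))))


def _check_common(n_patients: int, T: int, trials_m: int) -> None:
    if n_patients < 1:
        raise ValidationError("n_patients must be >= 1")
    if T < 1:
        raise ValidationError("T must be >= 1")
    if trials_m < 1:
        raise ValidationError("trials_m must be >= 1")


# ---------------------------------------------------------------------------
# per-patient kernels


def _markov_binomial_one(
    rng: np.random.Generator,
    T: int,
    trials_m: int,
    initial: np.ndarray,
    transition: np.ndarray,
    emission_p: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    K = emission_p.size
    states = np.empty(T, dtype=np.int64)
    states[0] = rng.choice(K, p=initial)
    for t in range(1, T):
        states[t] = rng.choice(K, p=transition[states[t - 1]])
    counts = rng.binomial(trials_m, emission_p[states])
    return counts, states


def _smooth_severity_one(
    rng: np.random.Generator,
    T: int,
    trials_m: int,
    ar_phi: float,
    innovation_sd: float,
    baseline_logit: float,
) -> np.ndarray:
    if innovation_sd > 0:
        stat_sd = innovation_sd / np.sqrt(1.0 - ar_phi**2)
        x = rng.normal(0.0, stat_sd)
    else:
        x = 0.0
    latent = np.empty(T)
    for t in range(T):
        if t > 0:
            x = ar_phi * x + (rng.normal(0.0, innovation_sd) if innovation_sd else 0.0)
        latent[t] = baseline_logit + x
    return rng.binomial(trials_m, expit(latent))


def _network_one(
    rng: np.random.Generator,
    T: int,
    n_nodes: int,
    connectivity_c: float,
    stress_b: float,
    gain: float,
    noise_sd: float,
    initial_active: np.ndarray | None,
) -> np.ndarray:
    """Synchronous weekly updates of a fully connected binary network.

    Activation probability of node i given the previous week's states:
    logistic(gain * (stress_b + c * (k_i - (N-1)/2)) + noise), where k_i is
    the number of active nodes among the other N-1. Centring the neighbour
    count makes stress_b = 0 the symmetric zero-field condition, so the same
    rule governs activation and deactivation.
    """
    half = (n_nodes - 1) / 2.0
    if initial_active is None:
        state = rng.random(n_nodes) < expit(gain * stress_b)
    else:
        state = np.asarray(initial_active, dtype=bool).copy()
        if state.shape != (n_nodes,):
            raise ValidationError(f"initial_active must have {n_nodes} entries")
    activations = np.empty((n_nodes, T), dtype=np.int64)
    for t in range(T):
        k = state.sum() - state.astype(int)  # active neighbours of each node
        arg = gain * (stress_b + connectivity_c * (k - half))
        if noise_sd > 0:
            arg = arg + rng.normal(0.0, noise_sd, size=n_nodes)
        state = rng.random(n_nodes) < expit(arg)
        activations[:, t] = state
    return activations


# ---------------------------------------------------------------------------
# public generators


def simulate_markov_binomial(
    n_patients: int,
    *,
    T: int = DEFAULT_T,
    trials_m: int = DEFAULT_TRIALS,
    initial: Sequence[float] = TWO_REGIME["initial"],
    transition: Sequence[Sequence[float]] = TWO_REGIME["transition"],
    emission_p: Sequence[float] = TWO_REGIME["emission_p"],
    seed: int = 0,
    id_prefix: str = "mb",
    _index_offset: int = 0,
) -> list[SymptomSeries]:
    """Cohort of K-regime Markov-switching binomial count series.

    The latent state path is retained on each series (``true_states``) so
    decoding and recovery can be scored against the truth.
    """
    _check_common(n_patients, T, trials_m)
    emission_p = np.atleast_1d(np.asarray(emission_p, dtype=float))
    initial = np.asarray(initial, dtype=float)
    transition = np.atleast_2d(np.asarray(transition, dtype=float))
    K = emission_p.size
    if K < 1:
        raise ValidationError("at least one state is required")
    if (emission_p < 0).any() or (emission_p > 1).any():
        raise ValidationError("emission probabilities must lie in [0, 1]")
    if initial.shape != (K,) or abs(initial.sum() - 1.0) > 1e-9 or (initial < 0).any():
        raise ValidationError("initial must be a length-K probability vector")
    if transition.shape != (K, K):
        raise ValidationError("transition must be K x K")
    rows = transition.sum(axis=1)
    bad = np.nonzero((np.abs(rows - 1.0) > 1e-9) | (transition < 0).any(axis=1))[0]
    if bad.size:
        raise ValidationError(
            f"transition matrix row {int(bad[0])} is not a probability "
            f"distribution (sum = {rows[int(bad[0])]!r})"
        )

    cohort = []
    for i in range(n_patients):
        rng = _patient_rng(seed, i + _index_offset)
        counts, states = _markov_binomial_one(
            rng, T, trials_m, initial, transition, emission_p
        )
        cohort.append(
            SymptomSeries(
                patient_id=f"{id_prefix}{i + _index_offset:04d}",
                counts=counts,
                trials_m=trials_m,
                generator="markov_binomial",
                true_states=states,
            )
        )
    return cohort


def simulate_smooth_severity(
    n_patients: int,
    *,
    T: int = DEFAULT_T,
    trials_m: int = DEFAULT_TRIALS,
    ar_phi: float = 0.95,
    innovation_sd: float = 0.35,
    baseline_logit: float = 0.0,
    seed: int = 0,
    id_prefix: str = "sm",
    _index_offset: int = 0,
) -> list[SymptomSeries]:
    """Cohort whose severity drifts smoothly (latent stationary AR(1)).

    Weekly counts are Binomial(m, logistic(baseline_logit + x_t)) with
    x_t = ar_phi * x_{t-1} + N(0, innovation_sd) started from the stationary
    distribution. Requires |ar_phi| < 1.
    """
    _check_common(n_patients, T, trials_m)
    if not abs(ar_phi) < 1:
        raise ValidationError(f"|ar_phi| must be < 1 for stationarity, got {ar_phi}")
    if innovation_sd < 0:
        raise ValidationError("innovation_sd must be >= 0")
    cohort = []
    for i in range(n_patients):
        rng = _patient_rng(seed, i + _index_offset)
        counts = _smooth_severity_one(
            rng, T, trials_m, ar_phi, innovation_sd, baseline_logit
        )
        cohort.append(
            SymptomSeries(
                patient_id=f"{id_prefix}{i + _index_offset:04d}",
                counts=counts,
                trials_m=trials_m,
                generator="smooth_severity",
            )
        )
    return cohort


def simulate_flatline(
    n_patients: int,
    *,
    T: int = DEFAULT_T,
    trials_m: int = DEFAULT_TRIALS,
    emission_p: float = 0.5,
    seed: int = 0,
    id_prefix: str = "fl",
    _index_offset: int = 0,
) -> list[SymptomSeries]:
    """Single-regime cohort: counts iid Binomial(m, emission_p)."""
    _check_common(n_patients, T, trials_m)
    if not 0.0 <= emission_p <= 1.0:
        raise ValidationError("emission_p must lie in [0, 1]")
    cohort = []
    for i in range(n_patients):
        rng = _patient_rng(seed, i + _index_offset)
        counts = rng.binomial(trials_m, emission_p, size=T)
        cohort.append(
            SymptomSeries(
                patient_id=f"{id_prefix}{i + _index_offset:04d}",
                counts=counts,
                trials_m=trials_m,
                generator="flatline",
            )
        )
    return cohort


def simulate_symptom_network(
    *,
    T: int = DEFAULT_T,
    n_nodes: int = DEFAULT_TRIALS,
    connectivity_c: float = 1.2,
    stress_b: float = 0.0,
    gain: float = 1.0,
    noise_sd: float = 0.0,
    initial_active: Sequence[int] | None = None,
    seed: int = 0,
    patient_id: str = "net0000",
    _index: int = 0,
) -> tuple[SymptomSeries, np.ndarray]:
    """One series from the connected symptom network, plus node activations.

    Returns the weekly count series (count = number of active nodes) and the
    full ``n_nodes x T`` binary activation matrix. With connectivity 0 and
    stress 0 every node is an independent fair coin each week, so counts are
    iid Binomial(n_nodes, 0.5); with high connectivity the network is
    bistable and the series shows rectangular jumps between mostly-off and
    mostly-on configurations.
    """
    if T < 1:
        raise ValidationError("T must be >= 1")
    if connectivity_c < 0:
        raise ValidationError("connectivity_c must be >= 0")
    if gain <= 0:
        raise ValidationError("gain must be > 0")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = _patient_rng(seed, _index)
    init = None if initial_active is None else np.asarray(initial_active)
    activations = _network_one(
        rng, T, n_nodes, connectivity_c, stress_b, gain, noise_sd, init
    )
    counts = activations.sum(axis=0)
    series = SymptomSeries(
        patient_id=patient_id,
        counts=counts,
        trials_m=n_nodes,
        generator="network",
    )
    return series, activations


def simulate_network_cohort(
    n_patients: int,
    *,
    T: int = DEFAULT_T,
    n_nodes: int = DEFAULT_TRIALS,
    connectivity_c: float = 1.2,
    stress_b: float = 0.0,
    gain: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    id_prefix: str = "net",
    _index_offset: int = 0,
) -> list[SymptomSeries]:
    """Cohort of independent network-driven series (counts only)."""
    _check_common(n_patients, T, n_nodes)
    cohort = []
    for i in range(n_patients):
        series, _ = simulate_symptom_network(
            T=T,
            n_nodes=n_nodes,
            connectivity_c=connectivity_c,
            stress_b=stress_b,
            gain=gain,
            noise_sd=noise_sd,
            seed=seed,
            patient_id=f"{id_prefix}{i + _index_offset:04d}",
            _index=i + _index_offset,
        )
        cohort.append(series)
    return cohort


# ---------------------------------------------------------------------------
# mixtures

_GENERATOR_DISPATCH = {
    "markov_binomial": simulate_markov_binomial,
    "smooth_severity": simulate_smooth_severity,
    "flatline": simulate_flatline,
    "network": simulate_network_cohort,
}


def default_mixture_components() -> list[dict]:
    """Cohort mixture mirroring the observed pattern shares.

    66 % persistent two-regime series, with the remaining third split
    between gradually drifting (29 %) and narrow flat-line (5 %) series —
    the non-jumping patterns rescaled from their observed 38 % / 7 % shares.
    """
    return [
        {"kind": "markov_binomial", "proportion": 0.66, "params": dict(TWO_REGIME)},
        {"kind": "smooth_severity", "proportion": 0.29, "params": {}},
        {"kind": "flatline", "proportion": 0.05, "params": {"emission_p": 0.5}},
    ]


def _allocate(proportions: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder allocation of n patients to mixture components."""
    raw = proportions * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def simulate_cohort(
    components: Sequence[dict],
    n_patients: int,
    *,
    T: int = DEFAULT_T,
    trials_m: int = DEFAULT_TRIALS,
    seed: int = 0,
) -> list[SymptomSeries]:
    """Mixture cohort: each component is {"kind", "proportion", "params"}.

    Proportions must sum to 1 (within 1e-9); patient counts per component
    are allocated by largest remainder so the cohort size is exact. Each
    series keeps its generator label so downstream classification can be
    scored against the truth.
    """
    if not components:
        raise ValidationError("mixture must contain at least one component")
    props = np.array([float(c.get("proportion", np.nan)) for c in components])
    if np.isnan(props).any() or (props < 0).any():
        raise ValidationError("every component needs a non-negative proportion")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValidationError(
            f"mixture proportions must sum to 1, got {props.sum()!r}"
        )
    _check_common(n_patients, T, trials_m)

    alloc = _allocate(props, n_patients)
    cohort: list[SymptomSeries] = []
    offset = 0
    for comp, n_comp in zip(components, alloc):
        if n_comp == 0:
            continue
        kind = comp.get("kind")
        if kind not in _GENERATOR_DISPATCH:
            raise ValidationError(
                f"unknown generator kind {kind!r}; expected one of "
                f"{GENERATOR_KINDS}"
            )
        params = dict(comp.get("params", {}))
        fn = _GENERATOR_DISPATCH[kind]
        kwargs = dict(T=T, seed=seed, id_prefix="p", _index_offset=offset)
        if kind == "network":
            kwargs["n_nodes"] = trials_m
        else:
            kwargs["trials_m"] = trials_m
        try:
            cohort.extend(fn(n_comp, **kwargs, **params))
        except TypeError as exc:
            raise ValidationError(
                f"invalid parameters for generator {kind!r}: {exc}"
            ) from exc
        offset += n_comp
    return cohort
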