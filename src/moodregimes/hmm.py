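"""Hidden Markov Models with binomial emissions for symptom-count series.

A K-state HMM with weekly counts y_t ~ Binomial(m, p_k) given latent state
k, Markovian state transitions, and free emission probabilities. The study
design compares a 1-state model (iid binomial counts, no regimes) against a
2-state model (two regimes — "healthy" and "depressed" — with persistence)
by BIC; the 2-state model winning is the model-based indicator of
bimodality, and the distance between the state means Theta_k = m * p_k
measures how far apart the two regimes sit on the symptom scale.

Everything here is implemented directly: scaled forward-backward
recursions, Baum-Welch EM with multiple restarts, Viterbi decoding, and the
information criteria. Emission probabilities are clamped to
[1e-6, 1 - 1e-6] during EM so degenerate all-zero or all-nine series do not
produce log(0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import binom as _binom

from ._errors import ValidationError
from .series import SymptomSeries

P_CLAMP = 1e-6

__all__ = [
    "HMMParameters",
    "HMMFit",
    "ModelComparison",
    "binomial_log_pmf",
    "forward_backward",
    "log_likelihood",
    "fit_hmm",
    "fit_hmm_many",
    "information_criteria",
    "count_free_parameters",
    "compare_models",
    "mode_distance",
    "viterbi_path",
]


# ---------------------------------------------------------------------------
# parameters and results


@dataclass
class HMMParameters:
    """Parameters of a K-state binomial-emission HMM.

    ``initial_pi`` and the rows of ``transition_A`` must sum to 1 (within
    1e-9); emission probabilities must lie in [0, 1].
    """

    trials_m: int
    initial_pi: np.ndarray
    transition_A: np.ndarray
    emission_p: np.ndarray

    def __post_init__(self) -> None:
        self.initial_pi = np.asarray(self.initial_pi, dtype=float)
        self.transition_A = np.atleast_2d(
            np.asarray(self.transition_A, dtype=float)
        )
        self.emission_p = np.atleast_1d(np.asarray(self.emission_p, dtype=float))
        K = self.emission_p.size
        if K < 1:
            raise ValidationError("at least one state is required")
        if self.initial_pi.shape != (K,):
            raise ValidationError("initial_pi must have one entry per state")
        if self.transition_A.shape != (K, K):
            raise ValidationError("transition_A must be K x K")
        if abs(self.initial_pi.sum() - 1.0) > 1e-9 or (self.initial_pi < 0).any():
            raise ValidationError("initial_pi must be a probability vector")
        row_sums = self.transition_A.sum(axis=1)
        bad = np.nonzero(np.abs(row_sums - 1.0) > 1e-9)[0]
        if bad.size or (self.transition_A < 0).any():
            row = int(bad[0]) if bad.size else int(
                np.nonzero((self.transition_A < 0).any(axis=1))[0][0]
            )
            raise ValidationError(
                f"transition matrix row {row} is not a probability "
                f"distribution (sum = {row_sums[row]!r})"
            )
        if (self.emission_p < 0).any() or (self.emission_p > 1).any():
            raise ValidationError("emission probabilities must lie in [0, 1]")
        if self.trials_m < 1:
            raise ValidationError("trials_m must be >= 1")

    @property
    def K(self) -> int:
        return int(self.emission_p.size)


@dataclass
class HMMFit:
    """A fitted K-state model and its goodness-of-fit summaries.

    ``modes_theta`` are the per-state expected counts Theta_k = m * p_k,
    sorted ascending (state 1 is the healthier regime by convention);
    ``mode_distance`` is |Theta_2 - Theta_1| for K = 2 fits and None
    otherwise; ``stay_probabilities`` is the diagonal of the transition
    matrix.
    """

    patient_id: str
    params: HMMParameters
    logl: float
    nfree: int
    aic: float
    bic: float
    modes_theta: np.ndarray
    mode_distance: float | None
    stay_probabilities: np.ndarray
    converged: bool
    n_restarts_used: int
    logl_history: np.ndarray | None = field(default=None, repr=False)

    @property
    def K(self) -> int:
        return self.params.K


@dataclass(frozen=True)
class ModelComparison:
    """1-state vs 2-state fits with the BIC-selected state count.

    The 2-state model is selected iff its BIC is strictly lower; ties go to
    the 1-state model (parsimony).
    """

    fit_1state: HMMFit
    fit_2state: HMMFit
    selected_K: int
    delta_bic: float


# ---------------------------------------------------------------------------
# likelihood building blocks


def binomial_log_pmf(count: int, trials_m: int, p: float) -> float:
    """Log of the Binomial(trials_m, p) mass at ``count``.

    Certain outcomes (p = 0 with count 0, p = 1 with count m) have log-pmf
    0; impossible ones return -inf.
    """
    count = int(count)
    trials_m = int(trials_m)
    if not 0 <= count <= trials_m:
        raise ValidationError(
            f"count {count} outside [0, {trials_m}]"
        )
    if p <= 0.0:
        return 0.0 if count == 0 else -math.inf
    if p >= 1.0:
        return 0.0 if count == trials_m else -math.inf
    log_comb = (
        math.lgamma(trials_m + 1)
        - math.lgamma(count + 1)
        - math.lgamma(trials_m - count + 1)
    )
    return log_comb + count * math.log(p) + (trials_m - count) * math.log1p(-p)


def _counts_of(series: SymptomSeries | np.ndarray) -> np.ndarray:
    if isinstance(series, SymptomSeries):
        return series.counts
    x = np.asarray(series, dtype=np.int64)
    if x.ndim != 1 or x.size == 0:
        raise ValidationError("series must be a non-empty 1-d count vector")
    return x


def _emission_matrix(x: np.ndarray, m: int, p: np.ndarray) -> np.ndarray:
    """Binomial emission probabilities, shape (..., T, K)."""
    return np.exp(_binom.logpmf(x[..., :, None], m, p[..., None, :]))


def forward_backward(
    series: SymptomSeries | np.ndarray, params: HMMParameters
) -> tuple[float, np.ndarray, np.ndarray]:
    """Scaled forward-backward recursions.

    Returns ``(logl, gamma, xi)`` where ``gamma[t, k]`` is the posterior
    probability of state k in week t (rows sum to 1) and ``xi[t, i, j]`` the
    posterior probability of the transition i -> j between weeks t and t+1
    (shape (T-1, K, K)). Per-step scaling keeps 104-week series far from
    underflow.
    """
    x = _counts_of(series)
    T, K, m = x.size, params.K, params.trials_m
    B = _emission_matrix(x, m, params.emission_p)  # (T, K)
    A = params.transition_A

    alpha = np.empty((T, K))
    c = np.empty(T)
    a = params.initial_pi * B[0]
    c[0] = a.sum()
    if c[0] <= 0:
        raise ValidationError("series has zero likelihood under the model")
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        if c[t] <= 0:
            raise ValidationError("series has zero likelihood under the model")
        alpha[t] = a / c[t]
    logl = float(np.log(c).sum())

    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi = (
        alpha[:-1, :, None]
        * A[None, :, :]
        * (B[1:] * beta[1:])[:, None, :]
        / c[1:, None, None]
    )
    return logl, gamma, xi


def log_likelihood(
    series: SymptomSeries | np.ndarray, params: HMMParameters
) -> float:
    """Log-likelihood of a series under fixed parameters (scaled forward)."""
    x = _counts_of(series)
    B = _emission_matrix(x, params.trials_m, params.emission_p)
    a = params.initial_pi * B[0]
    logl = 0.0
    for t in range(x.size):
        if t > 0:
            a = (a @ params.transition_A) * B[t]
        s = a.sum()
        if s <= 0:
            return -math.inf
        logl += math.log(s)
        a = a / s
    return logl


def viterbi_path(
    series: SymptomSeries | np.ndarray, params: HMMParameters
) -> np.ndarray:
    """Most probable latent state sequence (log-space Viterbi).

    Ties are broken toward the lower-indexed state.
    """
    x = _counts_of(series)
    T, K = x.size, params.K
    with np.errstate(divide="ignore"):
        logB = _binom.logpmf(x[:, None], params.trials_m, params.emission_p[None, :])
        logA = np.log(params.transition_A)
        logpi = np.log(params.initial_pi)
    delta = logpi + logB[0]
    back = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + logA  # (from, to)
        back[t] = np.argmax(cand, axis=0)  # argmax picks the lowest index on ties
        delta = cand[back[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


# ---------------------------------------------------------------------------
# information criteria and model comparison


def count_free_parameters(K: int) -> int:
    """Freely estimated parameters of a K-state fit.

    K emission probabilities + K(K-1) free transition entries + (K-1) free
    initial probabilities. For K = 1 the initial distribution and transition
    matrix are fixed, leaving a single free parameter (the emission
    probability); for K = 2 this gives 5.
    """
    K = int(K)
    if K < 1:
        raise ValidationError("K must be >= 1")
    return K + K * (K - 1) + (K - 1)


def information_criteria(logl: float, nfree: int, T: int) -> tuple[float, float]:
    """AIC = -2 logl + 2 nfree and BIC = -2 logl + nfree ln(T).

    The BIC sample size is the number of weeks T.
    """
    if T < 1:
        raise ValidationError("T must be >= 1")
    if nfree < 0:
        raise ValidationError("nfree must be >= 0")
    aic = -2.0 * logl + 2.0 * nfree
    bic = -2.0 * logl + nfree * math.log(T) if nfree else -2.0 * logl
    return aic, bic


def mode_distance(fit: HMMFit) -> float:
    """Distance |Theta_2 - Theta_1| between the two state means.

    Only defined for 2-state fits.
    """
    if fit.K != 2:
        raise ValidationError("mode distance is defined for 2-state fits only")
    return float(abs(fit.modes_theta[1] - fit.modes_theta[0]))


def compare_models(fit_1state: HMMFit, fit_2state: HMMFit) -> ModelComparison:
    """Select between the 1- and 2-state fits of the same series by BIC."""
    if fit_1state.K != 1 or fit_2state.K != 2:
        raise ValidationError("compare_models expects a 1-state and a 2-state fit")
    if fit_1state.patient_id != fit_2state.patient_id:
        raise ValidationError(
            f"fits are for different series: {fit_1state.patient_id!r} vs "
            f"{fit_2state.patient_id!r}"
        )
    selected = 2 if fit_2state.bic < fit_1state.bic else 1
    return ModelComparison(
        fit_1state=fit_1state,
        fit_2state=fit_2state,
        selected_K=selected,
        delta_bic=fit_1state.bic - fit_2state.bic,
    )


# ---------------------------------------------------------------------------
# Baum-Welch EM


def _initial_params(
    x: np.ndarray, K: int, n_restarts: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Starting values for each restart: (pi, A, p) stacked over restarts.

    Restart 0 is deterministic: split the counts at their median and set the
    state means from the below/above halves. Remaining restarts place the
    emission probabilities on a uniform grid jittered by the seeded
    generator.
    """
    R = n_restarts
    m_scale = max(float(x.max()), 1.0)  # scale by the observed range
    p0 = np.empty((R, K))

    # deterministic median-split start
    if K == 1:
        p0[0] = np.clip(x.mean() / m_scale, 0.05, 0.95)
    else:
        qs = np.quantile(x, np.linspace(0, 1, K + 1))
        for k in range(K):
            lo, hi = qs[k], qs[k + 1]
            sel = (x >= lo) & (x <= hi)
            mean_k = x[sel].mean() if sel.any() else (lo + hi) / 2.0
            p0[0, k] = mean_k / m_scale
        p0[0] = np.clip(p0[0] + 1e-3 * np.arange(K), 0.02, 0.98)

    # jittered-grid restarts
    grid = (np.arange(K) + 1.0) / (K + 1.0)
    for r in range(1, R):
        jitter = rng.uniform(-0.5, 0.5, size=K) / (K + 1.0)
        p0[r] = np.clip(np.sort(grid + jitter), 0.02, 0.98)

    pi0 = np.full((R, K), 1.0 / K)
    if K == 1:
        A0 = np.ones((R, 1, 1))
    else:
        stay = 0.8
        A0 = np.full((R, K, K), (1.0 - stay) / (K - 1))
        idx = np.arange(K)
        A0[:, idx, idx] = stay
    return pi0, A0, p0


def _em_batch(
    x: np.ndarray,
    m: int,
    pi: np.ndarray,
    A: np.ndarray,
    p: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, list]:
    """Run Baum-Welch on a batch of (series, restart) rows in parallel.

    ``x`` has shape (N, T): one row per EM run (the same series may appear
    on several rows, once per restart), and ``pi``/``A``/``p`` hold that
    row's current parameters. Returns final (pi, A, p), the last E-step
    log-likelihoods, a converged flag per row and the per-iteration
    log-likelihood history. Rows that have converged are frozen (their
    parameters stop updating), which keeps every row's likelihood trace
    monotone.
    """
    N, K = p.shape
    T = x.shape[1]
    ll_prev = np.full(N, -np.inf)
    converged = np.zeros(N, dtype=bool)
    history: list[np.ndarray] = []

    for _ in range(max_iter):
        # E-step (all rows; frozen ones recompute an unchanged value)
        B = _emission_matrix(x, m, p)  # (N, T, K)
        alpha = np.empty((N, T, K))
        c = np.empty((N, T))
        a = pi * B[:, 0]
        c[:, 0] = a.sum(axis=1)
        a /= c[:, 0, None]
        alpha[:, 0] = a
        for t in range(1, T):
            a = np.einsum("nk,nkj->nj", a, A) * B[:, t]
            c[:, t] = a.sum(axis=1)
            a /= c[:, t, None]
            alpha[:, t] = a
        ll = np.log(c).sum(axis=1)
        history.append(ll.copy())

        newly = (
            ~converged
            & np.isfinite(ll_prev)
            & (np.abs(ll - ll_prev) <= tol * np.maximum(np.abs(ll_prev), 1.0))
        )
        converged |= newly
        ll_prev = ll
        active = ~converged
        if not active.any():
            break

        # backward pass with sufficient-statistic accumulation
        beta = np.ones((N, K))
        gamma_last = alpha[:, T - 1]
        gamma0 = gamma_last.copy()
        g_sum = gamma_last.copy()
        gx_sum = gamma_last * x[:, T - 1, None]
        xi_sum = np.zeros((N, K, K))
        for t in range(T - 2, -1, -1):
            bb = B[:, t + 1] * beta  # (N, K)
            xi_sum += (
                alpha[:, t, :, None] * A * bb[:, None, :] / c[:, t + 1, None, None]
            )
            beta = np.einsum("nkj,nj->nk", A, bb) / c[:, t + 1, None]
            g = alpha[:, t] * beta
            g /= g.sum(axis=1, keepdims=True)
            g_sum += g
            gx_sum += g * x[:, t, None]
            if t == 0:
                gamma0 = g

        # M-step, applied only to still-active rows
        new_pi = gamma0
        denom = xi_sum.sum(axis=2, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            new_A = np.where(denom > 0, xi_sum / denom, A)
        new_p = np.clip(gx_sum / (m * g_sum), P_CLAMP, 1.0 - P_CLAMP)
        if K == 1:
            new_pi = np.ones((N, 1))
            new_A = np.ones((N, 1, 1))
        pi = np.where(active[:, None], new_pi, pi)
        A = np.where(active[:, None, None], new_A, A)
        p = np.where(active[:, None], new_p, p)
        # re-normalise against rounding drift
        pi = pi / pi.sum(axis=1, keepdims=True)
        A = A / A.sum(axis=2, keepdims=True)

    return pi, A, p, ll_prev, converged, history


def _fit_from_batch(
    x: np.ndarray,
    pid: str,
    trials_m: int,
    K: int,
    pi: np.ndarray,
    A: np.ndarray,
    p: np.ndarray,
    ll: np.ndarray,
    conv: np.ndarray,
    history: list[np.ndarray] | None,
    n_restarts: int,
) -> HMMFit:
    """Assemble an HMMFit from one series' slice of a finished EM batch."""
    candidates = np.nonzero(conv)[0] if conv.any() else np.arange(len(ll))
    best = int(candidates[np.argmax(ll[candidates])])

    order = np.argsort(p[best], kind="stable")
    params = HMMParameters(
        trials_m=trials_m,
        initial_pi=pi[best][order],
        transition_A=A[best][np.ix_(order, order)],
        emission_p=p[best][order],
    )
    # final log-likelihood recomputed under the returned (relabelled) params
    logl = log_likelihood(x, params)
    nfree = count_free_parameters(K)
    aic, bic = information_criteria(logl, nfree, x.size)
    theta = trials_m * params.emission_p
    dist = float(abs(theta[1] - theta[0])) if K == 2 else None
    hist = np.array([h[best] for h in history]) if history is not None else None
    return HMMFit(
        patient_id=pid,
        params=params,
        logl=logl,
        nfree=nfree,
        aic=aic,
        bic=bic,
        modes_theta=theta,
        mode_distance=dist,
        stay_probabilities=np.diag(params.transition_A).copy(),
        converged=bool(conv.any()),
        n_restarts_used=n_restarts,
        logl_history=hist,
    )


def fit_hmm_many(
    cohort: Sequence[SymptomSeries],
    K: int,
    *,
    n_restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed_fn=None,
) -> list[HMMFit]:
    """Fit one K-state model per series, batching the EM across the cohort.

    Equivalent to calling :func:`fit_hmm` on each series (same restarts,
    same selection rule) but runs all (series, restart) EM chains in one
    vectorised sweep, which is much faster for cohort-sized inputs. Series
    must share a common length and trial count. ``seed_fn``, if given, maps
    a patient_id to the restart seed for that series (defaults to the shared
    ``seed``), so results do not depend on cohort ordering.
    """
    if not cohort:
        raise ValidationError("cohort must be non-empty")
    K = int(K)
    if K < 1:
        raise ValidationError("K must be >= 1")
    n_restarts = max(1, int(n_restarts))
    T = cohort[0].T
    trials_m = cohort[0].trials_m
    for s in cohort:
        if s.T != T or s.trials_m != trials_m:
            raise ValidationError(
                "fit_hmm_many requires a cohort with a common length and "
                "trial count"
            )
    if T < K:
        raise ValidationError(f"series of length {T} cannot support K={K}")

    S = len(cohort)
    xs = np.stack([s.counts for s in cohort])  # (S, T)
    pis, As, ps = [], [], []
    for s in cohort:
        rseed = seed if seed_fn is None else seed_fn(s.patient_id)
        rng = np.random.default_rng(rseed)
        pi0, A0, p0 = _initial_params(s.counts, K, n_restarts, rng)
        pis.append(pi0)
        As.append(A0)
        ps.append(p0)
    x_rows = np.repeat(xs, n_restarts, axis=0)  # (S * R, T)
    pi, A, p, ll, conv, _ = _em_batch(
        x_rows,
        trials_m,
        np.concatenate(pis),
        np.concatenate(As),
        np.concatenate(ps),
        tol,
        max_iter,
    )
    fits = []
    for i, s in enumerate(cohort):
        sl = slice(i * n_restarts, (i + 1) * n_restarts)
        fits.append(
            _fit_from_batch(
                s.counts, s.patient_id, trials_m, K,
                pi[sl], A[sl], p[sl], ll[sl], conv[sl], None, n_restarts,
            )
        )
    return fits


def fit_hmm(
    series: SymptomSeries | np.ndarray,
    K: int,
    *,
    trials_m: int | None = None,
    n_restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    track_history: bool = False,
) -> HMMFit:
    """Fit a K-state binomial-emission HMM by Baum-Welch EM.

    Multiple restarts are run (a deterministic median-split start plus
    seeded jittered-grid starts) and the best converged solution by
    log-likelihood is returned; if no restart converges within ``max_iter``
    iterations the best solution is returned with ``converged=False``.
    States are relabelled so the emission probabilities are ascending, and
    emission estimates are clamped to [1e-6, 1 - 1e-6].
    """
    x = _counts_of(series)
    pid = series.patient_id if isinstance(series, SymptomSeries) else ""
    if trials_m is None:
        trials_m = series.trials_m if isinstance(series, SymptomSeries) else 9
    K = int(K)
    if K < 1:
        raise ValidationError("K must be >= 1")
    if x.size < K:
        raise ValidationError(f"series of length {x.size} cannot support K={K}")
    if x.max() > trials_m:
        raise ValidationError("counts exceed trials_m")
    n_restarts = max(1, int(n_restarts))

    rng = np.random.default_rng(seed)
    pi0, A0, p0 = _initial_params(x, K, n_restarts, rng)
    x_rows = np.broadcast_to(x, (n_restarts, x.size))
    pi, A, p, ll, conv, history = _em_batch(
        x_rows, trials_m, pi0, A0, p0, tol, max_iter
    )
    return _fit_from_batch(
        x, pid, trials_m, K, pi, A, p, ll, conv,
        history if track_history else None, n_restarts,
    )
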