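# Methods

This note records the exact statistical conventions the package implements,
the defaults it ships, and the judgement calls behind them.

## Data model

A patient's record is a series of weekly symptom counts `y_1 … y_T` with
`y_t ∈ {0, …, m}`, `m = 9` symptoms and `T = 104` weeks by default. Analyses
reject series of the wrong length; cohort readers exclude such patients
complete-case and report the exclusion rather than silently imputing.

## Bimodality coefficient

```
BC = (s² + 1) / (k + C(n)),    C(n) = 3(n−1)² / ((n−2)(n−3))
```

* `s` and `k` are the **bias-corrected** sample skewness (G1) and excess
  kurtosis (G2), computed via `scipy.stats.skew/kurtosis(bias=False)`. The
  uncorrected convention is available through
  `sample_moments(..., bias_corrected=False)`.
* `C(n)` is the finite-sample correction; `C(104) = 3.089` and
  `C(n) → 3` as `n → ∞`, recovering the asymptotic form.
* Reference points: normal 1/3, uniform 5/9 ≈ 0.556, two-point → 1.
* Classification is **strictly greater than 0.55**; the threshold sits just
  below the uniform value, so anything at least as flat as a uniform is
  flagged. The threshold is configurable (`bc_threshold`).
* A constant series has zero variance; skewness and kurtosis are undefined
  and `bimodality_coefficient` raises `DegenerateSeriesError`. The pipeline
  treats these patients as "BC undefined" and reports them separately rather
  than excluding them — a flat series is still evidence about regimes (it is
  the clearest possible 1-state case).

## Hidden Markov model

Emissions are `y_t | state k ~ Binomial(m, p_k)`; states follow a Markov
chain with initial distribution π and transition matrix A.

* **Likelihood**: scaled forward recursion; verified in the test suite
  against exhaustive enumeration over all `K^T` state paths for short
  series (agreement to 1e-10).
* **Fitting**: Baum–Welch EM. Restart 0 is a deterministic median/quantile
  split of the observed counts; the remaining restarts (`n_restarts = 10` by
  default) jitter a grid of emission probabilities. Convergence when the
  relative log-likelihood change falls below `tol = 1e-8`, capped at
  `max_iter = 500` iterations. The best converged restart wins; if none
  converges the best non-converged solution is returned with
  `converged=False`.
* **Clamping**: emission probabilities are clamped to `[1e-6, 1 − 1e-6]`
  during EM so all-zero or all-nine stretches cannot produce `log 0`. The
  clamp bounds the mode distance at `9(1 − 2·10⁻⁶)`, which rounds to 9.00.
* **Labelling**: states are relabelled so emission probabilities ascend —
  state 1 is always the healthier regime. Viterbi ties resolve to the
  lower-numbered state.
* **Free parameters**: `K − 1` initial probabilities, `K(K−1)` transition
  probabilities, `K` emission probabilities — so 1 for `K = 1` and 5 for
  `K = 2`. `AIC = −2ℓ + 2·nfree`, `BIC = −2ℓ + nfree·ln T`.
* **Selection**: the 2-state model is chosen iff its BIC is *strictly*
  lower; ties go to the simpler model.
* `fit_hmm_many` batches EM across patients (and restarts) in vectorised
  numpy and is bit-identical to per-patient `fit_hmm` calls; it exists
  because 2-state EM on genuinely one-regime data crawls along a flat ridge
  for hundreds of iterations, and fitting hundreds of patients sequentially
  is needlessly slow.

## Diagnostics

* **Mode distance** `|Θ₂ − Θ₁|` with `Θ_k = m·p_k`: how far apart the two
  regimes sit on the 0–9 scale. Only defined for 2-state fits.
* **Stay probabilities** `A_kk`: regime persistence. The acceptance check
  reads persistence **per state, pooled across the 2-state-selected fits**
  (share of fitted diagonal entries above 0.87). A stricter per-patient
  "both diagonals above 0.87" reading fails more often for a benign reason:
  when the minority regime is occupied for only a handful of weeks its stay
  probability is estimated from very few transitions and is noisy even when
  the model is otherwise right.

## Cohort summaries

`analyze_cohort` reports the proportion of patients with BC > 0.55 (over
the defined-BC denominator), the proportion where BIC selects 2 states, the
pooled-counts BC, per-patient BC moments, a Lilliefors test of BC normality
(`statsmodels` `kstest_normal`), and Spearman correlations among BC, mode
distance and the 2-state selection indicator (`None` when an input has zero
variance). Summaries are computed on a patient-id-sorted copy, so they are
invariant to input order; per-patient EM seeds are derived from the patient
id (CRC32 mixed with the master seed) for the same reason.

## Synthetic generators

Each patient gets an independent substream via
`np.random.SeedSequence((seed, patient_index))`, so cohorts are reproducible
bit-for-bit and individual patients can be regenerated in isolation.

* **`markov_binomial`** — the regime-switching data the analysis is built
  to detect. Defaults: initial (0.5, 0.5), stay probability 0.95 in both
  states, emissions (0.05, 0.85). Stay 0.95 gives mean dwell times of 20
  weeks — a few regime changes per 104-week record; emissions put the state
  means at 0.45 and 7.65 symptoms, comfortably but not trivially separated.
* **`smooth_severity`** — the continuous alternative: a stationary AR(1)
  latent severity on the logit scale (`ar_phi = 0.95`,
  `innovation_sd = 0.35`, `baseline_logit = 0`), mapped through the logistic
  to a weekly binomial probability. Highly autocorrelated but unimodal in
  the long run.
* **`flatline`** — iid `Binomial(9, p)` noise, default `p = 0.5`. Note that
  extreme `p` (near 0 or 1) produces skewed series whose BC can exceed 0.55
  — BC is a bimodality *coefficient*, not a test — which is why the default
  sits at the symmetric centre (BC ≈ 0.35 there).
* **`network`** — nine fully connected binary symptoms updated
  synchronously; each symptom activates with probability
  `logistic(gain·(stress_b + c·(k_active − 4)))`, where `k_active` counts
  the currently active symptoms. The coupling is **centred at half
  activation** so that `c = 0` reduces exactly to fair iid noise and
  increasing `c` moves the system smoothly toward bistable all-on/all-off
  dynamics — the connectivity hypothesis in generative form.
* **`simulate_cohort`** mixes generators with largest-remainder allocation
  of patient counts. The default mixture is 66 % two-regime, 29 % smooth,
  5 % flatline.

## Numerical and testing choices

* Heavy statistical tests use `n_restarts = 4` instead of the default 10.
  With the deterministic median-split start included, 4 restarts already
  identify the global optimum on essentially every series of this size, and
  the reduction keeps the full suite in the low minutes.
* Statistical acceptance thresholds (selection rates, recovery error,
  persistence share, mixture share band) were fixed before the final test
  runs, at the values the method claims — not tuned to the observed seeds.
* Lilliefors p-values in `statsmodels` are table-interpolated and truncated
  (e.g. reported as 0.001 below the table); treat them as indicative.

## Known limitations

* The 2-state model assumes constant emission probabilities within regime;
  slow drift inside a regime can inflate the estimated state separation.
* BC is sensitive to skew: one-sided floor effects (many zero weeks) can
  push BC over 0.55 without any second mode. The HMM comparison is the
  robustness check for exactly this case; agreement between the two methods
  is the interesting signal, not either alone.
* BIC with `T = 104` is conservative: brief regime visits (a few weeks) are
  often absorbed into a 1-state fit.
* The network generator is a deliberately minimal fully-connected,
  homogeneous-weight model; it is meant to generate connectivity-graded
  bimodality, not to be a realistic symptom network.
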