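# moodregimes

Does a patient's depression move between **two discrete states** — a healthy
regime and a depressed regime — or does it vary **continuously** along a
severity dimension? `moodregimes` answers this question patient by patient
from weekly symptom counts (0–9 symptoms per week, typically 104 weeks), using
two independent lines of evidence:

1. **Bimodality coefficient (BC).** A distribution with two well-separated
   modes has low excess kurtosis relative to its skewness. The coefficient

   ```
   BC = (s² + 1) / (k + C(n)),   C(n) = 3(n−1)² / ((n−2)(n−3))
   ```

   uses bias-corrected sample skewness `s` and excess kurtosis `k` with the
   finite-sample correction `C(n)` (`C(104) ≈ 3.089`). The uniform
   distribution scores BC = 5/9 ≈ 0.556; values **strictly above 0.55** are
   classified bimodal (a normal distribution scores 1/3, a two-point
   distribution approaches 1).

2. **Regime-switching model comparison.** Weekly counts are modelled as
   binomial draws, `y_t ~ Binomial(9, p_k)`, conditional on a hidden state
   `k` that evolves as a Markov chain. A 1-state model (one mood, iid noise)
   and a 2-state model (two persistent regimes) are fit by Baum–Welch EM with
   multiple restarts and compared by BIC. If the 2-state model wins, the
   fitted state means `Θ_k = 9·p_k` locate the two regimes on the symptom
   scale, their difference is the **mode distance**, and the diagonal of the
   transition matrix gives the **stay probabilities** (how sticky each regime
   is week to week).

The package also ships a first-class **synthetic cohort generator** — a
persistent two-regime Markov chain, a smoothly drifting AR(1) severity
process, iid "flatline" noise, and a coupled binary symptom network whose
connectivity tunes how bimodal the resulting series are — so every claim the
analysis makes can be checked against ground truth.

## Worked example

```python
from moodregimes import compare_models, fit_hmm, simulate_markov_binomial

(patient,) = simulate_markov_binomial(1, T=104, seed=7)
fit1 = fit_hmm(patient, 1, seed=0)
fit2 = fit_hmm(patient, 2, seed=0)
cmp = compare_models(fit1, fit2)
print(cmp.selected_K, fit2.modes_theta, fit2.stay_probabilities)
```

Running `python examples/fit_regime_hmm.py` (which does the above and more)
prints:

```
K=1: logl =  -469.18  AIC =  940.36  BIC =  943.00  (nfree = 1, converged = True)
K=2: logl =  -142.95  AIC =  295.90  BIC =  309.12  (nfree = 5, converged = True)

BIC selects the 2-state model (delta BIC = 633.88)
state means Theta = (0.55, 7.73) symptoms; mode distance = 7.19
stay probabilities = (0.945, 0.937) — both regimes are persistent week to week

Viterbi decoding recovers the true regime in 100% of weeks
```

A whole cohort goes through `analyze_cohort`, which returns per-patient
reports plus a `CohortSummary` (proportions flagged bimodal by each method,
pooled BC, Lilliefors normality test, and Spearman correlations between the
diagnostics). See `examples/cohort_report.py` for the full tour, and
`examples/simulate_cohorts.py` for the generators, including the network
connectivity sweep.

## Command line

```bash
moodregimes simulate --config cfg.yaml --out cohort.csv
moodregimes analyze  --in cohort.csv --config cfg.yaml --outdir results/
moodregimes figure   --in cohort.csv --patients p0000,p0003 --outdir figs/
```

`analyze` writes `patient_reports.csv`, `cohort_summary.csv` and
`table2.csv` (the 1- vs 2-state fit table for patients spanning the BC
percentiles). A fully annotated config file lives at
`docs/config_example.yaml`. Input CSVs are long format with a
`patient_id,week,n_symptoms` header; patients with missing or extra weeks
are excluded complete-case (and reported), while out-of-range counts,
duplicate weeks or malformed rows are hard errors with line numbers.

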