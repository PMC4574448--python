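# Fully annotated configuration for `moodregimes simulate` / `analyze`.
# Every value below is also the built-in default unless commented otherwise;
# any section or key may be omitted. Unknown keys are rejected with an error
# naming the key, so typos never silently fall back to defaults.

analysis:
  T: 104            # required series length; other lengths are excluded
  trials_m: 9       # symptoms on the checklist (counts range 0..trials_m)
  bc_threshold: 0.55  # BC strictly above this is classified bimodal
  n_restarts: 10    # EM restarts (deterministic median split + jittered grid)
  tol: 1.0e-8       # relative log-likelihood convergence tolerance
  max_iter: 500     # EM iteration cap per restart
  seed: 0           # master seed; per-patient fit seeds derive from it

simulate:
  n_patients: 178
  T: 104
  trials_m: 9
  seed: 0
  # A mixture of generators; proportions must sum to 1. Patient counts are
  # allocated by largest remainder, so they always total n_patients exactly.
  components:
    - kind: markov_binomial     # persistent two-regime patients
      proportion: 0.66
      params:
        initial: [0.5, 0.5]     # starting-regime probabilities
        transition: [[0.95, 0.05], [0.05, 0.95]]  # rows must sum to 1
        emission_p: [0.05, 0.85]  # per-regime symptom probability
    - kind: smooth_severity     # continuously drifting severity (AR(1))
      proportion: 0.29
      params:
        ar_phi: 0.95            # autocorrelation of the latent logit
        innovation_sd: 0.35     # innovation scale of the latent logit
        baseline_logit: 0.0     # long-run mean on the logit scale
    - kind: flatline            # iid binomial noise, no structure
      proportion: 0.05
      params:
        emission_p: 0.5
    # A fourth generator is available (not in the default mixture):
    # - kind: network           # coupled binary symptom network
    #   proportion: 0.0
    #   params:
    #     connectivity_c: 1.2   # symptom-symptom coupling strength
    #     stress_b: 0.0         # external stress field
    #     gain: 1.0             # slope of the activation function
    #     noise_sd: 0.0         # optional extra noise on the activation input

# Single-generator shorthand (instead of `components`):
#
# simulate:
#   n_patients: 50
#   kind: markov_binomial
#   params: {}
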