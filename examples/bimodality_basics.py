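"""The bimodality coefficient, from first principles to a diagnosis.

Computes BC on three hand-built series (unimodal, uniform-like, two-point)
and on a simulated two-regime patient, showing how the statistic separates
"one mood with noise" from "two distinct moods".
"""

import numpy as np

from moodregimes import (
    bc_value,
    bimodality_coefficient,
    correction_factor,
    simulate_markov_binomial,
)

T = 104

print(f"finite-sample correction C({T}) = {correction_factor(T):.3f}")
print(f"uniform-distribution reference BC = {bc_value(0.0, -1.2, 3.0):.3f}")
print("classification threshold          = 0.550 (strictly above = bimodal)\n")

rng = np.random.default_rng(0)
cases = {
    "unimodal (binomial p=0.4)": rng.binomial(9, 0.4, T),
    "near-uniform counts": rng.integers(0, 10, T),
    "two-point (0s and 9s)": rng.choice([0, 9], T),
}
for name, counts in cases.items():
    r = bimodality_coefficient(counts)
    print(
        f"{name:28s} BC = {r.bc:.3f}  "
        f"(skew {r.skewness:+.2f}, ex. kurtosis {r.excess_kurtosis:+.2f})"
        f"  -> {r.label}"
    )

(patient,) = simulate_markov_binomial(1, T=T, seed=42)
r = bimodality_coefficient(patient)
print(
    f"\nsimulated two-regime patient   BC = {r.bc:.3f} -> {r.label}\n"
    "Regime-switching series pile mass at both ends of the 0-9 scale, which\n"
    "drives excess kurtosis strongly negative and pushes BC above 0.55."
)
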