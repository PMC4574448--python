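"""Container for one patient's weekly symptom-count series.

The analysed variable is the number of DSM-IV depression symptoms present in
a given week, an integer between 0 and ``trials_m`` (9 in the study design:
depressed mood, diminished interest, eating problems, sleeping problems,
psychomotor problems, loss of energy, guilt, cognitive problems, suicidal
ideation). A complete record spans 104 weeks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._errors import ValidationError


@dataclass
class SymptomSeries:
    """Ordered weekly symptom counts for one patient.

    Parameters
    ----------
    patient_id
        Opaque identifier.
    counts
        Integer counts, one per week, each in ``[0, trials_m]``. Weeks are
        implicitly 1-based and contiguous.
    trials_m
        Number of binary symptoms counted each week (default 9).
    generator
        For synthetic series, the name of the generator that produced it.
    true_states
        For synthetic series with a latent regime, the true state path
        (same length as ``counts``); retained so recovery can be scored.
    """

    patient_id: str
    counts: np.ndarray
    trials_m: int = 9
    generator: str | None = None
    true_states: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size == 0:
            raise ValidationError("counts must be a non-empty 1-d sequence")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded):
                raise ValidationError("counts must be integers")
            counts = rounded.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if self.trials_m < 1:
            raise ValidationError("trials_m must be >= 1")
        if counts.min() < 0 or counts.max() > self.trials_m:
            raise ValidationError(
                f"counts must lie in [0, {self.trials_m}]; "
                f"got range [{counts.min()}, {counts.max()}]"
            )
        self.counts = counts
        if self.true_states is not None:
            states = np.asarray(self.true_states, dtype=np.int64)
            if states.shape != counts.shape:
                raise ValidationError("true_states must match counts in length")
            self.true_states = states

    @property
    def T(self) -> int:
        """Number of observed weeks."""
        return int(self.counts.size)

    @property
    def weeks(self) -> np.ndarray:
        """1-based week indices."""
        return np.arange(1, self.T + 1)
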