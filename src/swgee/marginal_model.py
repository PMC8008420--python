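"""True marginal outcome probabilities for the simulated trials.

The data-generating model is marginal (population-average) and log-linear in
time: baseline odds at occasion 1 are multiplied by a fixed odds ratio for
each later occasion and by the intervention odds ratio when treated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MarginalSpec", "marginal_probability"]


@dataclass(frozen=True)
class MarginalSpec:
    """Marginal model parameters.

    baseline_prevalence: control-condition outcome prevalence at occasion 1.
    time_or: odds ratio applied per measurement occasion (log-linear trend).
    intervention_or: marginal intervention odds ratio; log(intervention_or)
        is the true treatment coefficient used for coverage and bias.
    """

    baseline_prevalence: float = 0.30
    time_or: float = 1.05
    intervention_or: float = 1.3

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must lie in (0, 1)")
        if self.time_or <= 0 or self.intervention_or <= 0:
            raise ValueError("odds ratios must be strictly positive")

    @property
    def baseline_odds(self) -> float:
        # exact p/(1-p), not the rounded two-decimal value: rounding error
        # compounds over occasions
        return self.baseline_prevalence / (1.0 - self.baseline_prevalence)

    @property
    def true_log_or(self) -> float:
        return float(np.log(self.intervention_or))


def marginal_odds(spec: MarginalSpec, occasion: int, treated: int) -> float:
    """Marginal odds at a given 1-based occasion and condition."""
    if occasion < 1:
        raise ValueError("occasion is 1-based")
    return spec.baseline_odds * spec.time_or ** (occasion - 1) * spec.intervention_or**treated


def marginal_probability(spec: MarginalSpec, occasion: int, treated: int) -> float:
    """Marginal outcome probability odds/(1+odds) for one cell."""
    odds = marginal_odds(spec, occasion, treated)
    return odds / (1.0 + odds)
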