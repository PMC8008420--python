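"""Wald t-intervals and p-values for the intervention log odds ratio."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["InferenceResult", "wald_t_interval"]


@dataclass(frozen=True)
class InferenceResult:
    """Confidence interval and two-sided p-value for one coefficient.

    The estimate and interval are on the log odds-ratio scale;
    ``or_ci_low``/``or_ci_high`` exponentiate them.
    """

    log_or: float
    se: float
    df: float
    ci_low: float
    ci_high: float
    p_value: float
    level: float = 0.95
    labels: dict | None = None

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.log_or))

    @property
    def or_ci_low(self) -> float:
        return float(np.exp(self.ci_low))

    @property
    def or_ci_high(self) -> float:
        return float(np.exp(self.ci_high))

    def covers(self, true_log_or: float) -> bool:
        return self.ci_low <= true_log_or <= self.ci_high


def wald_t_interval(
    estimate: float,
    se: float,
    df: float,
    level: float = 0.95,
    labels: dict | None = None,
) -> InferenceResult:
    """Wald interval ``estimate +/- t_{df, (1+level)/2} * se``.

    ``df = inf`` uses the normal distribution.  The two-sided p-value tests
    the null of no effect; ``p < 1 - level`` if and only if the interval
    excludes zero, so power and coverage computed from the same result are
    mutually consistent.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if not (df >= 1 or np.isinf(df)):
        raise ValueError("df must be >= 1 (or inf for the normal approximation)")
    dist = stats.norm if np.isinf(df) else stats.t(df)
    q = dist.ppf(0.5 + level / 2.0)
    tstat = estimate / se
    p = 2.0 * dist.sf(abs(tstat))
    return InferenceResult(
        log_or=float(estimate),
        se=float(se),
        df=float(df),
        ci_low=float(estimate - q * se),
        ci_high=float(estimate + q * se),
        p_value=float(min(p, 1.0)),
        level=level,
        labels=labels,
    )
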