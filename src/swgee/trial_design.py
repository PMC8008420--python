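"""Stepped-wedge trial designs.

A stepped-wedge cluster randomised trial (SW-CRT) randomises clusters to
*sequences*; each sequence crosses from control to intervention at a different
trial period, so that by the final period every cluster receives the
intervention.  The designs built here have no all-control period: the first
sequence is already treated in period 1.

Six measurement occasions are mapped onto either six trial periods (one
occasion per period; six sequences) or three trial periods (two occasions per
period; three sequences).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["TrialDesign", "build_design", "covariate_row", "design_df"]

DF_FLAVORS = ("C-P", "CP-P", "CP-C-P")


@dataclass(frozen=True)
class TrialDesign:
    """A complete SW-CRT layout.

    Attributes
    ----------
    n_sequences : int
        Number of distinct crossover times (S).
    n_clusters : int
        Number of clusters (C), allocated round-robin to sequences.
    n_occasions : int
        Number of measurement occasions (6 throughout).
    n_periods : int
        Number of trial periods; equals ``n_sequences`` for the staircase
        designs used here.
    occasion_to_period : tuple[int, ...]
        1-based period index for each 1-based occasion.
    treatment : np.ndarray
        ``(S, n_periods)`` 0/1 array; ``treatment[s-1, t-1]`` is the condition
        of sequence ``s`` in period ``t``.
    cluster_to_sequence : tuple[int, ...]
        1-based sequence index for each 1-based cluster.
    """

    n_sequences: int
    n_clusters: int
    n_occasions: int
    n_periods: int
    occasion_to_period: tuple[int, ...]
    treatment: np.ndarray = field(repr=False)
    cluster_to_sequence: tuple[int, ...] = field(repr=False)

    @property
    def n_params(self) -> int:
        """Model parameters p: one cell-mean per period plus the treatment effect."""
        return self.n_periods + 1

    def period_of_occasion(self, occasion: int) -> int:
        return self.occasion_to_period[occasion - 1]

    def sequence_of_cluster(self, cluster: int) -> int:
        return self.cluster_to_sequence[cluster - 1]

    def treated(self, sequence: int, period: int) -> int:
        return int(self.treatment[sequence - 1, period - 1])

    def treated_at_occasion(self, sequence: int, occasion: int) -> int:
        return self.treated(sequence, self.period_of_occasion(occasion))

    def diagram(self) -> str:
        """ASCII picture of the sequence-by-period treatment staircase."""
        lines = ["seq \\ period " + " ".join(f"{t:>2d}" for t in range(1, self.n_periods + 1))]
        for s in range(1, self.n_sequences + 1):
            cells = " ".join(" X" if self.treated(s, t) else " ." for t in range(1, self.n_periods + 1))
            lines.append(f"{s:>12d} {cells}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"n_sequences": self.n_sequences, "n_clusters": self.n_clusters}


def build_design(
    n_sequences: int,
    n_clusters: int,
    *,
    n_occasions: int = 6,
    allow_generic: bool = False,
) -> TrialDesign:
    """Build the staircase SW-CRT design with no all-control period.

    Sequence ``k`` (1-based) is treated from period ``k`` onward, so sequence 1
    is treated in every period and the last sequence only in the final period.
    Clusters are assigned to sequences round-robin (cluster 1 to sequence 1,
    cluster 2 to sequence 2, ...).

    Parameters
    ----------
    n_sequences : int
        Number of sequences; 3 or 6 unless ``allow_generic`` is set.
    n_clusters : int
        Total clusters; must be at least ``n_sequences``.  A count that does
        not divide evenly across sequences only triggers a warning.
    n_occasions : int
        Measurement occasions; must be a multiple of ``n_sequences``.
    allow_generic : bool
        Permit staircases with a number of sequences other than 3 or 6.
    """
    if n_sequences not in (3, 6) and not allow_generic:
        raise ValueError(
            f"n_sequences must be 3 or 6 (got {n_sequences}); "
            "pass allow_generic=True for other staircases"
        )
    if n_clusters < n_sequences:
        raise ValueError("need at least one cluster per sequence")
    if n_occasions % n_sequences:
        raise ValueError("n_occasions must be a multiple of n_sequences")
    if n_clusters % n_sequences:
        warnings.warn(
            f"{n_clusters} clusters do not divide evenly across {n_sequences} sequences",
            stacklevel=2,
        )

    n_periods = n_sequences
    occ_per_period = n_occasions // n_periods
    occasion_to_period = tuple((o - 1) // occ_per_period + 1 for o in range(1, n_occasions + 1))
    # staircase: sequence k treated from period k onward
    treatment = np.zeros((n_sequences, n_periods), dtype=np.int8)
    for s in range(n_sequences):
        treatment[s, s:] = 1
    cluster_to_sequence = tuple(c % n_sequences + 1 for c in range(n_clusters))
    return TrialDesign(
        n_sequences=n_sequences,
        n_clusters=n_clusters,
        n_occasions=n_occasions,
        n_periods=n_periods,
        occasion_to_period=occasion_to_period,
        treatment=treatment,
        cluster_to_sequence=cluster_to_sequence,
    )


def covariate_row(design: TrialDesign, cluster: int, occasion: int) -> np.ndarray:
    """Model covariates for one observation.

    Cell-means coding for period: one indicator per trial period and no
    separate intercept, plus the treatment indicator last.  Length is
    ``n_periods + 1``; the last coefficient is the marginal log odds ratio of
    the intervention.
    """
    period = design.period_of_occasion(occasion)
    seq = design.sequence_of_cluster(cluster)
    row = np.zeros(design.n_params)
    row[period - 1] = 1.0
    row[-1] = design.treated(seq, period)
    return row


def design_df(design: TrialDesign, flavor: str) -> int:
    """Design-based degrees of freedom for the treatment-effect t-interval.

    ``C-P``: clusters minus parameters, ``C - (T_per + 1)``.
    ``CP-P``: cluster-periods minus parameters, ``C*T_per - (T_per + 1)``.
    ``CP-C-P``: ANOVA-style residual df with clusters as parameters,
    ``C*T_per - C - T_per`` (cells minus intercept, C-1 cluster effects,
    T_per-1 period effects and the treatment effect).

    Any non-positive value is replaced by 1.
    """
    C, T = design.n_clusters, design.n_periods
    p = T + 1
    if flavor == "C-P":
        df = C - p
    elif flavor == "CP-P":
        df = C * T - p
    elif flavor == "CP-C-P":
        df = C * T - C - T
    else:
        raise ValueError(f"unknown DF flavor {flavor!r}; expected one of {DF_FLAVORS}")
    return max(df, 1)
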