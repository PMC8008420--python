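"""Target within-cluster correlation structures on the proportion (phi) scale.

All structures share the within-occasion intracluster correlation rho:
observations in the same cluster and occasion are exchangeable at
correlation rho.  Across occasions the correlation either stays flat
(exchangeable), decays geometrically with occasion lag (AR(1) with per-lag
multiplier r0), or additionally halves when the two observations were
collected under different trial conditions (one control, one intervention),
as would happen if the intervention effect varied between clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CorrelationSpec", "pair_correlation", "FAMILY_NAMES"]

FAMILIES = ("exchangeable", "ar1", "ar1_discount")

#: config-file aliases -> (family, ar_parameter)
FAMILY_NAMES = {
    "exchangeable": ("exchangeable", 1.0),
    "ar1_0.6": ("ar1", 0.6),
    "ar1_0.8": ("ar1", 0.8),
    "ar1_0.8_discount": ("ar1_discount", 0.8),
}


@dataclass(frozen=True)
class CorrelationSpec:
    """Correlation family and parameters.

    icc: within-occasion ICC (rho) on the proportion scale.
    ar_parameter: per-occasion decay multiplier r0 (AR families; 1 for
        exchangeable).
    condition_discount: multiplier for control-vs-intervention pairs
        (ar1_discount family only).
    """

    family: str = "exchangeable"
    icc: float = 0.01
    ar_parameter: float = 1.0
    condition_discount: float = 0.5

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if not 0.0 <= self.icc < 1.0:
            raise ValueError("icc must lie in [0, 1)")
        if not 0.0 < self.ar_parameter <= 1.0:
            raise ValueError("ar_parameter must lie in (0, 1]")

    @classmethod
    def from_name(cls, name: str, icc: float) -> "CorrelationSpec":
        try:
            family, r0 = FAMILY_NAMES[name]
        except KeyError:
            raise ValueError(
                f"unknown correlation structure {name!r}; expected one of {sorted(FAMILY_NAMES)}"
            ) from None
        return cls(family=family, icc=icc, ar_parameter=r0)

    @property
    def name(self) -> str:
        for alias, (family, r0) in FAMILY_NAMES.items():
            if family == self.family and (family == "exchangeable" or r0 == self.ar_parameter):
                return alias
        return f"{self.family}_{self.ar_parameter:g}"


def pair_correlation(spec: CorrelationSpec, lag: int, discordant_condition: int = 0) -> float:
    """Target phi correlation between two same-cluster observations.

    Parameters
    ----------
    lag : int
        Absolute difference between the two measurement occasions.
    discordant_condition : {0, 1}
        1 if one observation is under control and the other under
        intervention.  Only possible for lag >= 1 since condition is constant
        within a cluster-occasion.
    """
    if lag < 0:
        raise ValueError("lag must be non-negative")
    if discordant_condition and lag == 0:
        raise ValueError("condition is constant within a cluster-occasion; lag-0 pairs cannot be discordant")
    rho = spec.icc
    if spec.family == "exchangeable":
        return rho
    rho = rho * spec.ar_parameter**lag
    if spec.family == "ar1_discount" and discordant_condition:
        rho *= spec.condition_discount
    return rho
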