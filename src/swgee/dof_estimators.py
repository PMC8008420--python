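"""Degrees of freedom for the treatment-coefficient t-interval.

With few clusters the sandwich variance estimate is itself noisy, so Wald
intervals need a t-distribution.  Two Satterthwaite-type estimators are
provided - Pan-Wall (moment-matching on the empirical variance of the
per-cluster variance contributions) and Fay-Graubard (moment-matching
against the model-implied covariance of the estimating-function
contributions) - alongside the design-based counts from
:mod:`swgee.trial_design` and the infinite-DF (normal) sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gee_fit import GEEFit
from .trial_design import TrialDesign, design_df

__all__ = ["DFEstimate", "df_pan_wall", "df_fay_graubard", "df_design"]

DF_METHODS = ("FG", "PW", "C-P", "CP-P", "CP-C-P", "Inf")


@dataclass(frozen=True)
class DFEstimate:
    method: str
    value: float  # np.inf encodes the normal approximation
    contrast: tuple | None = None


def _contrast(fit: GEEFit, contrast) -> np.ndarray:
    if contrast is None:
        ell = np.zeros(fit.n_params)
        ell[fit.treatment_index] = 1.0
        return ell
    return np.asarray(contrast, dtype=float)


def pan_wall_df_from_contributions(s: np.ndarray, cap: float = 1000.0) -> float:
    """Satterthwaite df from per-cluster variance contributions s_i.

    ``df = 2 (sum s_i)^2 / vhat`` with ``vhat = C x sample variance of
    {s_i}``, the empirical estimate of Var(sum s_i) for independent cluster
    contributions.  Returns the cap when the contributions are degenerate
    (vhat = 0).
    """
    s = np.asarray(s, dtype=float)
    C = s.shape[0]
    vhat = C * np.var(s, ddof=1)
    if vhat <= 0.0:
        return float(cap)
    return float(min(2.0 * s.sum() ** 2 / vhat, cap))


def df_pan_wall(fit: GEEFit, contrast=None, cap: float = 1000.0) -> DFEstimate:
    """Pan-Wall estimated df for one coefficient (default: treatment).

    The contributions are ``s_i = l' M B_i M l`` with ``B_i = g_i g_i'``, so
    ``l' Cov_LZ l = sum_i s_i``; the variance of the sum is estimated from the
    empirical spread of the s_i.  The estimator is known to be very variable
    in small samples; that spread is a property of the method, not damped
    here beyond the cap.
    """
    ell = _contrast(fit, contrast)
    proj = fit.g @ (fit.M @ ell)  # (C,)
    value = pan_wall_df_from_contributions(proj**2, cap)
    return DFEstimate("PW", value, tuple(ell))


def df_fay_graubard(fit: GEEFit, contrast=None, b: float = 0.75) -> DFEstimate:
    """Fay-Graubard estimated df for one coefficient (default: treatment).

    Projects each cluster's bias-adjusted estimating-function contribution
    onto the contrast, ``a_i = A_i M l`` with the same diagonal adjustment
    ``A_i = diag{(1 - min(b, [Q_i]_jj))^(-1/2)}`` used by the FG covariance,
    and matches moments against the model-implied covariance of the
    contributions, ``Cov(g_i, g_j) = delta_ij W_i - W_i M W_j`` (the second
    term reflects that residuals are taken at the estimated coefficients):

    ``df = (sum_i w_ii)^2 / sum_ij w_ij^2``, ``w_ij = a_i' Cov(g_i, g_j) a_j``.

    Floored at 1.
    """
    ell = _contrast(fit, contrast)
    W, M = fit.W, fit.M
    Q = W @ M
    d = np.diagonal(Q, axis1=1, axis2=2)
    adj = (1.0 - np.minimum(b, d)) ** -0.5  # (C, p)
    a = adj * (M @ ell)[None, :]  # (C, p)
    omega = np.einsum("cij,cj->ci", W, a)  # W_i a_i
    t = np.einsum("ci,ci->c", a, omega)  # a_i' W_i a_i
    G = omega @ M @ omega.T  # (C, C)
    w = np.diag(t) - G
    denom = float(np.sum(w * w))
    if denom <= 0.0:
        return DFEstimate("FG", 1.0, tuple(ell))
    value = float(np.trace(w)) ** 2 / denom
    return DFEstimate("FG", max(value, 1.0), tuple(ell))


def df_design(design: TrialDesign, flavor: str) -> DFEstimate:
    """Design-based df; flavor ``Inf`` is the normal-approximation sentinel."""
    if flavor == "Inf":
        return DFEstimate("Inf", np.inf)
    return DFEstimate(flavor, float(design_df(design, flavor)))
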