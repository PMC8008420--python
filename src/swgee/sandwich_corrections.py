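"""Small-sample corrections of the sandwich covariance estimator.

The uncorrected (Liang-Zeger) sandwich M (sum_i B_i) M underestimates the
true coefficient covariance with few clusters because fitted residuals are
shrunk toward zero.  The corrections either deflate this shrinkage through
the cluster leverage H_i = D_i M D_i' V_i^-1 (KC, MD, FG and the KC
approximation) or rescale the whole estimator (MW, MBN).

Every correction is computed from the same converged :class:`GEEFit`; there
is no refitting.  The leverage-based corrections are reduced to p x p
algebra through the Woodbury identity
``(I - H_i)^-1 r_i = r_i + D_i M (I - Q_i')^-1 g_i`` with
``Q_i = W_i M``, which gives

* MD: ``g_i -> (I - Q_i)^-1 g_i``
* KC-approx: symmetrised cross product of ``g_i`` and ``(I - Q_i)^-1 g_i``
* FG: ``g_i -> diag{(1 - min(b, [Q_i]_jj))^(-1/2)} g_i``

so the only n_i x n_i computation left is the exact KC square root
``(I - H_i)^(-1/2)``, taken via the Schur decomposition (the matrix is
generally non-symmetric).  The conditioning of that square root is recorded:
its instability under an exchangeable working correlation is a real property
of the estimator, surfaced rather than repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import sqrtm

from .gee_fit import GEEFit

__all__ = ["CovarianceEstimate", "sandwich", "METHODS"]

METHODS = ("LZ", "KC", "KC_approx", "FG", "MD", "MBN", "MW")

#: aliases accepted on CLIs / configs
_ALIASES = {
    "lz": "LZ",
    "uncorrected": "LZ",
    "kc": "KC",
    "kc-approx": "KC_approx",
    "kc_approx": "KC_approx",
    "fg": "FG",
    "md": "MD",
    "mbn": "MBN",
    "mw": "MW",
}


@dataclass
class CovarianceEstimate:
    """A corrected coefficient covariance matrix tagged by method."""

    method: str
    matrix: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def se_treatment(self) -> float:
        return float(np.sqrt(self.matrix[-1, -1]))

    def se(self, index: int) -> float:
        return float(np.sqrt(self.matrix[index, index]))


class CorrectionError(RuntimeError):
    """A leverage-based correction failed numerically (e.g. singular I - H_i).

    Simulation runners count this like non-convergence for the affected
    method; it is never silently substituted.
    """


def _bread(fit: GEEFit, meat: np.ndarray) -> np.ndarray:
    v = fit.M @ meat @ fit.M
    return (v + v.T) / 2.0


def sandwich(fit: GEEFit, method: str = "LZ", *, fg_boundary: float = 0.75) -> CovarianceEstimate:
    """Corrected sandwich covariance of the GEE coefficients.

    Parameters
    ----------
    fit : GEEFit
        A converged fit.
    method : str
        One of ``LZ`` (uncorrected), ``KC``, ``KC_approx``, ``FG``, ``MD``,
        ``MBN``, ``MW`` (case-insensitive aliases accepted).
    fg_boundary : float
        FG leverage bound b; the diagonal adjustment is
        ``(1 - min(b, [Q_i]_jj))^(-1/2)``.
    """
    method = _ALIASES.get(method.lower(), method)
    if method not in METHODS:
        raise ValueError(f"unknown correction {method!r}; expected one of {METHODS}")
    if not fit.converged:
        raise ValueError("sandwich corrections require a converged fit")

    g, W, M = fit.g, fit.W, fit.M
    C, p = g.shape
    N = fit.n_obs
    diagnostics: dict = {}

    if method in ("LZ", "MW", "MBN"):
        meat = g.T @ g
        if method == "MW":
            if C <= p:
                raise CorrectionError(f"MW multiplier undefined: C={C} <= p={p}")
            meat = meat * (C / (C - p))
        cov = _bread(fit, meat)
        if method == "MBN":
            if C <= p:
                raise CorrectionError(f"MBN constants undefined: C={C} <= p={p}")
            kappa = (N - 1) / (N - p) * C / (C - 1)
            delta = min(0.5, p / (C - p))
            phi_r = max(1.0, kappa * float(np.trace(M @ meat)) / p)
            cov = kappa * cov + delta * phi_r * M
            diagnostics.update(kappa=kappa, delta=delta, phi_r=phi_r)
        return CovarianceEstimate(method, cov, diagnostics)

    Q = W @ M  # (C, p, p); Q_i = D_i' V_i^-1 D_i M

    if method == "FG":
        d = np.diagonal(Q, axis1=1, axis2=2)
        adj = (1.0 - np.minimum(fg_boundary, d)) ** -0.5  # (C, p)
        diagnostics["n_bounded"] = int(np.sum(d > fg_boundary))
        ga = adj * g
        return CovarianceEstimate(method, _bread(fit, ga.T @ ga), diagnostics)

    if method in ("MD", "KC_approx"):
        eye = np.eye(p)
        try:
            gt = np.linalg.solve(eye[None] - Q, g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            raise CorrectionError(f"singular I - Q_i in {method}") from None
        if not np.all(np.isfinite(gt)):
            raise CorrectionError(f"non-finite adjusted contributions in {method}")
        if method == "MD":
            meat = gt.T @ gt
        else:
            cross = gt.T @ g
            meat = (cross + cross.T) / 2.0
        return CovarianceEstimate(method, _bread(fit, meat), diagnostics)

    # exact KC: r_i -> (I - H_i)^(-1/2) r_i with H_i = D_i M D_i' V_i^-1,
    # computed per cluster in the n_i x n_i space via the Schur method
    meat = np.zeros((p, p))
    max_cond = 0.0
    for i in range(C):
        D = fit.D_i(i)
        V = fit.V_i(i)
        try:
            Vinv = np.linalg.inv(V)
        except np.linalg.LinAlgError:
            raise CorrectionError(f"singular working covariance in cluster {i}") from None
        H = D @ M @ D.T @ Vinv
        ImH = np.eye(H.shape[0]) - H
        try:
            root = sqrtm(ImH)
            radj = np.linalg.solve(root, fit.r_i(i))
            max_cond = max(max_cond, float(np.linalg.cond(root)))
        except (np.linalg.LinAlgError, ValueError):
            raise CorrectionError(f"(I - H_i)^(1/2) failed in cluster {i}") from None
        if np.iscomplexobj(radj):
            if np.max(np.abs(radj.imag)) > 1e-8 * max(1.0, np.max(np.abs(radj.real))):
                raise CorrectionError(f"complex KC adjustment in cluster {i}")
            radj = radj.real
        if not np.all(np.isfinite(radj)):
            raise CorrectionError(f"non-finite KC adjustment in cluster {i}")
        gi = D.T @ Vinv @ radj
        meat += np.outer(gi, gi)
    diagnostics["sqrt_condition_number"] = max_cond
    return CovarianceEstimate(method, _bread(fit, meat), diagnostics)
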