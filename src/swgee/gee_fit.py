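"""Logistic GEE with independence or exchangeable working correlation.

Fits the marginal logistic model by Fisher scoring on the estimating
equations sum_i D_i' V_i^-1 (y_i - mu_i) = 0, with V_i = A_i^(1/2) R(alpha)
A_i^(1/2) and A_i = diag(mu_ij (1 - mu_ij)).  The exchangeable working
correlation alpha is re-estimated each iteration by the moment estimator
from cross-products of Pearson residuals.

All per-cluster building blocks needed by the sandwich corrections
(derivative matrices, working covariances, residuals, and the model-based
bread matrix M) are exposed on the returned :class:`GEEFit`.  The
exchangeable inverse is applied in closed form,
``R^-1 = I/(1-a) - a/((1-a)(1+(n-1)a)) J``, so the fit never forms an
n_i x n_i matrix; cluster reductions use ``np.add.reduceat`` over flat
arrays, which keeps ragged cluster sizes cheap.

Non-convergence (separation, singular information) is reported through the
``converged`` flag, never raised: simulation runners count failures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GEEFit", "fit_gee", "fit_gee_matrix", "exchangeable_alpha"]

WORKINGS = ("independence", "exchangeable")


@dataclass
class GEEFit:
    """Fitted GEE with per-cluster blocks.

    beta: coefficients (period cell-means then the treatment log odds ratio
        when built by :func:`fit_gee`; arbitrary columns via
        :func:`fit_gee_matrix`).
    alpha: exchangeable working correlation estimate (0.0 under independence).
    scale: Pearson dispersion estimate phi.
    g: (C, p) per-cluster estimating-function contributions D_i' V_i^-1 r_i.
    W: (C, p, p) per-cluster information blocks D_i' V_i^-1 D_i.
    M: (p, p) bread matrix (sum_i W_i)^-1.
    """

    beta: np.ndarray
    alpha: float
    scale: float
    converged: bool
    n_iterations: int
    working: str
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    mu: np.ndarray = field(repr=False)
    offsets: np.ndarray = field(repr=False)
    g: np.ndarray = field(repr=False)
    W: np.ndarray = field(repr=False)
    M: np.ndarray = field(repr=False)
    alpha_clipped: bool = False
    treatment_index: int = -1

    @property
    def n_clusters(self) -> int:
        return len(self.offsets) - 1

    @property
    def n_obs(self) -> int:
        return self.x.shape[0]

    @property
    def n_params(self) -> int:
        return self.x.shape[1]

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.diff(self.offsets)

    # -- per-cluster blocks, reconstructed on demand ---------------------
    def _slice(self, i: int) -> slice:
        return slice(self.offsets[i], self.offsets[i + 1])

    def D_i(self, i: int) -> np.ndarray:
        """Derivative matrix d mu_i / d beta = A_i X_i (logit link)."""
        s = self._slice(i)
        a = self.mu[s] * (1.0 - self.mu[s])
        return self.x[s] * a[:, None]

    def V_i(self, i: int) -> np.ndarray:
        """Working covariance A^(1/2) R(alpha) A^(1/2) (scale-free)."""
        s = self._slice(i)
        a = self.mu[s] * (1.0 - self.mu[s])
        n = a.shape[0]
        R = np.full((n, n), self.alpha)
        np.fill_diagonal(R, 1.0)
        sq = np.sqrt(a)
        return sq[:, None] * R * sq[None, :]

    def r_i(self, i: int) -> np.ndarray:
        s = self._slice(i)
        return self.y[s] - self.mu[s]


def _apply_rinv_exch(u: np.ndarray, alpha: float, offsets: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Apply blockwise R(alpha)^-1 to flat (N,) or (N, k) array u."""
    if alpha == 0.0:
        return u
    one = 1.0 - alpha
    c = alpha / (one * (1.0 + (sizes - 1) * alpha))
    sums = np.add.reduceat(u, offsets[:-1], axis=0)
    if u.ndim == 1:
        return u / one - np.repeat(c * sums, sizes)
    return u / one - np.repeat(c[:, None] * sums, sizes, axis=0)


def exchangeable_alpha(
    pearson: np.ndarray, offsets: np.ndarray, n_params: int, scale: float | None = None
) -> float:
    """Moment estimator of the exchangeable working correlation.

    ``alpha = [sum_i sum_{j<k} e_ij e_ik / (sum_i n_i(n_i-1)/2 - p)] / phi``
    with phi the Pearson dispersion (estimated from the same residuals when
    not supplied).  Not clipped here; the fitter clips to the valid range.
    """
    sizes = np.diff(offsets)
    n, p = pearson.shape[0], n_params
    if scale is None:
        scale = float(pearson @ pearson) / (n - p)
    s1 = np.add.reduceat(pearson, offsets[:-1])
    s2 = np.add.reduceat(pearson * pearson, offsets[:-1])
    cross = float(np.sum(s1 * s1 - s2)) / 2.0
    pairs = float(np.sum(sizes * (sizes - 1))) / 2.0
    if pairs - p <= 0:
        return 0.0  # too few within-cluster pairs to estimate a correlation
    return cross / (pairs - p) / scale


def fit_gee_matrix(
    y: np.ndarray,
    x: np.ndarray,
    clusters: np.ndarray,
    working: str = "independence",
    *,
    scale_fix: bool = False,
    tol: float = 1e-6,
    max_iter: int = 50,
    treatment_index: int = -1,
) -> GEEFit:
    """Fit a logistic GEE from an arbitrary design matrix.

    ``clusters`` labels rows; rows are reordered so clusters are contiguous
    (order within and between clusters does not affect either working
    structure).
    """
    if working not in WORKINGS:
        raise ValueError(f"working must be one of {WORKINGS}")
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    clusters = np.asarray(clusters)
    uniq, inv = np.unique(clusters, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    order = np.argsort(inv, kind="stable")
    y, x, inv = y[order], x[order], inv[order]
    sizes = np.bincount(inv)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    return _solve(y, x, offsets, working, scale_fix, tol, max_iter, treatment_index)


def _solve(y, x, offsets, working, scale_fix, tol, max_iter, treatment_index) -> GEEFit:
    n, p = x.shape
    sizes = np.diff(offsets)
    exch = working == "exchangeable"

    # start at the overall prevalence: with cell-means period coding this
    # puts every fitted probability at the grand mean
    ybar = min(max(y.mean(), 1e-3), 1 - 1e-3)
    beta = np.zeros(p)
    ones = np.isclose(x, 1.0) | np.isclose(x, 0.0)
    beta[:] = np.log(ybar / (1 - ybar)) if ones.all() else 0.0
    if ones.all():
        beta[treatment_index] = 0.0

    alpha = 0.0
    alpha_clipped = False
    converged = False
    it = 0
    singular = False
    eta = x @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))

    for it in range(1, max_iter + 1):
        a = mu * (1.0 - mu)
        r = y - mu
        sqa = np.sqrt(a)
        if exch:
            pearson = r / np.maximum(sqa, 1e-12)
            scale = float(pearson @ pearson) / (n - p)
            alpha = exchangeable_alpha(pearson, offsets, p, scale)
            max_n = int(sizes.max())
            lo = -1.0 / (max_n - 1) + 1e-6 if max_n > 1 else -0.999
            a_new = min(max(alpha, lo), 0.999)
            alpha_clipped = alpha_clipped or (a_new != alpha)
            alpha = a_new
        dx = x * a[:, None]  # D = A X
        u_r = _apply_rinv_exch(r / np.maximum(sqa, 1e-12), alpha, offsets, sizes)
        U = dx.T @ (u_r / np.maximum(sqa, 1e-12) * 1.0)
        qd = _apply_rinv_exch(dx / np.maximum(sqa, 1e-12)[:, None], alpha, offsets, sizes)
        qd /= np.maximum(sqa, 1e-12)[:, None]
        J = dx.T @ qd
        try:
            step = np.linalg.solve(J, U)
        except np.linalg.LinAlgError:
            singular = True
            break
        beta_new = beta + step
        if not np.all(np.isfinite(beta_new)) or np.max(np.abs(beta_new)) > 1e3:
            singular = True
            beta = beta_new
            break
        delta = np.max(np.abs(step))
        beta = beta_new
        eta = x @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        if delta < tol:
            converged = True
            break

    a = mu * (1.0 - mu)
    r = y - mu
    sqa = np.maximum(np.sqrt(a), 1e-12)
    pearson = r / sqa
    scale = 1.0 if scale_fix else float(pearson @ pearson) / (n - p)

    if singular or not np.all(np.isfinite(beta)):
        converged = False

    # per-cluster blocks at the final estimate
    dx = x * a[:, None]
    q_r = _apply_rinv_exch(r / sqa, alpha, offsets, sizes) / sqa
    g = np.add.reduceat(dx * q_r[:, None], offsets[:-1], axis=0)
    qd = _apply_rinv_exch(dx / sqa[:, None], alpha, offsets, sizes) / sqa[:, None]
    W = np.add.reduceat(dx[:, :, None] * qd[:, None, :], offsets[:-1], axis=0)
    Jtot = W.sum(axis=0)
    try:
        M = np.linalg.inv(Jtot)
    except np.linalg.LinAlgError:
        M = np.full((p, p), np.nan)
        converged = False

    return GEEFit(
        beta=beta,
        alpha=float(alpha) if exch else 0.0,
        scale=scale,
        converged=converged,
        n_iterations=it,
        working=working,
        x=x,
        y=y,
        mu=mu,
        offsets=offsets,
        g=g,
        W=W,
        M=M,
        alpha_clipped=alpha_clipped,
        treatment_index=treatment_index,
    )


def fit_gee_prepared(
    y: np.ndarray,
    x: np.ndarray,
    offsets: np.ndarray,
    working: str = "independence",
    *,
    scale_fix: bool = False,
    tol: float = 1e-6,
    max_iter: int = 50,
    treatment_index: int = -1,
) -> GEEFit:
    """Fit from cluster-contiguous arrays (``offsets`` are block boundaries).

    Fast path for simulation runners that already hold cluster-major data;
    skips the label sort done by :func:`fit_gee_matrix`.
    """
    if working not in WORKINGS:
        raise ValueError(f"working must be one of {WORKINGS}")
    return _solve(
        np.asarray(y, dtype=float),
        np.asarray(x, dtype=float),
        np.asarray(offsets),
        working,
        scale_fix,
        tol,
        max_iter,
        treatment_index,
    )


def fit_gee(
    data: pd.DataFrame,
    working: str = "independence",
    *,
    scale_fix: bool = False,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> GEEFit:
    """Fit the SW-CRT analysis model to a long-format table.

    ``data`` needs columns ``cluster``, ``period``, ``treated`` and
    ``outcome``.  The model has one cell-mean indicator per trial period (no
    intercept) plus the treatment indicator, so the last coefficient is the
    marginal log odds ratio of the intervention.
    """
    required = {"cluster", "period", "treated", "outcome"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"data is missing columns {sorted(missing)}")
    y = data["outcome"].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    periods = np.sort(data["period"].unique())
    pcol = data["period"].to_numpy()
    x = np.zeros((len(data), len(periods) + 1))
    for j, t in enumerate(periods):
        x[pcol == t, j] = 1.0
    x[:, -1] = data["treated"].to_numpy(dtype=float)
    return fit_gee_matrix(
        y,
        x,
        data["cluster"].to_numpy(),
        working,
        scale_fix=scale_fix,
        tol=tol,
        max_iter=max_iter,
    )
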