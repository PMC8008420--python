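"""Marginally-specified correlated binary data for SW-CRTs.

The generator is the Emrich-Piedmonte construction: each cluster's outcome
vector is a thresholded draw from a zero-mean multivariate normal.  The
latent normal correlation for every pair of observations is solved (by
bracketing root-finding on the bivariate-normal orthant probability) so that
the dichotomised 0/1 data attain exactly the requested marginal
probabilities and pairwise phi correlations.  Because the marginals are set
directly, the intervention log odds ratio of the generating model is the
exact population-average parameter - no attenuation, no conditional/marginal
mismatch.

Cluster sizes are either constant or drawn from a negative binomial on the
cluster total, left-truncated so every occasion keeps a minimum number of
observations and calibrated so the post-truncation total has the requested
mean and coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr, ndtri, owens_t

from .correlation_structures import CorrelationSpec, pair_correlation
from .marginal_model import MarginalSpec, marginal_probability
from .trial_design import TrialDesign

__all__ = [
    "ClusterSizeSpec",
    "solve_latent_correlation",
    "build_latent_covariance",
    "sample_cluster_sizes",
    "simulate_trial",
    "TrialSimulator",
]


# ---------------------------------------------------------------------------
# bivariate normal orthant probability and the latent-correlation solver


def bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(X <= h, Y <= k) for a standard bivariate normal with correlation rho.

    Owen's T representation; accurate to ~1e-14 for |rho| < 1.
    """
    if rho == 0.0:
        return float(ndtr(h) * ndtr(k))
    if rho >= 1.0:
        return float(ndtr(min(h, k)))
    if rho <= -1.0:
        return float(max(0.0, ndtr(h) + ndtr(k) - 1.0))
    # nudge exact zeros off the removable singularity of the T arguments
    if h == 0.0:
        h = 1e-15
    if k == 0.0:
        k = 1e-15
    r = np.sqrt(1.0 - rho * rho)
    ah = (k - rho * h) / (h * r)
    ak = (h - rho * k) / (k * r)
    beta = 0.0 if h * k > 0 else 0.5
    return float(ndtr(h) + ndtr(k)) / 2.0 - float(owens_t(h, ah)) - float(owens_t(k, ak)) - beta


def _upper_orthant(a: float, b: float, rho: float) -> float:
    """P(Z1 > a, Z2 > b) under correlation rho."""
    return 1.0 - float(ndtr(a)) - float(ndtr(b)) + bvn_cdf(a, b, rho)


def phi_bounds(p1: float, p2: float) -> tuple[float, float]:
    """Frechet bounds on the phi correlation of Bernoulli(p1), Bernoulli(p2)."""
    s = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    lo = (max(0.0, p1 + p2 - 1.0) - p1 * p2) / s
    hi = (min(p1, p2) - p1 * p2) / s
    return float(lo), float(hi)


@lru_cache(maxsize=100_000)
def _solve_latent_cached(p1: float, p2: float, phi: float) -> float:
    if phi == 0.0:
        return 0.0
    lo, hi = phi_bounds(p1, p2)
    if not lo + 1e-12 < phi < hi - 1e-12:
        raise ValueError(
            f"phi={phi} infeasible for marginals ({p1}, {p2}); "
            f"feasible interval is ({lo:.6f}, {hi:.6f})"
        )
    a, b = ndtri(1.0 - p1), ndtri(1.0 - p2)
    target = p1 * p2 + phi * np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))

    def f(delta: float) -> float:
        return _upper_orthant(a, b, delta) - target

    delta = optimize.brentq(f, -1.0 + 1e-10, 1.0 - 1e-10, xtol=1e-12, rtol=8.9e-16)
    if abs(f(delta)) > 1e-10:
        raise RuntimeError(
            f"latent-correlation solve did not converge for (p1={p1}, p2={p2}, phi={phi})"
        )
    return float(delta)


def solve_latent_correlation(p1: float, p2: float, phi: float) -> float:
    """Latent normal correlation delta reproducing a target phi correlation.

    Solves ``P(Z1 > z(1-p1), Z2 > z(1-p2); delta) - p1*p2 =
    phi*sqrt(p1 q1 p2 q2)`` for delta.  Solutions are cached by
    ``(p1, p2, phi)`` (rounded to 12 decimals) because a simulation study
    re-uses a small number of distinct pair classes across thousands of
    clusters and replicates.
    """
    if not (0.0 < p1 < 1.0 and 0.0 < p2 < 1.0):
        raise ValueError("marginal probabilities must lie in (0, 1)")
    return _solve_latent_cached(round(float(p1), 12), round(float(p2), 12), round(float(phi), 12))


def achieved_phi(p1: float, p2: float, delta: float) -> float:
    """Phi correlation of the dichotomised pair implied by latent correlation delta."""
    a, b = ndtri(1.0 - p1), ndtri(1.0 - p2)
    p11 = _upper_orthant(a, b, delta)
    return (p11 - p1 * p2) / np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))


# ---------------------------------------------------------------------------
# cluster sizes


@dataclass(frozen=True)
class ClusterSizeSpec:
    """Cluster-size distribution.

    mean_total: mean individuals per cluster across all occasions.
    cv: coefficient of variation of the cluster-total size (0 = constant).
    min_per_occasion: hard floor on observations per cluster-occasion.
    """

    mean_total: int = 24
    cv: float = 0.0
    min_per_occasion: int = 2

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")


@lru_cache(maxsize=None)
def _truncated_nb_params(
    mean_occ: float, var_occ: float, minimum: int
) -> tuple[float, float, float]:
    """Base negative-binomial (r, p_scipy) whose left-truncated-at-`minimum`
    version has the requested mean and variance; returns (r, p, F(minimum-1)).

    Truncation both raises the mean and shrinks the variance, so the base
    parameters are solved numerically from the truncated-moment equations.
    """
    if var_occ <= mean_occ:
        raise ValueError(
            f"per-occasion variance {var_occ:.3f} <= mean {mean_occ:.3f}: "
            "not representable by a negative binomial"
        )

    def trunc_moments(x: np.ndarray) -> np.ndarray:
        mu0, ex_var = np.exp(x)
        v0 = mu0 + ex_var
        r = mu0 * mu0 / (v0 - mu0)
        p = r / (r + mu0)
        ks = np.arange(minimum)
        pmf = stats.nbinom.pmf(ks, r, p)
        tail = 1.0 - pmf.sum()
        m1 = (mu0 - (ks * pmf).sum()) / tail
        m2 = (v0 + mu0 * mu0 - (ks * ks * pmf).sum()) / tail
        return np.array([m1 - mean_occ, (m2 - m1 * m1) - var_occ])

    x0 = np.log([mean_occ, max(var_occ - mean_occ, 0.5) * 1.5])
    sol = optimize.fsolve(trunc_moments, x0, full_output=True)
    x, info, ier, msg = sol
    if ier != 1 or np.max(np.abs(info["fvec"])) > 1e-8 * max(1.0, var_occ):
        raise ValueError(
            f"could not calibrate truncated negative binomial for mean={mean_occ}, "
            f"var={var_occ}: {msg}"
        )
    mu0, ex_var = np.exp(x)
    v0 = mu0 + ex_var
    r = mu0 * mu0 / (v0 - mu0)
    p = r / (r + mu0)
    flow = float(stats.nbinom.cdf(minimum - 1, r, p))
    return float(r), float(p), flow


def sample_cluster_sizes(
    spec: ClusterSizeSpec, n_occasions: int, rng: np.random.Generator, n_clusters: int = 1
) -> np.ndarray:
    """Per-occasion observation counts, shape ``(n_clusters, n_occasions)``.

    cv=0 gives the constant ``mean_total / n_occasions``.  Otherwise the
    cluster-total size is drawn from a negative binomial left-truncated at
    ``n_occasions * min_per_occasion`` (sampled by inversion of the
    conditional CDF, equivalent in law to redrawing until the floor is met),
    calibrated so the post-truncation total has mean ``mean_total`` and CV
    ``cv``; the total is then split as evenly as possible across occasions,
    the remainder going to occasions chosen at random.  Drawing the total
    rather than per-occasion counts keeps the >=2-per-occasion floor
    compatible with the requested dispersion: a per-occasion floor of 2 at
    mean 4 cannot reach the variance a total CV of 0.4 requires.
    """
    m, T = spec.mean_total, n_occasions
    if m % T:
        raise ValueError("mean_total must be a multiple of n_occasions")
    base = m // T
    if base < spec.min_per_occasion:
        raise ValueError("mean per occasion below the minimum per occasion")
    if spec.cv == 0.0:
        return np.full((n_clusters, T), base, dtype=np.int64)
    minimum = T * spec.min_per_occasion
    r, p, flow = _truncated_nb_params(float(m), (spec.cv * m) ** 2, minimum)
    u = rng.uniform(flow, 1.0, size=n_clusters)
    totals = stats.nbinom.ppf(u, r, p).astype(np.int64)
    sizes = np.tile(totals[:, None] // T, (1, T))
    rem = totals - sizes.sum(axis=1)
    for i in range(n_clusters):
        if rem[i]:
            sizes[i, rng.choice(T, size=rem[i], replace=False)] += 1
    return sizes


# ---------------------------------------------------------------------------
# latent covariance assembly


def _sequence_tables(
    design: TrialDesign, marginal: MarginalSpec, corr: CorrelationSpec
) -> dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per sequence: (marginal p per occasion, latent thresholds, 6x6 latent
    correlation table between occasions).

    The table's diagonal holds the lag-0 (within-occasion) latent
    correlation; expanding it to a full cluster matrix only requires
    repeating rows/columns by the per-occasion sizes and resetting the unit
    diagonal.
    """
    T = design.n_occasions
    tables = {}
    for s in range(1, design.n_sequences + 1):
        treated = np.array([design.treated_at_occasion(s, o) for o in range(1, T + 1)])
        probs = np.array(
            [marginal_probability(marginal, o, int(treated[o - 1])) for o in range(1, T + 1)]
        )
        thresholds = ndtri(1.0 - probs)
        delta = np.empty((T, T))
        for i in range(T):
            for j in range(i, T):
                discordant = int(treated[i] != treated[j])
                phi = pair_correlation(corr, lag=j - i, discordant_condition=discordant)
                delta[i, j] = delta[j, i] = solve_latent_correlation(probs[i], probs[j], phi)
        tables[s] = (probs, thresholds, delta)
    return tables


def build_latent_covariance(
    design: TrialDesign,
    marginal: MarginalSpec,
    corr: CorrelationSpec,
    sizes,
    sequence: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-diagonal latent normal covariance and thresholds for one cluster.

    ``sizes`` are the per-occasion observation counts.  Positive definiteness
    is verified by Cholesky; failure is an error (the simulated parameter
    ranges all give PD matrices, so a failure indicates a configuration bug).
    """
    sizes = np.asarray(sizes, dtype=np.int64)
    if np.any(sizes < 1):
        raise ValueError("each occasion needs at least one observation")
    probs, thresholds, delta = _sequence_tables(design, marginal, corr)[sequence]
    occ_idx = np.repeat(np.arange(design.n_occasions), sizes)
    sigma = delta[np.ix_(occ_idx, occ_idx)].copy()
    np.fill_diagonal(sigma, 1.0)
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        raise RuntimeError(
            f"latent covariance not positive definite (sequence {sequence}, "
            f"corr {corr.name}, icc {corr.icc})"
        ) from None
    return sigma, thresholds[occ_idx]


# ---------------------------------------------------------------------------
# trial simulation


class TrialSimulator:
    """Reusable simulator for one scenario.

    Caches the solved latent correlation tables per sequence and, for
    constant cluster sizes, the Cholesky factor of each sequence's latent
    covariance, so repeated replicates cost one matrix-vector product per
    cluster.
    """

    def __init__(
        self,
        design: TrialDesign,
        marginal: MarginalSpec,
        corr: CorrelationSpec,
        sizes: ClusterSizeSpec,
    ):
        self.design = design
        self.marginal = marginal
        self.corr = corr
        self.sizes = sizes
        self.tables = _sequence_tables(design, marginal, corr)
        self._chol_cache: dict = {}
        # fixed layout for constant cluster size
        if sizes.cv == 0.0:
            T = design.n_occasions
            per_occ = np.full(T, sizes.mean_total // T, dtype=np.int64)
            self._fixed_sizes = np.tile(per_occ, (design.n_clusters, 1))
        else:
            self._fixed_sizes = None

    def _cholesky(self, sequence: int, sizes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        key = (sequence, tuple(int(v) for v in sizes))
        cached = self._chol_cache.get(key) if self.sizes.cv == 0.0 else None
        if cached is not None:
            return cached
        _, thresholds, delta = self.tables[sequence]
        occ_idx = np.repeat(np.arange(self.design.n_occasions), sizes)
        sigma = delta[np.ix_(occ_idx, occ_idx)].copy()
        np.fill_diagonal(sigma, 1.0)
        try:
            L = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            raise RuntimeError(
                f"latent covariance not positive definite (sequence {sequence}, "
                f"corr {self.corr.name}, icc {self.corr.icc})"
            ) from None
        out = (L, thresholds[occ_idx])
        if self.sizes.cv == 0.0:
            self._chol_cache[key] = out
        return out

    def draw_sizes(self, rng: np.random.Generator) -> np.ndarray:
        """Per-cluster, per-occasion counts; constant layouts consume no randomness."""
        if self._fixed_sizes is not None:
            return self._fixed_sizes
        return sample_cluster_sizes(
            self.sizes, self.design.n_occasions, rng, n_clusters=self.design.n_clusters
        )

    def simulate_arrays(self, rng: np.random.Generator):
        """One replicate as flat arrays.

        Returns ``(sizes, y)`` where ``sizes`` is ``(C, T)`` and ``y`` is the
        concatenated 0/1 outcome vector, cluster-major then occasion-major.
        """
        sizes = self.draw_sizes(rng)
        chunks = []
        for c in range(1, self.design.n_clusters + 1):
            seq = self.design.sequence_of_cluster(c)
            L, thr = self._cholesky(seq, sizes[c - 1])
            z = L @ rng.standard_normal(L.shape[0])
            chunks.append(z > thr)
        return sizes, np.concatenate(chunks).astype(np.int8)


def simulate_trial(
    design: TrialDesign,
    marginal: MarginalSpec,
    corr: CorrelationSpec,
    sizes: ClusterSizeSpec,
    seed,
) -> pd.DataFrame:
    """Simulate one SW-CRT dataset.

    Returns a long-format frame with one row per individual and columns
    ``cluster, sequence, occasion, period, treated, outcome``.  Deterministic
    given ``seed`` (anything acceptable to :class:`numpy.random.SeedSequence`
    or a ``Generator``).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sim = TrialSimulator(design, marginal, corr, sizes)
    size_mat, y = sim.simulate_arrays(rng)
    T = design.n_occasions
    recs_cluster, recs_seq, recs_occ = [], [], []
    for c in range(1, design.n_clusters + 1):
        n_c = int(size_mat[c - 1].sum())
        recs_cluster.append(np.full(n_c, c))
        recs_seq.append(np.full(n_c, design.sequence_of_cluster(c)))
        recs_occ.append(np.repeat(np.arange(1, T + 1), size_mat[c - 1]))
    cluster = np.concatenate(recs_cluster)
    sequence = np.concatenate(recs_seq)
    occasion = np.concatenate(recs_occ)
    period = np.array([design.period_of_occasion(int(o)) for o in occasion])
    treated = np.array(
        [design.treated(int(s), int(t)) for s, t in zip(sequence, period)], dtype=np.int8
    )
    return pd.DataFrame(
        {
            "cluster": cluster,
            "sequence": sequence,
            "occasion": occasion,
            "period": period,
            "treated": treated,
            "outcome": y,
        }
    )
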