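"""Multivariate Bernoulli mixture on the presence/absence matrix (BinEM).

Each gene family's P/A profile across N genomes is modeled as one of K
components, each with a binary centroid μ_k ∈ {0,1}^N and a dispersion
ε_k ∈ [ε_floor, ½]^N giving the per-genome probability of deviating from
the centroid:

    P(X_i) = Σ_k π_k Π_j ε_kj^|x_ij−μ_kj| (1−ε_kj)^(1−|x_ij−μ_kj|)

Dispersion is constrained by default to be constant within a component
(one ε per partition) to avoid over-fitting.  Parameters are estimated
by EM from a triangular initialization that pins component 1 to the
persistent (all-present) pattern and component K to the cloud
(all-absent) pattern, which fixes label order and sidesteps label
switching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .matrix import PAMatrix
from .partition import Partitioning, assign_partitions

__all__ = [
    "EPS_FLOOR",
    "EPS_CEIL",
    "BMMParams",
    "triangular_init",
    "family_log_density",
    "log_density_matrix",
    "e_step",
    "m_step",
    "run_binem",
    "BernoulliMixturePartitioner",
]

EPS_FLOOR = 1e-4
# strictly below 1/2: at exactly 1/2 the component density is data-independent
# and mirrored centroids (mu=1 vs mu=0) become indistinguishable twins that EM
# can never separate
EPS_CEIL = 0.5 - 1e-3


@dataclass
class BMMParams:
    """Mixture parameters θ = (π, μ, ε) for K components over N genomes."""

    pi: np.ndarray  # (K,)
    mu: np.ndarray  # (K, N) binary
    epsilon: np.ndarray  # (K, N) in [EPS_FLOOR, 1/2]
    constrained_dispersion: bool = True

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.mu = np.asarray(self.mu, dtype=np.int8)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if self.mu.shape != self.epsilon.shape:
            raise ValueError("mu and epsilon must share the K×N shape")
        if len(self.pi) != self.mu.shape[0]:
            raise ValueError("pi length must equal the number of components")

    @property
    def K(self) -> int:
        return len(self.pi)

    @property
    def n_genomes(self) -> int:
        return self.mu.shape[1]

    def mean_presence(self) -> np.ndarray:
        """Per-component expected presence frequency, mean_j P(x_j = 1)."""
        p1 = self.mu * (1.0 - self.epsilon) + (1 - self.mu) * self.epsilon
        return p1.mean(axis=1)

    def reordered(self, order: np.ndarray) -> "BMMParams":
        return BMMParams(
            self.pi[order], self.mu[order], self.epsilon[order], self.constrained_dispersion
        )


def triangular_init(K: int, N: int, constrained_dispersion: bool = True) -> BMMParams:
    """Triangular starting point for the EM.

    With s = 1/⌈K/2⌉: mixing proportions are uniform, centroids are
    all-ones for the first ⌊K/2⌋ components and all-zeros after, and the
    dispersions ramp up linearly toward the middle components and back
    down (ε_k = s·k/2 for k ≤ K/2, s·(K−k+1)/2 beyond), peaking just
    below ½ (clamped to EPS_CEIL) — extreme components start crisp,
    intermediate ones diffuse.  This
    makes component 1 persistent-like and component K cloud-like from the
    first iteration.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if N < 1:
        raise ValueError("N must be >= 1")
    s = 1.0 / np.ceil(K / 2)
    k = np.arange(1, K + 1)
    mu = np.broadcast_to((k <= K / 2).astype(np.int8)[:, None], (K, N)).copy()
    eps_row = np.where(k <= K / 2, s * k / 2.0, s * (K - k + 1) / 2.0)
    eps = np.clip(np.broadcast_to(eps_row[:, None], (K, N)).copy(), EPS_FLOOR, EPS_CEIL)
    pi = np.full(K, 1.0 / K)
    return BMMParams(pi, mu, eps, constrained_dispersion)


def log_density_matrix(X: np.ndarray, params: BMMParams) -> np.ndarray:
    """F×K matrix of log component densities log p(X_i | z_i = k)."""
    X = np.asarray(X)
    eps = np.clip(params.epsilon, EPS_FLOOR, EPS_CEIL)
    log_eps = np.log(eps)
    log_1meps = np.log1p(-eps)
    out = np.empty((X.shape[0], params.K))
    for k in range(params.K):
        mismatch = (X != params.mu[k]).astype(float)  # F×N
        out[:, k] = mismatch @ log_eps[k] + (1.0 - mismatch) @ log_1meps[k]
    return out


def family_log_density(x: np.ndarray, k: int, params: BMMParams) -> float:
    """Log density of a single family profile under component k (0-based)."""
    x = np.atleast_2d(np.asarray(x))
    return float(log_density_matrix(x, params)[0, k])


def e_step(X: np.ndarray, params: BMMParams) -> tuple[np.ndarray, float]:
    """Posterior responsibilities T (F×K) and total log-likelihood.

    Computed in log space with log-sum-exp row normalization.
    """
    log_joint = np.log(np.clip(params.pi, 1e-300, None)) + log_density_matrix(X, params)
    row_norm = logsumexp(log_joint, axis=1)
    T = np.exp(log_joint - row_norm[:, None])
    return T, float(row_norm.sum())


def m_step(X: np.ndarray, T: np.ndarray, constrained_dispersion: bool = True) -> BMMParams:
    """Maximization update from row-normalized responsibilities.

    π_k is the mean responsibility; μ_kj rounds the responsibility-
    weighted presence mean (ties at exactly 0.5 go to 0); ε_kj is the
    weighted mismatch rate, clamped to [EPS_FLOOR, EPS_CEIL] and, in constrained
    mode, averaged across genomes within each component.  A component
    whose responsibility mass vanishes is re-seeded from the triangular
    start.
    """
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    F, N = X.shape
    K = T.shape[1]
    mass = T.sum(axis=0)  # (K,)
    pi = mass / F

    empty = mass <= 1e-12
    safe_mass = np.where(empty, 1.0, mass)
    P = (T.T @ X) / safe_mass[:, None]  # weighted presence mean, K×N
    mu = (P > 0.5).astype(np.int8)
    eps = np.where(mu == 1, 1.0 - P, P)
    if constrained_dispersion:
        eps = np.broadcast_to(eps.mean(axis=1, keepdims=True), eps.shape).copy()
    eps = np.clip(eps, EPS_FLOOR, EPS_CEIL)

    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} empty component(s) re-seeded from the triangular start",
            RuntimeWarning,
            stacklevel=2,
        )
        seed = triangular_init(K, N, constrained_dispersion)
        mu[empty] = seed.mu[empty]
        eps[empty] = seed.epsilon[empty]
        pi = np.where(empty, 1.0 / F, pi)
        pi = pi / pi.sum()
    return BMMParams(pi, mu, eps, constrained_dispersion)


def _as_array(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, PAMatrix):
        return X.X, X.family_ids
    return np.asarray(X), None


class BernoulliMixturePartitioner(ClusterMixin, BaseEstimator):
    """EM-fitted Bernoulli mixture partitioner of a binary P/A matrix.

    Clusters gene families (rows) into ``n_partitions`` components and
    maps them onto persistent / shell / cloud labels.  The graph-free
    baseline of the pangenome partitioner; see
    :class:`pangem.nem.NEMPartitioner` for the graph-aware variant.

    Parameters
    ----------
    n_partitions : int, default=3
        Number of mixture components K; component 1 is persistent,
        component K cloud, the K−2 in between shell.
    max_iter : int, default=100
        Maximum EM iterations.
    tol : float, default=1e-6
        Relative log-likelihood change below which EM stops.
    constrained_dispersion : bool, default=True
        One shared ε per component (recommended) instead of per-genome ε.
    resort : bool, default=True
        After convergence, re-order components by decreasing expected
        presence frequency so the persistent/cloud ends stay pinned even
        if labels drifted during EM.

    Attributes
    ----------
    weights_ : ndarray of shape (K,)
        Mixing proportions π.
    centroids_ : ndarray of shape (K, N)
        Binary centroids μ.
    dispersion_ : ndarray of shape (K, N)
        Dispersion ε.
    posteriors_ : ndarray of shape (F, K)
        Responsibilities at convergence.
    labels_ : ndarray of shape (F,)
        0-based component index per family.
    partitioning_ : Partitioning
        Biological labels (persistent/shell/cloud) with posteriors.
    log_likelihood_trace_ : list of float
        Log-likelihood at each E-step; non-decreasing up to round-off.
    """

    def __init__(
        self,
        n_partitions: int = 3,
        max_iter: int = 100,
        tol: float = 1e-6,
        constrained_dispersion: bool = True,
        resort: bool = True,
    ):
        self.n_partitions = n_partitions
        self.max_iter = max_iter
        self.tol = tol
        self.constrained_dispersion = constrained_dispersion
        self.resort = resort

    def _validate_X(self, X) -> tuple[np.ndarray, list[str] | None]:
        arr, fam = _as_array(X)
        arr = check_array(arr, dtype=np.int8)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("presence/absence matrix entries must be 0 or 1")
        return arr, fam

    def fit(self, X, y=None):
        """Run EM from the triangular start on the F×N binary matrix X."""
        arr, fam = self._validate_X(X)
        F, N = arr.shape
        K = self.n_partitions
        if K < 2:
            raise ValueError("n_partitions must be >= 2")
        if K > F:
            raise ValueError(f"n_partitions={K} exceeds the number of families F={F}")

        params = triangular_init(K, N, self.constrained_dispersion)
        trace: list[float] = []
        T = None
        for _ in range(self.max_iter):
            T, ll = e_step(arr, params)
            trace.append(ll)
            if len(trace) > 1:
                prev = trace[-2]
                if abs(ll - prev) < self.tol * abs(prev):
                    break
            params = m_step(arr, T, self.constrained_dispersion)

        if self.resort:
            order = np.argsort(-params.mean_presence(), kind="stable")
            params = params.reordered(order)
            T = T[:, order]

        self.params_ = params
        self.weights_ = params.pi
        self.centroids_ = params.mu
        self.dispersion_ = params.epsilon
        self.posteriors_ = T
        self.log_likelihood_trace_ = trace
        self.n_iter_ = len(trace)
        self.family_ids_ = fam
        self.partitioning_ = assign_partitions(T, K, fam)
        self.labels_ = self.partitioning_.components - 1
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Posterior responsibilities of new family profiles."""
        check_is_fitted(self, "params_")
        arr, _ = self._validate_X(X)
        T, _ = e_step(arr, self.params_)
        return T

    def predict(self, X) -> np.ndarray:
        """0-based component assignment of new family profiles."""
        return self.predict_proba(X).argmax(axis=1)

    def score(self, X, y=None) -> float:
        """Mean per-family log-likelihood under the fitted mixture."""
        check_is_fitted(self, "params_")
        arr, _ = self._validate_X(X)
        _, ll = e_step(arr, self.params_)
        return ll / arr.shape[0]


def run_binem(
    X,
    K: int,
    max_iter: int = 100,
    tol: float = 1e-6,
    constrained_dispersion: bool = True,
    resort: bool = True,
) -> tuple[BMMParams, np.ndarray, list[float]]:
    """Functional wrapper: fit the mixture and return (params, T, trace)."""
    est = BernoulliMixturePartitioner(
        n_partitions=K,
        max_iter=max_iter,
        tol=tol,
        constrained_dispersion=constrained_dispersion,
        resort=resort,
    ).fit(X)
    return est.params_, est.posteriors_, est.log_likelihood_trace_
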