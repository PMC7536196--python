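"""Scikit-learn estimator interface.

:class:`Hidalgo` is a clustering-style estimator: ``fit(X)`` segments the
rows of a coordinate matrix (or of a precomputed distance matrix, with
``metric="precomputed"``) into ``n_manifolds`` groups of homogeneous local
intrinsic dimension; ``labels_`` holds the hard assignment (1..K, with 0
for points whose membership probability never clears the threshold) and
``d_mean_`` the posterior-mean dimension of each manifold.  It composes
with standard sklearn tooling via ``get_params``/``set_params``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_array

from . import sampler
from .model import HidalgoConfig
from .neighbors import TWO_PI, compute_mu, find_neighbors, neighbor_stats
from .selection import KScanResult, scan_K

__all__ = ["Hidalgo"]


class Hidalgo(ClusterMixin, BaseEstimator):
    """Bayesian segmentation by local intrinsic dimension.

    Parameters
    ----------
    n_manifolds : int, default=2
        Number of manifolds K.  Choose it with :meth:`scan`, which compares
        the mean log-posterior across K.
    q : int, default=3
        Neighborhood range of the homogeneity term.
    xi : float, default=0.8
        Local homogeneity level in [0.5, 1); 0.5 disables the constraint.
        Values below 0.5 contradict the model's premise and require
        ``allow_low_xi=True``.
    metric : {"euclidean", "periodic_euclidean", "normalized_euclidean",
        "precomputed"}, default="euclidean"
        How to turn ``X`` into distances.  ``periodic_euclidean`` wraps
        coordinates with period ``period`` (angle data); ``precomputed``
        expects a square distance matrix.
    period : float or array-like, default=2*pi
        Coordinate period for the periodic metric.
    gamma_shape, gamma_rate : float, default=1.0
        Gamma prior on each manifold dimension (prior mean shape/rate).
    dirichlet_conc : float, default=1.0
        Dirichlet concentration on the mixing weights.
    n_sweeps : int, default=100_000
        Gibbs sweeps per chain.
    keep_fraction : float, default=0.1
        Trailing fraction of sweeps retained for all estimates.
    n_chains : int, default=10
        Independent restarts; the chain with the highest mean retained
        log-posterior is reported.
    assignment_threshold : float, default=0.8
        Minimum membership probability for a hard label.
    jitter : float, optional
        Amplitude of uniform coordinate noise to break exact ties
        (duplicated points are otherwise an error).
    backend : {"numba", "python"}, default="numba"
        Compiled kernel or the reference numpy sampler.
    random_state : int or RandomState, optional
        Seeds the chains (chain j uses seed + j).

    Attributes
    ----------
    labels_ : (N,) int array — manifold of each point, 1..K, 0 = unassigned.
    pi_ : (N, K) membership probabilities.
    d_mean_, d_sd_ : (K,) posterior mean / sd of the intrinsic dimensions.
    p_mean_ : (K,) posterior-mean mixing weights.
    mean_log_posterior_ : retained-sample mean log-posterior L of the best
        chain (the model-selection score).
    """

    def __init__(
        self,
        n_manifolds: int = 2,
        q: int = 3,
        xi: float = 0.8,
        metric: str = "euclidean",
        period=TWO_PI,
        gamma_shape: float = 1.0,
        gamma_rate: float = 1.0,
        dirichlet_conc: float = 1.0,
        n_sweeps: int = 100_000,
        keep_fraction: float = 0.1,
        n_chains: int = 10,
        assignment_threshold: float = 0.8,
        jitter: float | None = None,
        allow_low_xi: bool = False,
        backend: str = "numba",
        random_state=None,
    ):
        self.n_manifolds = n_manifolds
        self.q = q
        self.xi = xi
        self.metric = metric
        self.period = period
        self.gamma_shape = gamma_shape
        self.gamma_rate = gamma_rate
        self.dirichlet_conc = dirichlet_conc
        self.n_sweeps = n_sweeps
        self.keep_fraction = keep_fraction
        self.n_chains = n_chains
        self.assignment_threshold = assignment_threshold
        self.jitter = jitter
        self.allow_low_xi = allow_low_xi
        self.backend = backend
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _base_seed(self) -> int:
        if isinstance(self.random_state, (int, np.integer)):
            return int(self.random_state)
        rs = check_random_state(self.random_state)
        return int(rs.randint(0, 2**31 - 1))

    def _config(self, seed: int) -> HidalgoConfig:
        return HidalgoConfig(
            K=self.n_manifolds,
            q=self.q,
            xi=self.xi,
            a=self.gamma_shape,
            b=self.gamma_rate,
            c=self.dirichlet_conc,
            n_sweeps=self.n_sweeps,
            keep_fraction=self.keep_fraction,
            n_chains=self.n_chains,
            seed=seed,
            assignment_threshold=self.assignment_threshold,
            allow_low_xi=self.allow_low_xi,
        )

    def _stats(self, X):
        X = check_array(X, dtype=np.float64)
        if self.metric == "precomputed":
            n = X.shape[0]
            if X.shape[1] != n:
                raise ValueError("precomputed metric requires a square matrix")
            if not np.allclose(X, X.T, atol=1e-9):
                raise ValueError("precomputed distance matrix must be symmetric")
            return compute_mu(find_neighbors(X, self.q))
        return neighbor_stats(
            X,
            self.q,
            metric=self.metric,
            period=self.period,
            jitter=self.jitter,
            rng=np.random.default_rng(self._base_seed()),
        )

    def fit(self, X, y=None):
        """Segment the rows of X; y is ignored (unsupervised)."""
        seed = self._base_seed()
        stats = self._stats(X)
        cfg = self._config(seed)
        result = sampler.fit(stats, cfg, backend=self.backend)
        self.n_features_in_ = X.shape[1]
        self.stats_ = stats
        self.result_ = result
        self.labels_ = result.labels
        self.pi_ = result.pi
        self.d_mean_ = result.d_mean
        self.d_sd_ = result.d_sd
        self.p_mean_ = result.p_mean
        self.mean_log_posterior_ = result.L
        self.best_chain_ = result.best_chain
        return self

    def scan(self, X, K_min: int = 1, K_max: int = 6, delta: float | None = None) -> KScanResult:
        """Model selection: fit each K in ``K_min..K_max`` with identical
        settings and return the scan (``K_best`` maximizes the mean
        log-posterior).  Leaves the estimator fitted at ``K_best``."""
        seed = self._base_seed()
        stats = self._stats(X)
        scan_result = scan_K(
            stats, self._config(seed), K_min=K_min, K_max=K_max, delta=delta, backend=self.backend
        )
        best = scan_result.best_fit
        self.n_features_in_ = X.shape[1]
        self.stats_ = stats
        self.result_ = best
        self.labels_ = best.labels
        self.pi_ = best.pi
        self.d_mean_ = best.d_mean
        self.d_sd_ = best.d_sd
        self.p_mean_ = best.p_mean
        self.mean_log_posterior_ = best.L
        self.best_chain_ = best.best_chain
        self.scan_result_ = scan_result
        return scan_result

    def __sklearn_is_fitted__(self) -> bool:
        return hasattr(self, "labels_")
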