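"""Log-density building blocks of the heterogeneous-ID mixture model.

The model couples three ingredients:

* a Pareto likelihood ``f(mu | d) = d mu^-(d+1)`` per point, whose shape
  parameter is the intrinsic dimension of the manifold the point sits on;
* a mixture structure with latent labels ``z_i`` in 1..K, mixing weights
  ``p`` (Dirichlet prior) and per-manifold dimensions ``d_k`` (Gamma
  priors);
* a neighborhood-homogeneity likelihood for the directed q-neighbor graph:
  each of a point's q neighbor slots falls in the point's own manifold with
  probability ``xi`` and outside it with probability ``1 - xi``, normalized
  by a partition factor ``Z(xi, N_k)`` that depends on the manifold sizes.

The partition factor used here is the combinatorial normalization over
which of the q neighbor slots are in-manifold given the sizes,

.. math::

    Z(\\xi, N_k) = \\sum_{n=0}^{q} \\binom{N_k - 1}{n}
        \\binom{N - N_k}{q - n} \\xi^n (1 - \\xi)^{q - n},

which is exactly neutral at ``xi = 0.5`` (by the Vandermonde identity the
sum is then independent of ``N_k``), so the constrained posterior reduces
term-by-term to the unconstrained mixture there.

All computation is in log space.  ``log_posterior`` keeps *every* term that
depends on K — including the prior normalizers and the partition factors —
because its retained-sample average is compared across K during model
selection; only genuinely K-independent constants are dropped (there are
none: the value returned is the full log joint density of
``(mu, neighbor graph, z, d, p)``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln, logsumexp

from .neighbors import NeighborStats

__all__ = [
    "HidalgoConfig",
    "ChainState",
    "pareto_logpdf",
    "partition_function",
    "log_partition_table",
    "neighborhood_loglik",
    "log_posterior",
]

logger = logging.getLogger(__name__)


def _prior_vec(value, K: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=np.float64), (K,)).copy()
    if np.any(arr <= 0):
        raise ValueError(f"prior parameter {name} must be positive")
    return arr


@dataclass(frozen=True)
class HidalgoConfig:
    """Sampler and model configuration.

    Parameters
    ----------
    K : number of manifolds (mixture components).
    q : neighborhood range — how many nearest neighbors enter the
        homogeneity term (default 3, the method's working point).
    xi : local homogeneity level in [0.5, 1): probability that a neighbor
        belongs to the same manifold.  ``xi = 0.5`` is the no-constraint
        control; the model's premise requires xi > 0.5.
    a, b : Gamma prior shape/rate on each d_k (default 1, 1: prior mean 1).
    c : Dirichlet concentration on the mixing weights (default 1: flat).
    n_sweeps : Gibbs sweeps per chain (default 1e5).
    keep_fraction : retained tail of the chain used for all estimates
        (default 0.10 — the last 10% of the sweeps).
    n_chains : independent restarts M (default 10); the best chain by mean
        retained log-posterior is reported.
    assignment_threshold : minimum membership probability pi_ik for a hard
        assignment; below it the point is reported as unassigned
        (default 0.8).
    """

    K: int
    q: int = 3
    xi: float = 0.8
    a: np.ndarray = field(default=1.0)  # type: ignore[assignment]
    b: np.ndarray = field(default=1.0)  # type: ignore[assignment]
    c: np.ndarray = field(default=1.0)  # type: ignore[assignment]
    n_sweeps: int = 100_000
    keep_fraction: float = 0.10
    n_chains: int = 10
    seed: int = 0
    assignment_threshold: float = 0.8
    allow_low_xi: bool = False

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.q < 1:
            raise ValueError("q must be >= 1")
        lo = 0.0 if self.allow_low_xi else 0.5
        if not (lo <= self.xi < 1.0):
            raise ValueError(
                f"xi={self.xi} outside [{lo}, 1); xi >= 0.5 is the model's "
                "premise (xi = 0.5 disables the constraint)"
            )
        if not (0.0 < self.keep_fraction <= 1.0):
            raise ValueError("keep_fraction must be in (0, 1]")
        if self.n_sweeps < 1 or self.n_chains < 1:
            raise ValueError("n_sweeps and n_chains must be >= 1")
        if not (1.0 / self.K < self.assignment_threshold <= 1.0) and self.K > 1:
            raise ValueError("assignment_threshold must be in (1/K, 1]")
        for name in ("a", "b", "c"):
            object.__setattr__(self, name, _prior_vec(getattr(self, name), self.K, name))

    @property
    def n_retained(self) -> int:
        return int(math.ceil(self.keep_fraction * self.n_sweeps))

    def with_K(self, K: int) -> "HidalgoConfig":
        """Copy of the config for a different K (scalar priors re-broadcast)."""
        return replace(self, K=K, a=float(self.a[0]), b=float(self.b[0]), c=float(self.c[0]))


@dataclass
class ChainState:
    """Current Gibbs state: labels (0-based, internal), dimensions, weights."""

    z: np.ndarray
    d: np.ndarray
    p: np.ndarray
    log_post: float = np.nan

    @property
    def K(self) -> int:
        return self.d.shape[0]

    def counts(self) -> np.ndarray:
        return np.bincount(self.z, minlength=self.K).astype(np.int64)

    def validate(self) -> None:
        if self.z.min() < 0 or self.z.max() >= self.K:
            raise ValueError("labels out of range")
        if np.any(self.d <= 0):
            raise ValueError("dimensions must be positive")
        if abs(self.p.sum() - 1.0) > 1e-12 or np.any(self.p < 0):
            raise ValueError("p must lie on the simplex")


def pareto_logpdf(mu, d):
    """Log density ``ln d - (d+1) ln mu`` of the TWO-NN ratio (elementwise)."""
    mu = np.asarray(mu, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    if np.any(mu < 1.0):
        raise ValueError("mu must be >= 1 (r2 >= r1 by construction)")
    if np.any(d <= 0.0):
        raise ValueError("d must be positive")
    return np.log(d) - (d + 1.0) * np.log(mu)


def log_partition_table(xi: float, N: int, q: int) -> np.ndarray:
    """``ln Z(xi, N_k)`` for all sizes N_k = 0..N (index = size).

    The N_k = 0 entry is defined as the N_k = 1 value (an empty manifold,
    like a singleton, can have no in-manifold neighbors).
    """
    if not (0.0 < xi <= 1.0):
        raise ValueError("xi must be in (0, 1]")
    if q > N - 1:
        raise ValueError("q must be <= N - 1")
    n = np.arange(q + 1)
    sizes = np.arange(1, N + 1)[:, None]  # N_k
    log_c1 = gammaln(sizes) - gammaln(n + 1) - gammaln(sizes - n)
    log_c2 = gammaln(N - sizes + 1) - gammaln(q - n + 1) - gammaln(N - sizes - (q - n) + 1)
    valid = (n <= sizes - 1) & (q - n <= N - sizes)
    lxi = n * math.log(xi)
    if xi < 1.0:
        l1m = (q - n) * math.log1p(-xi)
    else:
        l1m = np.where(q - n == 0, 0.0, -np.inf)
    terms = np.where(valid, log_c1 + log_c2 + lxi + l1m, -np.inf)
    table = np.empty(N + 1)
    table[1:] = logsumexp(terms, axis=1)
    table[0] = table[1]
    return table


def partition_function(xi: float, N_k: int, N: int, q: int) -> float:
    """Partition factor Z(xi, N_k) for a single manifold size."""
    if not (0 <= N_k <= N):
        raise ValueError("need 0 <= N_k <= N")
    if N_k == 0:
        logger.debug("Z called with N_k=0; using the N_k=1 value")
    return float(np.exp(log_partition_table(xi, N, q)[N_k]))


def _n_in(neighbor_idx: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Number of each point's q neighbors sharing its label."""
    return np.sum(z[neighbor_idx] == z[:, None], axis=1)


def neighborhood_loglik(
    stats: NeighborStats,
    z: np.ndarray,
    xi: float,
    q: int | None = None,
    counts: np.ndarray | None = None,
    lnZ: np.ndarray | None = None,
) -> float:
    """Log likelihood of the directed q-neighbor graph given the labels.

    ``sum_i [ n_i_in ln xi + (q - n_i_in) ln(1-xi) - ln Z(xi, N_{z_i}) ]``.
    Returns -inf (with a warning) if xi = 1 and any neighbor crosses a
    manifold boundary.
    """
    q = stats.q if q is None else q
    N = stats.n_points
    K = int(z.max()) + 1
    if counts is None:
        counts = np.bincount(z, minlength=K)
    n_in = _n_in(stats.neighbor_idx[:, :q], z)
    if lnZ is None:
        lnZ = log_partition_table(xi, N, q)
    if xi >= 1.0:
        if np.any(n_in < q):
            logger.warning("xi=1 with out-of-manifold neighbors: likelihood is zero")
            return -np.inf
        return float(-np.sum(lnZ[counts[z]]))
    val = np.sum(n_in) * math.log(xi) + np.sum(q - n_in) * math.log1p(-xi)
    val -= np.sum(lnZ[counts[z]])
    return float(val)


def log_posterior(
    state: ChainState,
    stats: NeighborStats,
    cfg: HidalgoConfig,
    lnZ: np.ndarray | None = None,
) -> float:
    """Full log joint density of (mu, neighbor graph, z, d, p).

    This is the un-normalized log posterior sampled by the Gibbs chain; its
    retained-sample mean is the model-selection score L, so every
    K-dependent term (prior normalizers, partition factors) is kept.
    """
    if stats.mu is None:
        raise ValueError("stats.mu missing; run compute_mu first")
    z, d, p = state.z, state.d, state.p
    counts = np.bincount(z, minlength=cfg.K)
    lnmu = np.log(stats.mu)
    V_k = np.bincount(z, weights=lnmu, minlength=cfg.K)
    # Pareto likelihood: depends on each manifold only through (N_k, V_k)
    lp = float(np.sum(counts * np.log(d)) - np.sum((d + 1.0) * V_k))
    lp += neighborhood_loglik(stats, z, cfg.xi, cfg.q, counts, lnZ)
    # labels given mixing weights
    lp += float(np.sum(counts * np.log(p)))
    # Gamma priors on d (with normalizers: they depend on K)
    lp += float(
        np.sum(cfg.a * np.log(cfg.b) - gammaln(cfg.a) + (cfg.a - 1.0) * np.log(d) - cfg.b * d)
    )
    # Dirichlet prior on p (with normalizer)
    lp += float(gammaln(cfg.c.sum()) - np.sum(gammaln(cfg.c)) + np.sum((cfg.c - 1.0) * np.log(p)))
    return lp
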