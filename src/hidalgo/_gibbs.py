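"""Compiled Gibbs-sampling kernel.

One call runs a full chain: systematic scans over the labels (with exact
incremental bookkeeping of the mixture counts, the per-manifold sums of log
mu, and the partition-factor deltas), conjugate Gamma/Dirichlet updates for
the dimensions and mixing weights, and the full log joint density per
sweep.  The per-point label weight is, up to label-independent constants,

    ln w_k = ln p_k + ln d_k - (d_k + 1) ln mu_i
             + (n_i_in(k) + m_i(k)) * [ln xi - ln(1 - xi)]
             + N_k ln Z(N_k) - (N_k + 1) ln Z(N_k + 1)

with the point removed from its manifold first: n_i_in(k) counts the
point's own q neighbors with label k, m_i(k) counts the points that list it
as a neighbor and have label k, and N_k is the size of manifold k without
the point.  Correctness of this bookkeeping is pinned against full
log-posterior recomputation and against exact posterior enumeration on a
tiny system (via the optional joint-configuration tally).

Randomness is numba's Mersenne Twister, seeded once per chain, so a chain
is bit-reproducible given its seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["gibbs_chain", "z_logweights_kernel"]


@njit(cache=True)
def _z_logweights_into(w, i, z, counts, d, lnd, lnp, lnmu, nbr, in_indptr, in_indices, lnZ, logit_xi):
    """Label log-weights for point i (already removed from its manifold)."""
    K = d.shape[0]
    q = nbr.shape[1]
    for k in range(K):
        w[k] = 0.0
    for t in range(q):
        w[z[nbr[i, t]]] += logit_xi
    for ptr in range(in_indptr[i], in_indptr[i + 1]):
        w[z[in_indices[ptr]]] += logit_xi
    for k in range(K):
        nk = counts[k]
        w[k] += lnp[k] + lnd[k] - (d[k] + 1.0) * lnmu[i] + nk * lnZ[nk] - (nk + 1) * lnZ[nk + 1]


@njit(cache=True)
def z_logweights_kernel(i, z, counts, d, p, lnmu, nbr, in_indptr, in_indices, lnZ, logit_xi):
    """Standalone label log-weights for tests; removes point i itself."""
    K = d.shape[0]
    w = np.empty(K)
    k0 = z[i]
    counts2 = counts.copy()
    counts2[k0] -= 1
    lnd = np.log(d)
    lnp = np.log(p)
    _z_logweights_into(w, i, z, counts2, d, lnd, lnp, lnmu, nbr, in_indptr, in_indices, lnZ, logit_xi)
    return w


@njit(cache=True)
def gibbs_chain(
    lnmu,
    nbr,
    in_indptr,
    in_indices,
    K,
    xi,
    a,
    b,
    c,
    lnZ,
    n_sweeps,
    n_retained,
    seed,
    tally_configs,
):
    """Run one chain; returns retained samples, tallies and the L series.

    Returns
    -------
    d_samples, p_samples, counts_samples : (S, K) retained per-sweep values
    z_tally : (N, K) per-point label frequencies over the retained sweeps
    log_post : (n_sweeps,) full log joint density per sweep
    config_tally : (K**N,) joint-configuration counts over retained sweeps
        if ``tally_configs`` (tiny systems only), else a length-1 dummy.
    """
    np.random.seed(seed)
    N = lnmu.shape[0]
    q = nbr.shape[1]
    keep_start = n_sweeps - n_retained

    lxi = math.log(xi)
    l1mxi = math.log(1.0 - xi)
    logit_xi = lxi - l1mxi

    # random initial configuration: uniform labels, priors for d and p
    z = np.empty(N, dtype=np.int64)
    for i in range(N):
        z[i] = np.random.randint(0, K)
    d = np.empty(K)
    p = np.empty(K)
    s = 0.0
    for k in range(K):
        d[k] = np.random.gamma(a[k], 1.0 / b[k])
        p[k] = np.random.gamma(c[k], 1.0)
        s += p[k]
    for k in range(K):
        p[k] /= s

    counts = np.zeros(K, dtype=np.int64)
    V = np.zeros(K)
    for i in range(N):
        counts[z[i]] += 1
        V[z[i]] += lnmu[i]

    lnd = np.log(d)
    lnp = np.log(p)

    # K-dependent prior normalizers (constant over the run)
    prior_const = 0.0
    csum = 0.0
    for k in range(K):
        prior_const += a[k] * math.log(b[k]) - math.lgamma(a[k]) - math.lgamma(c[k])
        csum += c[k]
    prior_const += math.lgamma(csum)

    d_samples = np.empty((n_retained, K))
    p_samples = np.empty((n_retained, K))
    counts_samples = np.empty((n_retained, K), dtype=np.int64)
    z_tally = np.zeros((N, K), dtype=np.int64)
    log_post = np.empty(n_sweeps)
    if tally_configs:
        config_tally = np.zeros(K**N, dtype=np.int64)
    else:
        config_tally = np.zeros(1, dtype=np.int64)

    w = np.empty(K)
    for sweep in range(n_sweeps):
        # -- labels, systematic scan with incremental count/V updates
        for i in range(N):
            k0 = z[i]
            counts[k0] -= 1
            V[k0] -= lnmu[i]
            _z_logweights_into(
                w, i, z, counts, d, lnd, lnp, lnmu, nbr, in_indptr, in_indices, lnZ, logit_xi
            )
            wmax = w[0]
            for k in range(1, K):
                if w[k] > wmax:
                    wmax = w[k]
            tot = 0.0
            for k in range(K):
                w[k] = math.exp(w[k] - wmax)
                tot += w[k]
            u = np.random.random() * tot
            cum = 0.0
            knew = K - 1
            for k in range(K):
                cum += w[k]
                if u <= cum:
                    knew = k
                    break
            z[i] = knew
            counts[knew] += 1
            V[knew] += lnmu[i]

        # -- dimensions: conjugate Gamma(a + N_k, b + V_k)
        for k in range(K):
            d[k] = np.random.gamma(a[k] + counts[k], 1.0 / (b[k] + V[k]))
            lnd[k] = math.log(d[k])

        # -- mixing weights: conjugate Dirichlet(c + counts)
        tot = 0.0
        for k in range(K):
            p[k] = np.random.gamma(c[k] + counts[k], 1.0)
            tot += p[k]
        for k in range(K):
            p[k] /= tot
            lnp[k] = math.log(p[k])

        # -- full log joint density
        lp = prior_const
        for k in range(K):
            lp += counts[k] * lnd[k] - (d[k] + 1.0) * V[k]
            lp += counts[k] * lnp[k]
            lp += (a[k] - 1.0) * lnd[k] - b[k] * d[k]
            lp += (c[k] - 1.0) * lnp[k]
        for i in range(N):
            nin = 0
            for t in range(q):
                if z[nbr[i, t]] == z[i]:
                    nin += 1
            lp += nin * lxi + (q - nin) * l1mxi - lnZ[counts[z[i]]]
        log_post[sweep] = lp

        if sweep >= keep_start:
            idx = sweep - keep_start
            for k in range(K):
                d_samples[idx, k] = d[k]
                p_samples[idx, k] = p[k]
                counts_samples[idx, k] = counts[k]
            for i in range(N):
                z_tally[i, z[i]] += 1
            if tally_configs:
                code = 0
                for i in range(N):
                    code = code * K + z[i]
                config_tally[code] += 1

    return d_samples, p_samples, counts_samples, z_tally, log_post, config_tally
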