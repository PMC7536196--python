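# hidalgo

Segmentation of point clouds by **local intrinsic dimension** (ID): a
Bayesian mixture model that splits a dataset into K manifolds, each with
its own dimension, using only distances between points.

## The problem

The intrinsic dimension — the number of independent directions along which
data spread locally — is usually treated as one number per dataset.  In
many real datasets it is not: molecular-dynamics trajectories mix folded
(high-ID) and unfolded (low-ID) configurations, task-driven brain voxels
carry higher-dimensional signals than idle ones, and so on.  This package
segments points by their local ID, a purely topological feature that is
insensitive to density variations, curvature and topology.

## The model

For each point *i*, let `r_i1 <= r_i2` be the distances to its first and
second nearest neighbors.  Under local density uniformity the ratio
`mu_i = r_i2 / r_i1` follows a Pareto law whose shape is the local ID:

    f(mu | d) = d * mu^-(d+1),        mu >= 1.

With K manifolds of dimensions `d_1..d_K`, prior weights `p` and latent
labels `z_i`, the mu-likelihood alone cannot assign points (Pareto
densities overlap heavily), so a neighborhood-homogeneity term couples
each point to its q nearest neighbors: a neighbor falls inside the point's
own manifold with probability `xi > 1/2`,

    P(graph | z) = prod_i  xi^(n_i_in) (1 - xi)^(q - n_i_in) / Z(xi, N_z_i),

where `n_i_in` counts point i's q neighbors sharing its label and
`Z(xi, N_k) = sum_n C(N_k-1, n) C(N-N_k, q-n) xi^n (1-xi)^(q-n)` is the
partition factor given the manifold sizes.  Gamma priors on `d_k`,
a Dirichlet prior on `p`, and Gibbs sampling over `(z, d, p)` yield
posterior-mean dimensions, membership probabilities `pi_ik`, and hard
labels (`pi_ik > 0.8`, otherwise "unassigned").  The number of manifolds K
is chosen by scanning K and comparing the mean retained log-posterior.
The working point is `q = 3, xi = 0.8`; `xi = 0.5` switches the
neighborhood term off exactly.

## Worked example

```python
from hidalgo import Hidalgo, make_gaussian_pair, nmi

data = make_gaussian_pair(8, 4, n=1000, seed=1)   # dims 8 and 4, overlapping
est = Hidalgo(n_manifolds=2, q=3, xi=0.8,
              n_sweeps=20_000, n_chains=3, random_state=5)
est.fit(data.data)
print("dimensions:", est.d_mean_.round(2))
print("NMI vs truth:", round(nmi(est.labels_, data.labels), 3))
```

prints (exact values depend on the seed)

```
dimensions: [8.1  4.05]
NMI vs truth: 0.974
```

i.e. the two interleaved Gaussian clouds are separated almost perfectly
and their dimensions are recovered.  `est.pi_` holds the per-point
membership probabilities; `est.labels_` uses `0` for points whose largest
membership probability does not clear the 0.8 threshold.

The same pipeline runs from the shell:

```bash
hidalgo simulate --preset gauss2:8 --n 1000 --seed 1 --out sim/
hidalgo fit --input sim/data.csv --k 2 --sweeps 20000 --chains 3 --seed 5 --out fit/
hidalgo evaluate --pred fit/labels.csv --truth sim/labels.csv
hidalgo scan-k --input sim/data.csv --kmin 1 --kmax 4 --sweeps 20000 --out scan/
```

Distance matrices (`--distances`), periodic metrics for angle data
(`--metric periodic`) and row-normalized metrics (`--metric normalized`)
are supported; see `hidalgo fit --help`.

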