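"""Synthetic multi-manifold benchmarks with ground-truth labels.

These generators reproduce, offline, the standard validation setups for
heterogeneous intrinsic-dimension segmentation:

* a pair of Gaussians of dimensions (d1, d2) with per-coordinate scale
  ``1/d_i``, partly overlapping (:func:`make_gaussian_pair`);
* five Gaussians of dimensions 1, 2, 4, 5, 9 (same per-coordinate scale
  convention) with an intersecting placement
  (:func:`make_five_gaussians`), either flat in R^9 or carried by curved
  embeddings (circle, torus, Swiss roll, two spheres) in R^10.

Exact placements are a documented convention (the module-level tables
below) honouring the benchmarks' qualitative constraints: the dimension-4
and dimension-5 Gaussians sit half a unit apart, the dimension-1 Gaussian
is a line crossing both, intersecting pairs have centers one unit apart.
Center offsets between close same-scale components are taken *orthogonal*
to the components' spans: this is what keeps their q-nearest-neighbor
graphs nearly separated (the regime in which segmentation by local
intrinsic dimension is demonstrably possible) while the point clouds still
overlap in projection.  Low-dimensional components have much smaller
nearest-neighbor spacings than high-dimensional ones, so intersections
contaminate mainly the highest-dimensional component's neighborhoods.

Every embedding map is locally (approximately) isometric on the sampled
region, so it preserves the local intrinsic dimension — the quantity the
segmentation method measures.  A 9-sphere needs 10 ambient coordinates, so
the curved benchmark lives in R^10.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ManifoldComponent",
    "SyntheticSpec",
    "LabeledDataset",
    "embed",
    "generate",
    "make_gaussian_pair",
    "make_five_gaussians",
    "preset_dataset",
]

#: ambient slots an embedding consumes for latent dimension m
_EMBED_SLOTS = {
    "linear": lambda m: m,
    "circle": lambda m: 2,
    "torus": lambda m: 3,
    "swiss_roll": lambda m: m + 1,
    "sphere": lambda m: m + 1,
}


@dataclass(frozen=True)
class ManifoldComponent:
    """One mixture component of a synthetic benchmark.

    ``axes`` picks the ambient coordinates the embedded component occupies
    (default: the first ones); ``center`` is an ambient offset, zero-padded.
    ``scale`` multiplies the latent standard-normal coordinates.
    """

    intrinsic_dim: int
    n_points: int = 1000
    scale: float = 1.0
    embedding: str = "linear"
    center: tuple = ()
    axes: tuple | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.intrinsic_dim < 1 or self.n_points < 1:
            raise ValueError("intrinsic_dim and n_points must be >= 1")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.embedding not in _EMBED_SLOTS:
            raise ValueError(f"unknown embedding {self.embedding!r}")
        if self.embedding == "circle" and self.intrinsic_dim != 1:
            raise ValueError("circle embedding requires intrinsic_dim 1")
        if self.embedding == "torus" and self.intrinsic_dim != 2:
            raise ValueError("torus embedding requires intrinsic_dim 2")
        if self.embedding == "swiss_roll" and self.intrinsic_dim < 2:
            raise ValueError("swiss_roll embedding requires intrinsic_dim >= 2")
        if self.axes is not None and len(self.axes) != self.ambient_slots:
            raise ValueError(
                f"axes must list exactly {self.ambient_slots} ambient slots"
            )

    @property
    def ambient_slots(self) -> int:
        return _EMBED_SLOTS[self.embedding](self.intrinsic_dim)


@dataclass(frozen=True)
class SyntheticSpec:
    """Component list + ambient dimension; ``generate`` realizes it."""

    components: tuple
    ambient_dim: int

    def __post_init__(self):
        for comp in self.components:
            if comp.ambient_slots > self.ambient_dim:
                raise ValueError(
                    f"embedding {comp.embedding!r} of a {comp.intrinsic_dim}-manifold "
                    f"needs {comp.ambient_slots} ambient slots, have {self.ambient_dim}"
                )
            if comp.axes is not None and max(comp.axes) >= self.ambient_dim:
                raise ValueError("component axes outside the ambient space")


@dataclass(frozen=True)
class LabeledDataset:
    """Coordinate matrix plus ground-truth component labels (1-based)."""

    data: np.ndarray
    labels: np.ndarray
    dims: tuple  # intrinsic dimension of each component, by label order

    @property
    def n_points(self) -> int:
        return self.data.shape[0]


def embed(latent: np.ndarray, embedding: str, **params) -> np.ndarray:
    """Map latent points into their curved embedding (no padding/centering).

    circle (latent m=1, radius R): arc-length parameterization
        ``t -> R (cos t/R, sin t/R)`` — locally isometric, so a latent
        spread of ~3 wraps a good part of the circle without self-overlap
        for R around 1.5.
    torus (latent m=2, radii R > r): angles ``u = t1/R, v = t2/r`` into
        ``((R + r cos v) cos u, (R + r cos v) sin u, r sin v)``.
    swiss_roll (latent m >= 2): the first latent coordinate becomes the
        arc length ``l = offset + t1`` along the spiral ``(s cos s, s sin s)``
        with ``s = sqrt(2 l)`` (unit speed, hence locally isometric); the
        base point at ``l = offset`` is moved to the origin; remaining
        latent coordinates pass through unchanged.
    sphere (latent m+1 coordinates, radius R): rows are radially projected
        onto the sphere S^m of radius R (uniform for standard-normal
        latents).
    """
    x = np.asarray(latent, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("latent must be 2-D (n_points, m)")
    m = x.shape[1]
    if embedding == "linear":
        return x.copy()
    if embedding == "circle":
        if m != 1:
            raise ValueError("circle embedding expects 1 latent coordinate")
        R = params.get("radius", 1.5)
        t = x[:, 0] / R
        return R * np.column_stack([np.cos(t), np.sin(t)])
    if embedding == "torus":
        if m != 2:
            raise ValueError("torus embedding expects 2 latent coordinates")
        R = params.get("R", 2.0)
        r = params.get("r", 0.75)
        u = x[:, 0] / R
        v = x[:, 1] / r
        ring = R + r * np.cos(v)
        return np.column_stack([ring * np.cos(u), ring * np.sin(u), r * np.sin(v)])
    if embedding == "swiss_roll":
        if m < 2:
            raise ValueError("swiss_roll embedding expects >= 2 latent coordinates")
        offset = params.get("offset", 30.0)
        arclen = offset + x[:, 0]
        if np.any(arclen <= 0):
            raise ValueError("swiss_roll arc length went non-positive; increase offset")
        s = np.sqrt(2.0 * arclen)
        s0 = math.sqrt(2.0 * offset)
        spiral = np.column_stack(
            [s * np.cos(s) - s0 * math.cos(s0), s * np.sin(s) - s0 * math.sin(s0)]
        )
        return np.hstack([spiral, x[:, 1:]])
    if embedding == "sphere":
        # latent carries m+1 coordinates for S^m
        R = params.get("radius", float(np.sqrt(m - 1)))
        norms = np.linalg.norm(x, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("zero latent vector cannot be projected to the sphere")
        return R * x / norms
    raise ValueError(f"unknown embedding {embedding!r}")


def generate(spec: SyntheticSpec, seed: int | None = 0) -> LabeledDataset:
    """Realize a :class:`SyntheticSpec` with a seeded generator."""
    rng = np.random.default_rng(seed)
    blocks = []
    labels = []
    dims = []
    for idx, comp in enumerate(spec.components, start=1):
        m = comp.intrinsic_dim
        n_latent = m + 1 if comp.embedding == "sphere" else m
        if comp.embedding == "sphere":
            latent = rng.standard_normal((comp.n_points, n_latent))
        else:
            latent = comp.scale * rng.standard_normal((comp.n_points, n_latent))
        emb = embed(latent, comp.embedding, **comp.params)
        block = np.zeros((comp.n_points, spec.ambient_dim))
        axes = comp.axes if comp.axes is not None else tuple(range(emb.shape[1]))
        block[:, list(axes)] = emb
        center = np.zeros(spec.ambient_dim)
        center[: len(comp.center)] = comp.center
        block += center
        blocks.append(block)
        labels.append(np.full(comp.n_points, idx, dtype=np.int64))
        dims.append(m)
    return LabeledDataset(
        data=np.vstack(blocks), labels=np.concatenate(labels), dims=tuple(dims)
    )


def make_gaussian_pair(
    d1: int,
    d2: int = 4,
    n: int = 1000,
    center_offset: float = 0.5,
    seed: int | None = 0,
) -> LabeledDataset:
    """Two Gaussians of dimensions d1 >= d2 with per-coordinate scale 1/d_i.

    Both are zero-padded into the ambient space R^max(d1,d2).  The second
    (lower-dimensional) component's center sits ``center_offset`` away
    along the first ambient axis orthogonal to its own span — the direction
    in which two manifolds of different dimension naturally sit apart — so
    at the default offset the clouds overlap in their tails.  (For
    d1 == d2 no orthogonal axis exists and the offset falls back to the
    first axis.)  Component 1 carries dimension d1, component 2 dimension
    d2.
    """
    if not (d1 >= d2 >= 1):
        raise ValueError("need d1 >= d2 >= 1")
    ambient = max(d1, d2)
    center = np.zeros(ambient)
    center[d2 if d1 > d2 else 0] = center_offset
    spec = SyntheticSpec(
        components=(
            ManifoldComponent(intrinsic_dim=d1, n_points=n, scale=1.0 / d1),
            ManifoldComponent(
                intrinsic_dim=d2, n_points=n, scale=1.0 / d2, center=tuple(center)
            ),
        ),
        ambient_dim=ambient,
    )
    return generate(spec, seed)


#: documented placement convention for the flat five-Gaussian benchmark
#: (ambient R^9, per-coordinate scale 1/d).  Each entry:
#: (scale, axes the component spans, center).  The d=4 and d=5 centers are
#: 0.5 apart along the fifth axis — a direction inside the d=5 span but
#: orthogonal to the d=4 span, so the two clouds overlap only in their
#: tails, exactly like the two-Gaussian benchmark.  The d=1 line runs
#: along that same axis (slightly off-center), piercing the d=4 cloud and
#: the d=5 slab; the d=2 plane sits one unit from the line's center and
#: intersects the line; the compact d=9 cloud sits one unit away along the
#: ninth axis.
_H2 = math.sqrt(1.0 - 0.81)
FIVE_GAUSSIAN_PLACEMENT = {
    1: (1.0, (4,), (0.3,)),
    2: (0.5, (0, 1), (0.3, _H2, 0, 0, 0.9)),
    4: (0.25, (0, 1, 2, 3), ()),
    5: (0.2, (0, 1, 2, 3, 4), (0, 0, 0, 0, 0.5)),
    9: (1.0 / 9.0, tuple(range(9)), (0,) * 8 + (1.0,)),
}

#: Curved variant (ambient R^10): the circle threads the region below the
#: torus, the Swiss-roll patch crosses the torus tube, the sphere S^5
#: encloses the circle at a small clearance, and the sparse S^9 shell sits
#: offset along the tenth axis.  Each entry:
#: (embedding, params, scale, axes, center).
FIVE_CURVED = {
    1: ("circle", {"radius": 1.5}, 1.0, (0, 1), ()),
    2: ("torus", {"R": 2.0, "r": 0.75}, 0.5, (0, 1, 2), (0, 0, 1.3)),
    4: ("swiss_roll", {"offset": 30.0}, 0.25, (0, 1, 3, 4, 5), (2.3, 0, 0.9)),
    5: ("sphere", {"radius": 1.0}, 1.0, (0, 1, 2, 3, 4, 5), ()),
    9: ("sphere", {"radius": 1.0}, 1.0, tuple(range(10)), (0,) * 9 + (1.5,)),
}


def make_five_gaussians(
    curved: bool = False,
    n: int = 1000,
    seed: int | None = 0,
    center_scale: float = 1.0,
) -> LabeledDataset:
    """Five Gaussians of dimensions 1, 2, 4, 5, 9 with intersecting placement.

    ``curved=False``: flat components in R^9 with the placement of
    :data:`FIVE_GAUSSIAN_PLACEMENT`.  ``curved=True``: the same intrinsic
    dimensions carried by a circle, a torus, a 4-D Swiss roll and spheres
    S^5 and S^9 in R^10 (:data:`FIVE_CURVED`).  ``center_scale``
    multiplies all center offsets (large values isolate the components,
    used as a control).
    """
    if n < 10:
        raise ValueError("need n >= 10 per component")
    comps = []
    for d in (1, 2, 4, 5, 9):
        if curved:
            embedding, params, scale, axes, center = FIVE_CURVED[d]
        else:
            embedding, params = "linear", {}
            scale, axes, center = FIVE_GAUSSIAN_PLACEMENT[d]
        comps.append(
            ManifoldComponent(
                intrinsic_dim=d,
                n_points=n,
                scale=scale,
                embedding=embedding,
                center=tuple(center_scale * c for c in center),
                axes=axes,
                params=params,
            )
        )
    spec = SyntheticSpec(components=tuple(comps), ambient_dim=10 if curved else 9)
    return generate(spec, seed)


def preset_dataset(name: str, n: int = 1000, seed: int | None = 0) -> LabeledDataset:
    """Named benchmark presets for the command line.

    ``gauss2:<d1>`` — Gaussian pair (d1, 4); ``gauss5`` — five flat
    Gaussians; ``gauss5-curved`` — five curved manifolds.
    """
    if name.startswith("gauss2:"):
        return make_gaussian_pair(int(name.split(":", 1)[1]), 4, n=n, seed=seed)
    if name == "gauss5":
        return make_five_gaussians(curved=False, n=n, seed=seed)
    if name == "gauss5-curved":
        return make_five_gaussians(curved=True, n=n, seed=seed)
    raise ValueError(f"unknown preset {name!r} (use gauss2:<d1>, gauss5, gauss5-curved)")
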