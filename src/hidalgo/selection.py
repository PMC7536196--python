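"""Model selection: choose the number of manifolds K.

The number of mixture components is selected by scanning K and comparing
the mean retained log-posterior L of the best chain for each K, computed
under the identical retained-sample rule and constant-term convention (the
full log joint density), so the values are comparable across K.  The
default is a full scan reporting the argmax; since each L is a Monte-Carlo
estimate, a difference from the maximum within twice its combined standard
error (batch-means estimates) counts as a tie, and ties resolve toward the
smaller K.  An optional early-stop threshold ``delta`` stops as
soon as the improvement L(K+1) - L(K) falls below it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import HidalgoConfig
from .neighbors import NeighborStats
from .sampler import FitResult, fit

__all__ = ["KScanResult", "scan_K"]


@dataclass
class KScanResult:
    K_values: list[int]
    L_values: list[float]
    K_best: int
    fits: list[FitResult]

    @property
    def best_fit(self) -> FitResult:
        return self.fits[self.K_values.index(self.K_best)]


def scan_K(
    stats: NeighborStats,
    base_cfg: HidalgoConfig,
    K_min: int = 1,
    K_max: int = 6,
    delta: float | None = None,
    backend: str = "numba",
) -> KScanResult:
    """Fit every K in ``K_min..K_max`` with identical settings and seeds.

    ``delta`` (off by default) enables early stopping when the score gain
    drops below it; the full scan is the reproducible default.
    """
    if not (1 <= K_min <= K_max):
        raise ValueError("need 1 <= K_min <= K_max")
    K_values: list[int] = []
    L_values: list[float] = []
    fits: list[FitResult] = []
    for K in range(K_min, K_max + 1):
        result = fit(stats, base_cfg.with_K(K), backend=backend)
        K_values.append(K)
        L_values.append(result.L)
        fits.append(result)
        if delta is not None and len(L_values) >= 2 and L_values[-1] - L_values[-2] < delta:
            break
    # argmax; a difference of two Monte-Carlo estimates within twice its
    # combined standard error is a tie, resolved toward the smaller K
    best_idx = int(np.argmax(L_values))
    for idx in range(len(L_values)):
        tol = 2.0 * math.hypot(fits[best_idx].L_se, fits[idx].L_se)
        if L_values[best_idx] - L_values[idx] <= tol:
            best_idx = idx
            break
    return KScanResult(K_values=K_values, L_values=L_values, K_best=K_values[best_idx], fits=fits)
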