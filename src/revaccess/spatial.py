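"""Spatial weights and global Moran's I.

Weights follow the study convention for outlet-level diagnostics: inverse
Euclidean distance between outlet points, zero diagonal, optionally
row-standardized. Moran's I is reported with its analytic null moments; the
z/p default to the normality assumption, with the randomization
(permutation-consistent) variance available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["SpatialWeights", "MoranResult", "inverse_distance_weights", "morans_i",
           "residual_moran"]


@dataclass
class SpatialWeights:
    """An n x n nonnegative spatial-weights matrix with zero diagonal."""

    ids: list
    W: np.ndarray
    style: str = "raw"  # raw | row_standardized

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.ids)
        if self.W.shape != (n, n):
            raise ValueError(f"weights shape {self.W.shape} does not match {n} ids")
        if np.any(self.W < 0):
            raise ValueError("weights must be nonnegative")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("weights diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def s0(self) -> float:
        return float(self.W.sum())

    def row_standardized(self) -> "SpatialWeights":
        """Return a copy whose rows sum to one (rows with no neighbor stay zero)."""
        if self.style == "row_standardized":
            return self
        rs = self.W.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        return SpatialWeights(list(self.ids), self.W / rs, style="row_standardized")


@dataclass
class MoranResult:
    I: float
    expected_I: float
    variance: float
    z_score: float
    p_value: float
    n: int

    def significant(self, z_crit: float = 1.96) -> bool:
        return abs(self.z_score) >= z_crit


def inverse_distance_weights(points: np.ndarray, min_dist_m: float = 1.0,
                             ids: list | None = None) -> SpatialWeights:
    """w_ij = 1 / max(d_ij, min_dist_m) on Euclidean distances, zero diagonal.

    The floor caps the weight of (near-)coincident points at 1/min_dist_m.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 2:
        raise ValueError("need at least 2 points for spatial weights")
    diff = points[:, None, :] - points[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    W = 1.0 / np.maximum(d, min_dist_m)
    np.fill_diagonal(W, 0.0)
    return SpatialWeights(ids if ids is not None else list(range(n)), W, style="raw")


def expected_morans_i(n: int) -> float:
    """Null expectation of Moran's I for n observations: -1/(n-1)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return -1.0 / (n - 1)


def _moments(W: np.ndarray, z: np.ndarray, assumption: str) -> tuple[float, float]:
    n = len(z)
    s0 = W.sum()
    s1 = 0.5 * ((W + W.T) ** 2).sum()
    s2 = ((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum()
    e_i = -1.0 / (n - 1)
    if assumption == "normality":
        var = (n * n * s1 - n * s2 + 3 * s0 * s0) / (s0 * s0 * (n * n - 1)) - e_i ** 2
    elif assumption == "randomization":
        b2 = n * (z ** 4).sum() / ((z ** 2).sum() ** 2)
        num = (n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0)
               - b2 * ((n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0))
        var = num / ((n - 1) * (n - 2) * (n - 3) * s0 * s0) - e_i ** 2
    else:
        raise ValueError(f"unknown assumption {assumption!r}")
    return e_i, float(var)


def morans_i(values: np.ndarray, weights: SpatialWeights,
             assumption: str = "normality") -> MoranResult:
    """Global Moran's I: I = (n/S0) * (z' W z) / (z' z), z = x - mean(x).

    The two-sided p-value uses the normal approximation under the chosen
    null (``normality`` or ``randomization``).
    """
    x = np.asarray(values, dtype=float)
    n = weights.n
    if len(x) != n:
        raise ValueError(f"{len(x)} values vs {n} weights ids")
    if n < 4:
        raise ValueError("Moran's I requires n >= 4")
    z = x - x.mean()
    denom = (z ** 2).sum()
    if denom == 0:
        raise ValueError("Moran's I undefined for zero variance")
    W = weights.W
    I = (n / W.sum()) * float(z @ W @ z) / denom
    e_i, var = _moments(W, z, assumption)
    if var <= 0:
        raise ValueError("degenerate weights: non-positive Moran variance")
    z_score = (I - e_i) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z_score))
    return MoranResult(I=float(I), expected_I=e_i, variance=var,
                       z_score=float(z_score), p_value=float(p), n=n)


def residual_moran(residuals: np.ndarray, weights: SpatialWeights,
                   assumption: str = "normality") -> MoranResult:
    """Moran's I of standardized model residuals.

    I is scale-invariant, so standardization does not change the statistic;
    it is applied anyway so the residual vector carried in reports is on a
    common scale.
    """
    r = np.asarray(residuals, dtype=float)
    sd = r.std(ddof=1)
    if sd == 0:
        raise ValueError("Moran's I undefined for zero variance")
    return morans_i(r / sd, weights, assumption=assumption)
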