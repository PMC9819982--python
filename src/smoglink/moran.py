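"""Global and local Moran's I spatial autocorrelation.

Global statistic for a cross-section x on weights W:

    I = n / S0 * [sum_ij w_ij (x_i - xbar)(x_j - xbar)] / sum_i (x_i - xbar)^2

equivalently the classical form with the population variance
S^2 = sum_i (x_i - xbar)^2 / n in the denominator and S0 = sum_ij w_ij.
E[I] = -1/(n-1) under the no-autocorrelation null.  Inference is offered
two ways: the normal approximation with randomization moments, and a
permutation test (two-sided pseudo p with the +1 correction), which is
what common GIS software defaults to.

The local (Anselin) statistic I_i = ((x_i - xbar)/S^2) * sum_j w_ij (x_j - xbar)
decomposes the global value: with row-standardized W the mean of the local
values equals the global I.  Moran-scatter quadrant labels (HH, HL, LH, LL)
classify each region by the signs of its own deviation and its spatial
lag's deviation; exact zeros count as positive so every region gets a
deterministic label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .weights import SpatialWeights

__all__ = [
    "MoranResult",
    "global_moran",
    "local_moran",
    "permutation_test",
    "moran_quadrants",
]


class MoranError(ValueError):
    pass


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected_I: float
    z: float
    p_normal: float
    p_perm: float | None = None
    n_perm: int = 0
    local_I: np.ndarray | None = None
    quadrant: tuple[str, ...] | None = None

    def to_dict(self) -> dict:
        d = {
            "I": self.I,
            "expected_I": self.expected_I,
            "z": self.z,
            "p_normal": self.p_normal,
            "p_perm": self.p_perm,
            "n_perm": self.n_perm,
        }
        if self.local_I is not None:
            d["local_I"] = list(map(float, self.local_I))
        if self.quadrant is not None:
            d["quadrant"] = list(self.quadrant)
        return d


def _check_inputs(x: np.ndarray, w: SpatialWeights) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.shape[0] != w.n:
        raise MoranError(f"x must be a length-{w.n} vector")
    if x.shape[0] < 3:
        raise MoranError("Moran's I needs n >= 3")
    if np.ptp(x) == 0:
        raise MoranError("x is constant: variance is degenerate")
    return x


def _moran_stat(z: np.ndarray, W: np.ndarray) -> float:
    # z must be mean-deviations
    return float(len(z) * z @ W @ z / (W.sum() * (z @ z)))


def global_moran(x: np.ndarray, w: SpatialWeights) -> MoranResult:
    """Global Moran's I with normal-approximation inference.

    The z score and two-sided p use the moments of I under the
    randomization (permutation) null.
    """
    x = _check_inputs(x, w)
    W = w.w
    n = len(x)
    z = x - x.mean()
    I = _moran_stat(z, W)
    EI = -1.0 / (n - 1)

    # randomization variance (standard S0/S1/S2/b2 moments)
    S0 = W.sum()
    S1 = 0.5 * ((W + W.T) ** 2).sum()
    S2 = ((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum()
    m2 = (z**2).sum() / n
    m4 = (z**4).sum() / n
    b2 = m4 / m2**2
    num = n * ((n**2 - 3 * n + 3) * S1 - n * S2 + 3 * S0**2) - b2 * (
        (n**2 - n) * S1 - 2 * n * S2 + 6 * S0**2
    )
    den = (n - 1) * (n - 2) * (n - 3) * S0**2
    VI = num / den - EI**2
    zscore = (I - EI) / np.sqrt(VI)
    p = 2 * stats.norm.sf(abs(zscore))
    return MoranResult(I=I, expected_I=EI, z=float(zscore), p_normal=float(p))


def local_moran(x: np.ndarray, w: SpatialWeights) -> np.ndarray:
    """Anselin local Moran's I_i; mean equals global I for row-standardized W."""
    x = _check_inputs(x, w)
    z = x - x.mean()
    s2 = (z**2).sum() / len(z)
    return z * (w.w @ z) / s2


def permutation_test(
    x: np.ndarray,
    w: SpatialWeights,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> MoranResult:
    """Two-sided permutation (randomization) test for global Moran's I.

    Pseudo p = (1 + #{|I_perm - E[I]| >= |I_obs - E[I]|}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise MoranError("use at least 99 permutations")
    x = _check_inputs(x, w)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    res = global_moran(x, w)
    W, n = w.w, len(x)
    z = x - x.mean()
    # all permutations at once: columns of Z are permuted deviation vectors
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    Z = z[idx].T  # (n, n_perm)
    denom = W.sum() * (z @ z)
    I_perm = n * np.einsum("ip,ip->p", Z, W @ Z) / denom
    EI = res.expected_I
    exceed = np.abs(I_perm - EI) >= np.abs(res.I - EI) - 1e-14
    p_perm = (1.0 + exceed.sum()) / (n_perm + 1.0)
    return MoranResult(
        I=res.I,
        expected_I=EI,
        z=res.z,
        p_normal=res.p_normal,
        p_perm=float(p_perm),
        n_perm=n_perm,
    )


def moran_quadrants(x: np.ndarray, w: SpatialWeights) -> tuple[str, ...]:
    """Moran-scatter quadrant per region from mean-deviations of x and Wx.

    HH: above-mean value with above-mean spatial lag; LL: both below;
    HL / LH: the discordant quadrants.  Exact zeros side with 'high'.
    """
    x = _check_inputs(x, w)
    z = x - x.mean()
    lag_dev = w.w @ z  # spatial lag of the mean-deviations
    labels = []
    for zi, li in zip(z, lag_dev):
        labels.append(("H" if zi >= 0 else "L") + ("H" if li >= 0 else "L"))
    return tuple(labels)


def moran_with_locals(
    x: np.ndarray,
    w: SpatialWeights,
    n_perm: int | None = 999,
    seed: int | np.random.Generator = 0,
) -> MoranResult:
    """Convenience: global + permutation + local + quadrants in one result."""
    base = permutation_test(x, w, n_perm=n_perm, seed=seed) if n_perm else global_moran(x, w)
    return MoranResult(
        I=base.I,
        expected_I=base.expected_I,
        z=base.z,
        p_normal=base.p_normal,
        p_perm=base.p_perm,
        n_perm=base.n_perm,
        local_I=local_moran(x, w),
        quadrant=moran_quadrants(x, w),
    )
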