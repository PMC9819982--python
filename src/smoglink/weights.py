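"""Spatial weight matrices: binary contiguity and inverse distance.

The weight matrix W encodes which regions are neighbours.  The main
analysis uses first-order contiguity exactly as the adjacency file encodes
it (w_ij = 1 iff regions i and j share a border); inverse-distance weights
are provided as a robustness variant.  Model estimation always works on the
row-standardized matrix, where each row sums to one so that (WY)_i is the
average of region i's neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np


class WeightsError(ValueError):
    """Invalid spatial-weights construction (unknown id, isolate, ...)."""


@dataclass(frozen=True)
class SpatialWeights:
    """An n-by-n non-negative weight matrix tied to a fixed region order.

    Attributes
    ----------
    w : ndarray, shape (n, n)
        Non-negative weights with a zero diagonal.
    region_ids : tuple of str
        Region order shared with the panel; ``w[i, j]`` links
        ``region_ids[i]`` to ``region_ids[j]``.
    standardized : bool
        True if every row sums to one.
    scheme : str
        ``"contiguity"`` or ``"inverse_distance"``.
    """

    w: np.ndarray
    region_ids: tuple[str, ...]
    standardized: bool = False
    scheme: str = "contiguity"

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "region_ids", tuple(str(r) for r in self.region_ids))
        n = len(self.region_ids)
        if w.shape != (n, n):
            raise WeightsError(f"weight matrix shape {w.shape} != ({n}, {n})")
        if not np.all(np.isfinite(w)):
            raise WeightsError("non-finite weights")
        if (w < 0).any():
            raise WeightsError("negative weights")
        if np.abs(np.diag(w)).max(initial=0.0) > 0:
            raise WeightsError("nonzero diagonal")

    @property
    def n(self) -> int:
        return len(self.region_ids)

    def isolates(self) -> list[str]:
        """Region ids whose row has no positive entry."""
        mask = self.w.sum(axis=1) <= 0
        return [r for r, m in zip(self.region_ids, mask) if m]

    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.w)).max())


def _check_isolates(w: np.ndarray, regions: Sequence[str]) -> None:
    mask = w.sum(axis=1) <= 0
    if mask.all():
        raise WeightsError("isolated units: all")
    if mask.any():
        bad = [r for r, m in zip(regions, mask) if m]
        raise WeightsError(f"isolated units: {', '.join(bad)}")


def build_contiguity(
    adjacency: Iterable[tuple[str, str]], regions: Sequence[str]
) -> SpatialWeights:
    """Binary symmetric contiguity matrix from a list of neighbour pairs.

    Every pair member must be a known region id; self-pairs and pairs
    leaving any region without a neighbour are errors (an island province
    needs an explicit bridge pair — silent patching changes results
    invisibly).
    """
    regions = [str(r) for r in regions]
    index = {r: i for i, r in enumerate(regions)}
    if len(index) != len(regions):
        raise WeightsError("duplicate region ids")
    n = len(regions)
    w = np.zeros((n, n))
    for a, b in adjacency:
        a, b = str(a), str(b)
        if a not in index or b not in index:
            unknown = a if a not in index else b
            raise WeightsError(f"unknown region id: {unknown!r}")
        if a == b:
            raise WeightsError(f"self-pair: {a!r}")
        w[index[a], index[b]] = 1.0
        w[index[b], index[a]] = 1.0
    _check_isolates(w, regions)
    return SpatialWeights(w=w, region_ids=tuple(regions), scheme="contiguity")


def build_inverse_distance(
    distances: Mapping[tuple[str, str], float],
    regions: Sequence[str],
    power: float = 1.0,
    cutoff: float | None = None,
) -> SpatialWeights:
    """w_ij = d_ij^(-power) for d_ij <= cutoff, else 0.

    ``distances`` maps unordered id pairs to km; a pair given in both
    orders must agree.  Zero or negative distances are errors.
    """
    regions = [str(r) for r in regions]
    index = {r: i for i, r in enumerate(regions)}
    n = len(regions)
    d = np.full((n, n), np.nan)
    np.fill_diagonal(d, 0.0)
    for (a, b), km in distances.items():
        a, b = str(a), str(b)
        if a not in index or b not in index:
            unknown = a if a not in index else b
            raise WeightsError(f"unknown region id: {unknown!r}")
        if a == b:
            raise WeightsError(f"self-distance for {a!r}")
        km = float(km)
        if km <= 0:
            raise WeightsError(f"non-positive distance for ({a!r}, {b!r}): {km}")
        i, j = index[a], index[b]
        for x, y in ((i, j), (j, i)):
            if not np.isnan(d[x, y]) and not np.isclose(d[x, y], km):
                raise WeightsError(f"asymmetric distances for ({a!r}, {b!r})")
            d[x, y] = km
    off = ~np.eye(n, dtype=bool)
    if np.isnan(d[off]).any():
        raise WeightsError("distance table incomplete")
    w = np.zeros((n, n))
    keep = off & ((d <= cutoff) if cutoff is not None else np.full_like(off, True))
    w[keep] = d[keep] ** (-power)
    _check_isolates(w, regions)
    return SpatialWeights(w=w, region_ids=tuple(regions), scheme="inverse_distance")


def row_standardize(weights: SpatialWeights) -> SpatialWeights:
    """Scale each row to sum to one.  Idempotent; zero rows are an error."""
    sums = weights.w.sum(axis=1)
    if (sums <= 0).any():
        _check_isolates(weights.w, weights.region_ids)
    return replace(weights, w=weights.w / sums[:, None], standardized=True)
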