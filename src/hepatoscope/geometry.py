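"""Sensor geometry: electrode layout, pair enumeration, liver weighting.

A six-electrode patch measured pairwise yields ``6*5/2 = 15`` electrode
pairs.  Each pair's current path is split between the liver region and
the surrounding (background) tissue; the liver fraction declines with
inter-electrode distance rank, reflecting that widely spaced pairs sample
proportionally more of the surrounding torso in this lumped-path world.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = ["SensorGeometry", "electrode_pairs", "default_geometry"]

# electrode centres of the 2 x 3 patch, arbitrary patch units
_DEFAULT_POSITIONS = np.array(
    [[0.0, 0.0], [0.0, 1.0], [0.0, 2.0], [1.0, 0.0], [1.0, 1.0], [1.0, 2.0]]
)


def electrode_pairs(n_electrodes: int) -> list[tuple[int, int]]:
    """All unordered electrode pairs, lexicographic over 0-based indices."""
    if n_electrodes < 2:
        raise ValueError("need at least 2 electrodes")
    return [(i, j) for i in range(n_electrodes) for j in range(i + 1, n_electrodes)]


@dataclass(frozen=True)
class SensorGeometry:
    """Electrode count, pair ordering and per-pair liver path fractions."""

    n_electrodes: int
    pairs: tuple[tuple[int, int], ...]
    liver_weight: np.ndarray

    def __post_init__(self) -> None:
        expected = self.n_electrodes * (self.n_electrodes - 1) // 2
        if len(self.pairs) != expected:
            raise ValueError(f"expected {expected} pairs for {self.n_electrodes} electrodes, got {len(self.pairs)}")
        if len(set(map(tuple, map(sorted, self.pairs)))) != len(self.pairs):
            raise ValueError("duplicate electrode pairs")
        w = np.asarray(self.liver_weight, dtype=float)
        if w.shape != (len(self.pairs),):
            raise ValueError("liver_weight length must equal the number of pairs")
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("liver_weight entries must lie in [0, 1]")
        object.__setattr__(self, "liver_weight", w)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def default_geometry(
    n_electrodes: int = 6,
    *,
    w_near: float = 0.5,
    w_far: float = 0.2,
) -> SensorGeometry:
    """Six-electrode 2 x 3 patch with distance-ranked liver weights.

    Pairs are ordered lexicographically.  Liver weights interpolate
    linearly from ``w_near`` (closest pair) down to ``w_far`` (farthest),
    using average ranks of the Euclidean inter-electrode distances so
    that equidistant pairs share a weight.
    """
    pairs = electrode_pairs(n_electrodes)
    if n_electrodes == _DEFAULT_POSITIONS.shape[0]:
        pos = _DEFAULT_POSITIONS
    else:  # generic fallback: electrodes on a line
        pos = np.stack([np.zeros(n_electrodes), np.arange(n_electrodes, dtype=float)], axis=1)
    dist = np.array([np.linalg.norm(pos[i] - pos[j]) for i, j in pairs])
    rank = rankdata(dist, method="average") - 1.0  # 0 .. n_pairs-1 (ties averaged)
    t = rank / max(len(pairs) - 1, 1)
    weights = w_near + (w_far - w_near) * t
    return SensorGeometry(n_electrodes=n_electrodes, pairs=tuple(pairs), liver_weight=weights)
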