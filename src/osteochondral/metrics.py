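"""Scalar descriptors of the bone-cartilage interface.

Two numbers summarize the interface: the Shannon entropy of the local-angle
distribution (high when the interface orientation is disordered, i.e.
fibrillated) and the homogeneity of an angle-level co-occurrence matrix
(ALCM; high when consecutive interface pixels share similar orientations,
low when sharp angle changes follow one another).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import HistoImage
from .lbp import AngleField, AngleHistogram, angle_field, angle_histogram

__all__ = [
    "InterfaceDescriptors",
    "entropy",
    "alcm",
    "homogeneity",
    "describe_interface",
]

# Offsets covering each 8-adjacency once; recording every pair in both
# orders supplies the symmetric counterparts.
_PAIR_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass
class InterfaceDescriptors:
    """The two interface descriptors plus the counts behind them."""

    entropy: float
    homogeneity: float
    n_defined_pixels: int
    n_pairs: int
    n_bins: int
    n_undefined_pixels: int = 0
    n_border_dropped: int = 0


def entropy(hist: AngleHistogram, base: float = 2.0) -> float:
    """Shannon entropy of the angle distribution, in bits by default.

    ``H = -sum p_i log(p_i)`` with the convention ``0 log 0 = 0``; ranges
    from 0 (all angles in one bin) to ``log(B)`` (uniform over B bins).
    """
    p = np.asarray(hist.probs, dtype=float)
    nz = p[p > 0]
    return float(-(nz * (np.log(nz) / np.log(base))).sum())


def _adjacent_values(arr: np.ndarray, dr: int, dc: int) -> tuple[np.ndarray, np.ndarray]:
    """Aligned views (a, b) such that b sits at offset (dr, dc) from a."""
    h, w = arr.shape
    r0, r1 = max(0, -dr), h - max(0, dr)
    c0, c1 = max(0, -dc), w - max(0, dc)
    a = arr[r0:r1, c0:c1]
    b = arr[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    return a, b


def alcm(field: AngleField, mask: np.ndarray, n_bins: int = 8) -> np.ndarray:
    """Angle-level co-occurrence matrix over adjacent interface pixels.

    Every unordered 8-adjacent pair of defined-angle pixels inside ``mask``
    increments both (bin_a, bin_b) and (bin_b, bin_a); the matrix is then
    normalized to sum to 1. Pooling all eight adjacency directions into one
    matrix makes the statistic invariant to rotating the section.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != field.angles.shape:
        raise ValueError("mask and angle field shapes differ")
    ok = field.defined & mask
    bins = np.full(mask.shape, -1, dtype=int)
    bins[ok] = np.minimum(
        (field.angles[ok] / (180.0 / n_bins)).astype(int), n_bins - 1
    )

    m = np.zeros((n_bins, n_bins))
    for dr, dc in _PAIR_OFFSETS:
        a, b = _adjacent_values(bins, dr, dc)
        valid = (a >= 0) & (b >= 0)
        np.add.at(m, (a[valid], b[valid]), 1.0)
        np.add.at(m, (b[valid], a[valid]), 1.0)
    total = m.sum()
    if total == 0:
        raise ValueError("no adjacent pairs of defined-angle pixels in the mask")
    return m / total


def count_pairs(field: AngleField, mask: np.ndarray) -> int:
    """Number of unordered adjacent defined-angle pairs (the ALCM support)."""
    ok = field.defined & np.asarray(mask, dtype=bool)
    n = 0
    for dr, dc in _PAIR_OFFSETS:
        a, b = _adjacent_values(ok, dr, dc)
        n += int((a & b).sum())
    return n


def homogeneity(matrix: np.ndarray, circular: bool = True) -> float:
    """Co-occurrence homogeneity ``sum P(i, j) / (1 + |i - j|)``.

    Equals 1 iff all co-occurring pairs fall in the same angle bin. Axial
    angles are periodic, so by default the bin distance wraps around the
    180-degree axis, ``d = min(|i - j|, B - |i - j|)``: an interface a few
    degrees either side of horizontal stays homogeneous. ``circular=False``
    gives the plain linear distance ``|i - j|``.
    """
    p = np.asarray(matrix, dtype=float)
    b = p.shape[0]
    i, j = np.indices(p.shape)
    d = np.abs(i - j)
    if circular:
        d = np.minimum(d, b - d)
    return float((p / (1.0 + d)).sum())


def describe_interface(
    image: HistoImage,
    mask: np.ndarray,
    n_bins: int = 8,
    entropy_base: float = 2.0,
    circular: bool = True,
) -> InterfaceDescriptors:
    """Entropy and homogeneity of one interface mask, with counts."""
    field = angle_field(image, mask)
    hist = angle_histogram(field, n_bins=n_bins)
    matrix = alcm(field, mask, n_bins=n_bins)
    return InterfaceDescriptors(
        entropy=entropy(hist, base=entropy_base),
        homogeneity=homogeneity(matrix, circular=circular),
        n_defined_pixels=hist.n_defined,
        n_pairs=count_pairs(field, mask),
        n_bins=n_bins,
        n_undefined_pixels=field.n_undefined,
        n_border_dropped=field.n_border_dropped,
    )
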