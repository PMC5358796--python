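"""Local binary patterns and per-pixel interface orientations.

For every interface pixel the eight radius-1 neighbours are thresholded at
the centre intensity (ties count as set, so the operator is invariant to
adding a constant to the whole image). The resulting 8-bit pattern encodes
where the locally bright side lies, and is turned into an axial
orientation — an angle modulo 180 degrees — by one of two rules:

* Edge patterns, whose set flags form one contiguous arc around the
  compass (the "uniform" patterns of the LBP literature: at most two
  0/1 transitions around the ring), are pixels with a bright side. The
  plain vector mean of the set flags points at that side, and the local
  structure runs perpendicular to it: a pixel whose brighter neighbours
  are SW, S and SE lies on a horizontal interface, angle 0.
* All other patterns have bright flags on more than one side (ridges and
  saddles, e.g. E and W set); their plain mean cancels, so the flags are
  averaged as axial directions with the classic angle-doubling trick —
  each set flag at compass angle theta contributes (cos 2*theta,
  sin 2*theta) and the angle is half the resultant direction, which maps
  E+W to the horizontal axis instead of cancelling.

A pattern is undefined when it carries no orientation at all: no flag or
every flag set, or a balanced multi-sided pattern whose doubled and plain
resultants both vanish (e.g. all four cardinal flags).

Compass convention: angles are measured in image coordinates with rows
increasing downward, so N means "one row up" on screen. Flag order is fixed
as E, NE, N, NW, W, SW, S, SE at angles 0, 45, ..., 315 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import HistoImage

__all__ = [
    "NEIGHBOR_ORDER",
    "NEIGHBOR_ANGLES_DEG",
    "LocalPattern",
    "AngleField",
    "AngleHistogram",
    "local_pattern",
    "pattern_to_angle",
    "angle_field",
    "angle_histogram",
    "pattern_angle_table",
]

NEIGHBOR_ORDER = ("E", "NE", "N", "NW", "W", "SW", "S", "SE")
NEIGHBOR_ANGLES_DEG = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)
#: (row, col) offset of each neighbour; rows increase downward, so N is -1 row.
NEIGHBOR_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1))

#: Resultants shorter than this (in doubled-vector units) are undefined.
RESULTANT_EPS = 1e-9


@dataclass(frozen=True)
class LocalPattern:
    """The 8 neighbour flags of one pixel, in :data:`NEIGHBOR_ORDER`."""

    flags: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.flags) != 8:
            raise ValueError("LocalPattern requires exactly 8 flags")

    @property
    def code(self) -> int:
        """The pattern as an integer, bit k = flag k (E = bit 0)."""
        return sum(1 << k for k, f in enumerate(self.flags) if f)


@dataclass
class AngleField:
    """Per-pixel axial angles on an interface mask.

    ``angles`` is a full-raster float array holding the angle in degrees in
    [0, 180) where defined and NaN elsewhere; ``defined`` marks the pixels
    with a defined angle. Mask pixels on the raster border cannot be
    evaluated and are dropped (counted in ``n_border_dropped``); mask pixels
    whose pattern carries no orientation (all flags equal, or a vanishing
    resultant) are retained but undefined (``n_undefined``).
    """

    angles: np.ndarray
    defined: np.ndarray
    n_border_dropped: int
    n_undefined: int

    @property
    def defined_angles(self) -> np.ndarray:
        return self.angles[self.defined]


@dataclass
class AngleHistogram:
    """Binned axial-angle distribution over [0, 180)."""

    probs: np.ndarray
    n_bins: int
    n_defined: int
    n_undefined: int

    @property
    def bin_width(self) -> float:
        return 180.0 / self.n_bins


def local_pattern(image: HistoImage, row: int, col: int) -> LocalPattern:
    """The LBP flags of one interior pixel (neighbour >= centre)."""
    h, w = image.shape
    if not (0 < row < h - 1 and 0 < col < w - 1):
        raise ValueError(
            f"pixel ({row}, {col}) is on the raster border; all 8 neighbours "
            "must exist"
        )
    centre = image.data[row, col]
    flags = tuple(
        bool(image.data[row + dr, col + dc] >= centre) for dr, dc in NEIGHBOR_OFFSETS
    )
    return LocalPattern(flags)


def is_edge_pattern(flags: tuple[bool, ...]) -> bool:
    """True when the set flags form one contiguous compass arc (1-7 flags)."""
    n_set = sum(flags)
    if n_set in (0, 8):
        return False
    transitions = sum(flags[k] != flags[(k + 1) % 8] for k in range(8))
    return transitions == 2


def pattern_to_angle(pattern: LocalPattern) -> float:
    """Axial orientation of the set flags in degrees, or NaN when undefined.

    Edge (contiguous-arc) patterns read as the axis perpendicular to the
    plain flag-mean; multi-sided patterns read as half the direction of
    the doubled-angle resultant, with the perpendicular rule as fallback
    when doubling cancels. Undefined when no flag or every flag is set, or
    when both resultants vanish.
    """
    flags = pattern.flags
    n_set = sum(flags)
    if n_set in (0, 8):
        return float("nan")
    v2x = v2y = v1x = v1y = 0.0
    for k, f in enumerate(flags):
        if f:
            theta = np.deg2rad(NEIGHBOR_ANGLES_DEG[k])
            v2x += np.cos(2.0 * theta)
            v2y += np.sin(2.0 * theta)
            v1x += np.cos(theta)
            v1y += np.sin(theta)
    plain_ok = np.hypot(v1x, v1y) >= RESULTANT_EPS
    doubled_ok = np.hypot(v2x, v2y) >= RESULTANT_EPS
    if is_edge_pattern(flags) and plain_ok:
        angle = (np.degrees(np.arctan2(v1y, v1x)) + 90.0) % 180.0
    elif doubled_ok:
        angle = np.degrees(np.arctan2(v2y, v2x)) / 2.0 % 180.0
    elif plain_ok:
        angle = (np.degrees(np.arctan2(v1y, v1x)) + 90.0) % 180.0
    else:
        return float("nan")
    # Round-off at the axial seam: a hair below 180 is the 0-degree axis.
    if angle >= 180.0 - 1e-9:
        angle = 0.0
    return float(angle)


def pattern_angle_table() -> np.ndarray:
    """Angle (or NaN) for each of the 256 patterns, indexed by pattern code.

    Shipped so the pattern-to-angle mapping is auditable in full.
    """
    table = np.empty(256)
    for code in range(256):
        flags = tuple(bool(code >> k & 1) for k in range(8))
        table[code] = pattern_to_angle(LocalPattern(flags))
    return table


def angle_field(image: HistoImage, mask: np.ndarray) -> AngleField:
    """Axial angle of every interface pixel, vectorised over the raster."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask and image shapes differ")
    if not mask.any():
        raise ValueError("interface mask is empty")

    interior = np.zeros_like(mask)
    interior[1:-1, 1:-1] = mask[1:-1, 1:-1]
    n_border_dropped = int(mask.sum() - interior.sum())

    data = image.data
    # Doubled-angle unit vectors per neighbour: E/W -> +x, NE/SW -> +y,
    # N/S -> -x, NW/SE -> -y.
    theta = np.deg2rad(np.asarray(NEIGHBOR_ANGLES_DEG))
    cos2, sin2 = np.cos(2.0 * theta), np.sin(2.0 * theta)
    cos1, sin1 = np.cos(theta), np.sin(theta)
    flag_planes = []
    for dr, dc in NEIGHBOR_OFFSETS:
        nb = np.full_like(data, np.nan)
        rs = slice(max(dr, 0), data.shape[0] + min(dr, 0))
        cs = slice(max(dc, 0), data.shape[1] + min(dc, 0))
        rs_src = slice(max(-dr, 0), data.shape[0] + min(-dr, 0))
        cs_src = slice(max(-dc, 0), data.shape[1] + min(-dc, 0))
        nb[rs, cs] = data[rs_src, cs_src]
        flag_planes.append(nb >= data)
    v2x = sum(np.where(f, cos2[k], 0.0) for k, f in enumerate(flag_planes))
    v2y = sum(np.where(f, sin2[k], 0.0) for k, f in enumerate(flag_planes))
    v1x = sum(np.where(f, cos1[k], 0.0) for k, f in enumerate(flag_planes))
    v1y = sum(np.where(f, sin1[k], 0.0) for k, f in enumerate(flag_planes))
    n_set = sum(f.astype(np.int8) for f in flag_planes)
    transitions = sum(
        (flag_planes[k] != flag_planes[(k + 1) % 8]).astype(np.int8)
        for k in range(8)
    )

    doubled_ok = np.hypot(v2x, v2y) >= RESULTANT_EPS
    plain_ok = np.hypot(v1x, v1y) >= RESULTANT_EPS
    informative = interior & (n_set > 0) & (n_set < 8)
    edge = informative & (transitions == 2) & plain_ok
    defined = informative & (doubled_ok | plain_ok)
    angles = np.full(data.shape, np.nan)
    perp = edge | (defined & ~doubled_ok)
    doubled = defined & doubled_ok & ~edge
    angles[perp] = (np.degrees(np.arctan2(v1y[perp], v1x[perp])) + 90.0) % 180.0
    angles[doubled] = (
        np.degrees(np.arctan2(v2y[doubled], v2x[doubled])) / 2.0 % 180.0
    )
    angles[defined & (angles >= 180.0 - 1e-9)] = 0.0  # axial seam round-off
    n_undefined = int(interior.sum() - defined.sum())
    return AngleField(
        angles=angles,
        defined=defined,
        n_border_dropped=n_border_dropped,
        n_undefined=n_undefined,
    )


def angle_histogram(field: AngleField, n_bins: int = 8) -> AngleHistogram:
    """Bin the defined angles into ``n_bins`` uniform bins over [0, 180)."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    values = field.defined_angles
    if values.size == 0:
        raise ValueError(
            f"no defined angles to bin ({field.n_undefined} undefined pixels)"
        )
    counts, _ = np.histogram(values, bins=n_bins, range=(0.0, 180.0))
    return AngleHistogram(
        probs=counts / counts.sum(),
        n_bins=n_bins,
        n_defined=int(values.size),
        n_undefined=field.n_undefined,
    )
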