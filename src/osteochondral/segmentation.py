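"""Bone-cartilage interface (BCI) segmentation.

The analysis starts from a thick band mask drawn around the BCI (manually in
a real study, from the ground-truth layer map for phantoms). Within the
band, pixels are classified as bone or cartilage, and the classification is
thinned to the interface itself: the pixels whose 8-neighbourhood contains
the opposite class. On smooth boundaries this yields the two one-pixel
boundary layers plus corner-touching pixels, i.e. a layer roughly three
pixels thick.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.filters import threshold_otsu

from .containers import (
    CALCIFIED_CARTILAGE,
    SUBCHONDRAL_PLATE,
    HistoImage,
    LayerMap,
)

__all__ = [
    "BandMask",
    "classify_band",
    "extract_interface",
    "band_from_layermap",
    "EmptyInterfaceWarning",
]

# The eight chess-king neighbour offsets (row, col).
NEIGHBOR_OFFSETS = (
    (0, 1),
    (-1, 1),
    (-1, 0),
    (-1, -1),
    (0, -1),
    (1, -1),
    (1, 0),
    (1, 1),
)


class EmptyInterfaceWarning(UserWarning):
    """The band contained only one tissue class; the interface mask is empty."""


@dataclass
class BandMask:
    """Thick boolean band containing the BCI near its middle."""

    mask: np.ndarray
    nominal_thickness_px: int = 7

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("BandMask must be a 2D boolean raster")
        if self.nominal_thickness_px < 1:
            raise ValueError("nominal_thickness_px must be >= 1")


def classify_band(
    image: HistoImage,
    band: BandMask,
    method: str = "otsu",
    threshold: float | None = None,
) -> np.ndarray:
    """Label every band pixel as cartilage (False) or bone (True).

    With ``method="otsu"`` the threshold is computed from the band-pixel
    intensities only, so the global image content cannot bias it; with
    ``method="fixed"`` the caller supplies ``threshold``. Bone is the
    brighter phase of the analyzed channel (invert the image upstream if the
    stain runs the other way). Pixels outside the band are False and carry
    no meaning.
    """
    mask = band.mask
    if mask.shape != image.shape:
        raise ValueError("band and image shapes differ")
    if mask.sum() < 9:
        raise ValueError("band must contain at least 9 pixels")
    values = image.data[mask]
    if method == "otsu":
        if np.ptp(values) == 0:
            raise ValueError(
                "band intensities are constant; Otsu cannot separate classes"
            )
        thresh = threshold_otsu(values)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        thresh = threshold
    else:
        raise ValueError(f"unknown method {method!r}")
    labels = np.zeros(image.shape, dtype=bool)
    labels[mask] = image.data[mask] >= thresh
    return labels


def _shift(a: np.ndarray, dr: int, dc: int, fill=False) -> np.ndarray:
    """Return ``a`` shifted by (dr, dc) with constant fill, same shape."""
    out = np.full_like(a, fill)
    rs = slice(max(dr, 0), a.shape[0] + min(dr, 0))
    cs = slice(max(dc, 0), a.shape[1] + min(dc, 0))
    rs_src = slice(max(-dr, 0), a.shape[0] + min(-dr, 0))
    cs_src = slice(max(-dc, 0), a.shape[1] + min(-dc, 0))
    out[rs, cs] = a[rs_src, cs_src]
    return out


def extract_interface(labels: np.ndarray, band: BandMask) -> np.ndarray:
    """Thin a band classification to the interface mask.

    A band pixel is kept iff its 8-neighbourhood, restricted to the band,
    contains at least one pixel of the opposite class. A band holding a
    single class yields an empty mask and an :class:`EmptyInterfaceWarning`.
    """
    mask = band.mask
    labels = np.asarray(labels, dtype=bool)
    if labels.shape != mask.shape:
        raise ValueError("labels and band shapes differ")
    keep = np.zeros_like(mask)
    for dr, dc in NEIGHBOR_OFFSETS:
        nb_in_band = _shift(mask, dr, dc)
        nb_labels = _shift(labels, dr, dc)
        keep |= mask & nb_in_band & (nb_labels != labels)
    if mask.any() and not keep.any():
        warnings.warn(
            "band contains a single tissue class; interface mask is empty",
            EmptyInterfaceWarning,
            stacklevel=2,
        )
    return keep


def band_from_layermap(layers: LayerMap, half_width_px: int = 3) -> BandMask:
    """Synthetic stand-in for the manual band: dilate the true BCI.

    The boundary is taken as the subchondral-plate pixels with calcified
    cartilage directly above them (the top plate pixel of each column).
    Plate pixels that merely touch cartilage sideways — the walls of open
    fenestrae — are not BCI and are left out, the way a manual tracing
    follows the interface and stops at gaps. The band is every pixel
    within Chebyshev distance ``half_width_px`` of that boundary, giving a
    band ``2*half_width_px + 1`` pixels thick on a flat interface (7 px at
    the default) with the BCI in its middle.
    """
    if half_width_px < 0:
        raise ValueError("half_width_px must be >= 0")
    lab = layers.labels
    calc = lab == CALCIFIED_CARTILAGE
    plate = lab == SUBCHONDRAL_PLATE
    for name, present in (("calcified_cartilage", calc), ("subchondral_plate", plate)):
        if not present.any():
            raise ValueError(f"LayerMap contains no {name} pixels; no BCI to band")
    boundary = plate & _shift(calc, 1, 0)  # calc sits one row above
    if not boundary.any():
        raise ValueError(
            "calcified_cartilage and subchondral_plate are never adjacent; "
            "no BCI boundary found"
        )
    if half_width_px == 0:
        band = boundary
    else:
        size = 2 * half_width_px + 1
        band = binary_dilation(boundary, structure=np.ones((size, size), dtype=bool))
        # Columns with no BCI (open fenestrae, eroded patches) carry no
        # band, and neither does a half-width margin next to them: tracing
        # stops short of a gap rather than wrapping around its corner.
        good = boundary.any(axis=0)
        bad = binary_dilation(
            ~good, structure=np.ones(2 * half_width_px + 1, dtype=bool)
        )
        band &= ~bad[None, :]
    return BandMask(band, nominal_thickness_px=2 * half_width_px + 1)
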