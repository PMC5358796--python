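"""Core raster containers shared by every pipeline stage.

The package works on plain 2D numpy rasters with a physical pixel size
attached. Coordinates are row-major with the origin at the top-left and row
indices increasing downward, so in an osteochondral section the articular
cartilage sits above the bone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Layer label codes used throughout the package.
BACKGROUND = 0
UNCALCIFIED_CARTILAGE = 1
CALCIFIED_CARTILAGE = 2
SUBCHONDRAL_PLATE = 3
TRABECULAR_BONE = 4
MARROW = 5

LABEL_NAMES = {
    BACKGROUND: "background",
    UNCALCIFIED_CARTILAGE: "uncalcified_cartilage",
    CALCIFIED_CARTILAGE: "calcified_cartilage",
    SUBCHONDRAL_PLATE: "subchondral_plate",
    TRABECULAR_BONE: "trabecular_bone",
    MARROW: "marrow",
}
NAME_TO_LABEL = {v: k for k, v in LABEL_NAMES.items()}

#: Labels counted as "bone" when the section is dichotomized at the
#: bone-cartilage interface (BCI).
BONE_LABELS = frozenset({SUBCHONDRAL_PLATE, TRABECULAR_BONE})
CARTILAGE_LABELS = frozenset({UNCALCIFIED_CARTILAGE, CALCIFIED_CARTILAGE})


@dataclass
class HistoImage:
    """A single-channel histology raster with physical pixel size.

    Parameters
    ----------
    data:
        2D float array of intensities; finite and non-negative.
    pixel_size:
        Physical size of one pixel in micrometres.
    channel:
        Tag describing which stain channel the raster holds (e.g. ``"red"``
        for the Safranin-O red channel, ``"gray"`` for grayscale input).
    """

    data: np.ndarray
    pixel_size: float
    channel: str = "gray"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or min(self.data.shape) < 3:
            raise ValueError("HistoImage must be a 2D raster of at least 3x3 pixels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("HistoImage intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("HistoImage intensities must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (micrometres per pixel)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class LayerMap:
    """Categorical per-pixel tissue labels for a synthetic section.

    Every pixel carries exactly one label from :data:`LABEL_NAMES`. In any
    column the labels appear, top to bottom, in the anatomical order
    background, uncalcified cartilage, calcified cartilage, subchondral
    plate, then trabecular bone or marrow (individual layers may be empty).
    """

    labels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise ValueError("LayerMap must be a 2D raster")
        unknown = set(np.unique(self.labels)) - set(LABEL_NAMES)
        if unknown:
            raise ValueError(f"unknown layer labels: {sorted(unknown)}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label
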