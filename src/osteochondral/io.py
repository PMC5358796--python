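"""File formats: images, masks, layer maps, study tables and reports.

Images travel as 8-bit PNG or 16-bit grayscale TIFF; masks as single
channel PNG (0 = outside, 255 = inside); layer maps as indexed PNG with a
JSON sidecar legend; study tables as comma-separated UTF-8 CSV with a
header row and ``NA`` for missing descriptor cells; reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .containers import LABEL_NAMES, HistoImage, LayerMap

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_layermap",
    "write_layermap",
    "read_table",
    "write_table",
    "write_report",
    "read_report",
]

_CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}


def read_image(path: str | Path, pixel_size: float, channel: str = "red") -> HistoImage:
    """Read a PNG/TIFF section image, reducing RGB to the stain channel.

    ``channel`` selects the analyzed stain channel of RGB input (the red
    channel for Safranin-O by default); single-channel input is used as is
    and tagged ``gray``.
    """
    path = Path(path)
    arr = (
        tifffile.imread(path)
        if path.suffix.lower() in (".tif", ".tiff")
        else iio.imread(path)
    )
    if arr.ndim == 3:
        if channel not in _CHANNEL_INDEX:
            raise ValueError(f"unknown channel {channel!r}")
        arr = arr[..., _CHANNEL_INDEX[channel]]
        tag = channel
    elif arr.ndim == 2:
        tag = "gray"
    else:
        raise ValueError(f"{path}: expected a 2D or RGB image, got shape {arr.shape}")
    return HistoImage(arr.astype(float), pixel_size=pixel_size, channel=tag)


def write_image(image: HistoImage, path: str | Path) -> None:
    """Write an image as 8-bit PNG or 16-bit grayscale TIFF by extension."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.round(image.data).astype(np.uint16))
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, np.round(np.clip(image.data, 0, 255)).astype(np.uint8))
    else:
        raise ValueError(f"unsupported image extension {path.suffix!r}")


def read_mask(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: mask must be single-channel")
    return arr > 0


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    mask = np.asarray(mask, dtype=bool)
    iio.imwrite(Path(path), (mask * np.uint8(255)))


def write_layermap(layers: LayerMap, path: str | Path) -> None:
    """Indexed PNG of label codes plus a ``.json`` sidecar legend."""
    path = Path(path)
    iio.imwrite(path, layers.labels)
    legend = {
        "pixel_size_um": layers.pixel_size,
        "labels": {str(k): v for k, v in LABEL_NAMES.items()},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(legend, indent=2))


def read_layermap(path: str | Path) -> LayerMap:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"layer map legend {sidecar} not found")
    legend = json.loads(sidecar.read_text())
    labels = iio.imread(path)
    return LayerMap(labels, pixel_size=float(legend["pixel_size_um"]))


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Study-table CSV: comma separated, dot decimals, ``NA`` for missing."""
    table.to_csv(Path(path), index=False, na_rep="NA")


def read_table(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(Path(path), na_values=["NA"], keep_default_na=True)
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed study table {path}: {err}") from err


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
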