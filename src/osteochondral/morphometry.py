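"""Layer-thickness morphometry.

Thickness of the uncalcified cartilage, calcified cartilage and subchondral
plate is measured as the vertical chord at five randomly selected but
evenly distributed points of the field of view: one uniform random column
per fifth of the image width. Group summaries and fold changes relate the
measurements to the subchondral bone grade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import NAME_TO_LABEL, LayerMap

__all__ = [
    "ThicknessMeasurement",
    "FoldChange",
    "sample_points",
    "layer_thickness",
    "summarize_by_grade",
    "fold_change",
]


@dataclass
class ThicknessMeasurement:
    """Per-point thicknesses of one layer in one section (micrometres).

    ``zero_columns`` lists the sampled columns where the layer was absent
    (e.g. a column running through an open fenestra of the plate); they
    contribute 0 um rather than being resampled, so callers can decide
    whether to exclude them.
    """

    layer: str
    columns: list[int]
    points_um: list[float]
    zero_columns: list[int] = field(default_factory=list)
    sample_id: str | None = None

    @property
    def mean_um(self) -> float:
        return float(np.mean(self.points_um))


@dataclass(frozen=True)
class FoldChange:
    """Thickness ratio relative to a reference grade."""

    ratio: float
    rounded: int


def sample_points(width_px: int, k: int = 5, seed: int = 0) -> list[int]:
    """``k`` random columns, one per equal-width strip of the view.

    Random *and* evenly distributed: strip ``i`` spans columns
    ``[round(i*w/k), round((i+1)*w/k))`` and contributes one uniform random
    column. Deterministic for a fixed seed.
    """
    if width_px < k:
        raise ValueError(f"width {width_px} px cannot host {k} separate points")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    edges = [round(i * width_px / k) for i in range(k + 1)]
    return [int(rng.integers(edges[i], edges[i + 1])) for i in range(k)]


def layer_thickness(
    layers: LayerMap,
    columns: list[int],
    layer: str,
    sample_id: str | None = None,
) -> ThicknessMeasurement:
    """Vertical chord length of one layer at the given columns.

    The chord is the count of pixels carrying the layer's label in the
    column times the pixel size. Columns without the label yield 0 um and
    are flagged in ``zero_columns``.
    """
    if layer not in NAME_TO_LABEL:
        raise ValueError(
            f"unknown layer {layer!r}; expected one of {sorted(NAME_TO_LABEL)}"
        )
    code = NAME_TO_LABEL[layer]
    h, w = layers.shape
    points = []
    zero_columns = []
    for c in columns:
        if not 0 <= c < w:
            raise ValueError(f"column {c} outside raster of width {w}")
        run = int((layers.labels[:, c] == code).sum())
        if run == 0:
            zero_columns.append(int(c))
        points.append(run * layers.pixel_size)
    return ThicknessMeasurement(
        layer=layer,
        columns=[int(c) for c in columns],
        points_um=points,
        zero_columns=zero_columns,
        sample_id=sample_id,
    )


def summarize_by_grade(
    table: pd.DataFrame,
    measure: str,
    grade_column: str = "bone_grade",
) -> pd.DataFrame:
    """Per-grade n, mean, SD and SE of one measurement column.

    SE = SD / sqrt(n). Groups with a single observation report NaN for SD
    and SE; grades absent from the table are simply not listed.
    """
    for col in (measure, grade_column):
        if col not in table.columns:
            raise ValueError(f"table has no column {col!r}")
    grouped = table.dropna(subset=[measure]).groupby(grade_column)[measure]
    out = grouped.agg(n="count", mean="mean", sd="std")
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out.index.name = grade_column
    return out


def fold_change(reference_mean: float, grade_mean: float) -> FoldChange:
    """Thickness ratio ``grade_mean / reference_mean`` and its integer fold."""
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    ratio = grade_mean / reference_mean
    return FoldChange(ratio=float(ratio), rounded=int(round(ratio)))
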