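"""Segmentation and measurement of organ-culture immunofluorescence images.

An :class:`OrganImage` holds three co-registered channels — cytokeratin
(tumor keratinocytes), PDPN (podoplanin) and DAPI (nuclei) — with a pixel
size in µm.  The image is oriented air-side up: row 0 is the top of the
section, the epithelial sheet occupies the top rows, and invasion proceeds
downward (increasing row index).

The pipeline is: threshold the cytokeratin channel (Otsu or fixed), split
the mask into the epithelial sheet (the largest component touching the top
border) and detached islands, count DAPI nuclei per island (Otsu within the
island, small components discarded), and measure per-island area, invasion
depth below the sheet base, and distance to the sheet.  Depth is referenced
to the median per-column lowest sheet row, which is robust to finger-like
protrusions of the front.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "MIN_ISLAND_AREA",
    "MIN_NUCLEUS_AREA",
    "OrganImage",
    "CellShape",
    "segment_keratinocytes",
    "sheet_base_row",
    "extract_islands",
    "count_nuclei",
    "invasion_depth",
    "measure_lwr",
    "mean_marker_intensity",
    "quantify_image",
]

#: Components smaller than this (px²) are noise, not islands.
MIN_ISLAND_AREA = 25
#: DAPI components smaller than this (px²) are not counted as nuclei.
MIN_NUCLEUS_AREA = 9

CHANNELS = ("cytokeratin", "pdpn", "dapi")


@dataclass
class OrganImage:
    """Calibrated multi-channel raster; intensities in [0, 1]."""

    channels: dict[str, np.ndarray]
    um_per_px: float = 1.0

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        shapes = {name: ch.shape for name, ch in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not present; have {sorted(self.channels)}"
            ) from None


@dataclass
class CellShape:
    cell_id: int
    major_axis_px: float
    minor_axis_px: float
    lwr: float = field(init=False)

    def __post_init__(self) -> None:
        self.lwr = self.major_axis_px / self.minor_axis_px


def segment_keratinocytes(
    image: OrganImage, channel: str = "cytokeratin", method: str = "otsu"
) -> tuple[np.ndarray, float]:
    """Threshold a channel into a binary mask; returns ``(mask, threshold)``.

    ``method`` is ``"otsu"`` or ``"fixed:<t>"`` with t in [0, 1].  The mask is
    true where intensity >= threshold.  A constant channel cannot be Otsu
    thresholded and raises with a suggestion to use a fixed threshold.
    """
    ch = image.channel(channel)
    if method == "otsu":
        if np.ptp(ch) == 0:
            raise ValueError(
                f"channel {channel!r} is constant; Otsu thresholding is "
                "undefined — use method='fixed:<t>'"
            )
        t = float(threshold_otsu(ch))
    elif method.startswith("fixed:"):
        t = float(method.split(":", 1)[1])
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"fixed threshold must be in [0, 1], got {t}")
    else:
        raise ValueError(f"unknown method {method!r}; use 'otsu' or 'fixed:<t>'")
    return ch >= t, t


def sheet_base_row(sheet_mask: np.ndarray) -> int:
    """Median over columns of the sheet's lowest occupied row."""
    occupied = sheet_mask.any(axis=0)
    if not occupied.any():
        raise ValueError("empty sheet mask")
    lowest = (sheet_mask.shape[0] - 1) - np.argmax(sheet_mask[::-1], axis=0)
    return int(np.median(lowest[occupied]))


def extract_islands(
    mask: np.ndarray,
    um_per_px: float | None = 1.0,
    min_island_area: int = MIN_ISLAND_AREA,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Split a keratinocyte mask into the sheet and detached islands.

    The sheet is the largest 8-connected component touching the top image
    border; every other component with area >= ``min_island_area`` is an
    island.  Returns ``(island_table, labels, sheet_mask)`` where the table
    has one ``is_sheet`` row plus one row per island with geometry columns
    (nuclei counts unfilled, -1).  Distances to the sheet are Euclidean
    nearest-pixel distances.  Pass ``um_per_px=None`` for uncalibrated input:
    µm columns are then NaN.
    """
    if not mask.any():
        raise ValueError("empty mask: nothing segmented")
    labels = measure.label(mask, connectivity=2)
    top_labels = np.unique(labels[0])
    top_labels = top_labels[top_labels != 0]
    if top_labels.size == 0:
        raise ValueError("no epithelial sheet found; check image orientation (air side must be up)")
    areas = np.bincount(labels.ravel())
    sheet_label = int(top_labels[np.argmax(areas[top_labels])])
    sheet_mask = labels == sheet_label
    base = sheet_base_row(sheet_mask)
    # Euclidean distance from every pixel to the nearest sheet pixel
    dist_to_sheet = ndimage.distance_transform_edt(~sheet_mask)

    cal = float(um_per_px) if um_per_px is not None else np.nan
    rows = [
        {
            "label": sheet_label,
            "is_sheet": True,
            "area_px2": int(areas[sheet_label]),
            "area_um2": areas[sheet_label] * cal**2,
            "nuclei_count": -1,
            "is_singular": False,
            "depth_um": 0.0,
            "min_distance_to_sheet_um": 0.0,
            "max_row": base,
        }
    ]
    for region in measure.regionprops(labels):
        if region.label == sheet_label or region.area < min_island_area:
            continue
        coords = region.coords
        max_row = int(coords[:, 0].max())
        depth_px = max(0, max_row - base)
        min_dist_px = float(dist_to_sheet[coords[:, 0], coords[:, 1]].min())
        rows.append(
            {
                "label": region.label,
                "is_sheet": False,
                "area_px2": int(region.area),
                "area_um2": region.area * cal**2,
                "nuclei_count": -1,
                "is_singular": False,
                "depth_um": depth_px * cal,
                "min_distance_to_sheet_um": min_dist_px * cal,
                "max_row": max_row,
            }
        )
    return pd.DataFrame(rows), labels, sheet_mask


def count_nuclei(
    image: OrganImage,
    island_mask: np.ndarray,
    min_nucleus_area: int = MIN_NUCLEUS_AREA,
) -> int:
    """Count DAPI nuclei inside one island.

    The DAPI channel restricted to the island is Otsu-thresholded and
    8-connected components with area >= ``min_nucleus_area`` are counted.
    An island with no DAPI signal counts 0.
    """
    dapi = image.channel("dapi")
    vals = dapi[island_mask]
    if vals.size == 0 or np.ptp(vals) == 0:
        # constant signal within the island: all-background (or all-foreground,
        # which a >=9 px² filter on one blob still counts correctly below)
        if vals.size and vals.max() > 0.5:
            nuc = island_mask
        else:
            return 0
    else:
        t = threshold_otsu(vals)
        nuc = island_mask & (dapi >= t)
    labels = measure.label(nuc, connectivity=2)
    if labels.max() == 0:
        return 0
    areas = np.bincount(labels.ravel())[1:]
    return int(np.count_nonzero(areas >= min_nucleus_area))


def fill_nuclei_counts(
    island_table: pd.DataFrame,
    image: OrganImage,
    labels: np.ndarray,
    cutoff: int = 15,
    min_nucleus_area: int = MIN_NUCLEUS_AREA,
) -> pd.DataFrame:
    """Fill ``nuclei_count`` / ``is_singular`` for every island row in place."""
    for i, row in island_table.iterrows():
        if row["is_sheet"]:
            continue
        n = count_nuclei(image, labels == row["label"], min_nucleus_area)
        island_table.loc[i, "nuclei_count"] = n
        island_table.loc[i, "is_singular"] = n < cutoff
    return island_table


def invasion_depth(island_table: pd.DataFrame) -> float:
    """Image-level invasion depth: maximum island depth (µm), 0 with no islands."""
    islands = island_table[~island_table["is_sheet"].astype(bool)]
    if islands.empty:
        return 0.0
    return float(islands["depth_um"].max())


def measure_lwr(cell_masks: list[np.ndarray]) -> tuple[list[CellShape], float]:
    """Length-to-width ratio of 2D cultured cells from binary masks.

    Major/minor axis lengths come from the eigenvalues of the second central
    moments of each mask's pixel set (the moment-equivalent ellipse); LWR =
    major/minor >= 1.  A value near 1 indicates a cuboidal epithelial cell,
    larger values an elongated, mesenchymal-like cell.  Returns the per-cell
    records and the population mean LWR.
    """
    shapes: list[CellShape] = []
    for i, mask in enumerate(cell_masks):
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() < 10:
            raise ValueError(f"cell mask {i}: fewer than 10 pixels")
        props = measure.regionprops(mask.astype(np.uint8))[0]
        if props.axis_minor_length == 0:
            raise ValueError(f"cell mask {i}: degenerate (collinear) pixel set")
        shapes.append(CellShape(i, props.axis_major_length, props.axis_minor_length))
    return shapes, float(np.mean([s.lwr for s in shapes]))


def mean_marker_intensity(image: OrganImage, mask: np.ndarray, channel: str) -> float:
    """Arithmetic mean of a channel over the mask pixels (e.g. PDPN in tumor)."""
    if not mask.any():
        raise ValueError("empty mask: mean intensity undefined")
    return float(image.channel(channel)[mask].mean())


def quantify_image(
    image: OrganImage,
    method: str = "otsu",
    min_island_area: int = MIN_ISLAND_AREA,
    min_nucleus_area: int = MIN_NUCLEUS_AREA,
    cutoff: int = 15,
) -> dict:
    """Run the full per-image pipeline.

    Returns a dict with ``island_table``, ``sheet_mask``, ``sheet_base_row``,
    ``labels``, ``depth_um``, ``threshold`` — everything the grading stage
    needs.
    """
    mask, threshold = segment_keratinocytes(image, "cytokeratin", method)
    table, labels, sheet = extract_islands(mask, image.um_per_px, min_island_area)
    fill_nuclei_counts(table, image, labels, cutoff, min_nucleus_area)
    return {
        "island_table": table,
        "sheet_mask": sheet,
        "sheet_base_row": sheet_base_row(sheet),
        "labels": labels,
        "depth_um": invasion_depth(table),
        "threshold": threshold,
    }
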