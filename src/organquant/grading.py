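"""Invasion grading of organ-culture section images.

Three readouts are computed from a per-image island table:

* **invasion index** — total detached-island area (µm²) × island count ×
  invasion depth (µm); a dimensionless composite that is 0 whenever no island
  exists or nothing lies below the epithelial sheet.
* **SPOI** (single pattern of invasion) — number of singular islands
  (< 15 nuclei) divided by number of clustered islands (>= 15 nuclei);
  recorded as 0 when no singular island is present.  With singular islands
  but zero clustered ones the ratio is undefined; we report the singular
  count with ``spoi_undefined_flag`` set so the value stays monotone in the
  singular count and is never silently mixed into aggregates.
* **WPOI** (worst pattern of invasion) — histological grade 1–5, "worst
  wins": 5 if any island sits >= 1 mm from the tumor mass; else 4 if any
  singular detached island exists; else 3 if any detached island exists;
  else 2 if the invasion front shows finger-like protrusions; else 1 (broad
  pushing front).  An island counted with exactly 15 nuclei is clustered,
  matching the SPOI dichotomy, and contributes to grade 3.

The island table is a DataFrame as produced by :mod:`organquant.imagequant`
(one row flagged ``is_sheet``, detached islands otherwise) with columns
``area_um2``, ``nuclei_count``, ``depth_um``, ``min_distance_to_sheet_um``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

__all__ = [
    "NUCLEI_CUTOFF",
    "WPOI5_DISTANCE_UM",
    "PROTRUSION_ASPECT",
    "GradingResult",
    "ExperimentSummary",
    "is_singular",
    "invasion_index",
    "compute_spoi",
    "wpoi_from_features",
    "count_protrusions",
    "grade_wpoi",
    "grade_image",
    "spoi_fold_change",
    "aggregate_experiment",
]

#: Islands with fewer nuclei than this are "singular"; >= cutoff is "clustered".
NUCLEI_CUTOFF = 15
#: Islands at least this far (µm) from the tumor mass force WPOI 5 (the 1 mm rule).
WPOI5_DISTANCE_UM = 1000.0
#: Minimum length/width ratio for a sheet protrusion to count as a WPOI-2 finger.
PROTRUSION_ASPECT = 2.0


@dataclass
class GradingResult:
    image_id: str
    invasion_index: float
    wpoi: int
    spoi: float
    n_singular: int
    n_clustered: int
    spoi_undefined_flag: bool = False


@dataclass
class ExperimentSummary:
    experiment_id: str
    n_fields: int
    mean_invasion_index: float
    sem_invasion_index: float
    mean_spoi: float
    sem_spoi: float
    wpoi_mode: int
    mean_wpoi: float


def is_singular(nuclei_count, cutoff: int = NUCLEI_CUTOFF):
    """True for islands with fewer than ``cutoff`` nuclei (element-wise)."""
    out = np.asarray(nuclei_count) < cutoff
    return out if out.ndim else bool(out)


def _island_rows(island_table: pd.DataFrame) -> pd.DataFrame:
    if "is_sheet" in island_table.columns:
        return island_table[~island_table["is_sheet"].astype(bool)]
    return island_table


def invasion_index(island_table: pd.DataFrame, image_depth_um: float) -> float:
    """Composite index = total island area (µm²) × island count × depth (µm)."""
    islands = _island_rows(island_table)
    n = len(islands)
    if n == 0:
        return 0.0
    total_area = float(islands["area_um2"].sum())
    return total_area * n * float(image_depth_um)


def compute_spoi(
    island_table: pd.DataFrame, cutoff: int = NUCLEI_CUTOFF
) -> tuple[float, int, int, bool]:
    """SPOI = n_singular / n_clustered; 0 when no singular island exists.

    Returns ``(spoi, n_singular, n_clustered, undefined_flag)``.  The flag is
    set when singular islands exist but clustered ones do not; the reported
    value is then the singular count.
    """
    islands = _island_rows(island_table)
    singular = is_singular(islands["nuclei_count"].to_numpy(), cutoff)
    n_sing = int(np.count_nonzero(singular))
    n_clus = int(len(islands) - n_sing)
    if n_sing == 0:
        return 0.0, n_sing, n_clus, False
    if n_clus == 0:
        return float(n_sing), n_sing, n_clus, True
    return n_sing / n_clus, n_sing, n_clus, False


def wpoi_from_features(
    n_islands: int,
    any_singular: bool,
    max_island_distance_um: float,
    n_protrusions: int,
    distance_cutoff_um: float = WPOI5_DISTANCE_UM,
) -> int:
    """Grade precedence 5 > 4 > 3 > 2 > 1 ("worst" pattern wins)."""
    if n_islands > 0 and max_island_distance_um >= distance_cutoff_um:
        return 5
    if n_islands > 0 and any_singular:
        return 4
    if n_islands > 0:
        return 3
    if n_protrusions >= 1:
        return 2
    return 1


def count_protrusions(
    sheet_mask: np.ndarray,
    sheet_base_row: int,
    aspect: float = PROTRUSION_ASPECT,
) -> int:
    """Count finger-like sheet protrusions below the base contour.

    Connected components (8-connectivity) of the sheet mask restricted to rows
    strictly below ``sheet_base_row`` whose vertical extent / horizontal
    extent >= ``aspect`` are counted as fingers.  The base contour is the
    median per-column lowest sheet row, so broad undulations of the front do
    not register as protrusions.
    """
    below = np.zeros_like(sheet_mask, dtype=bool)
    below[sheet_base_row + 1:] = sheet_mask[sheet_base_row + 1:]
    if not below.any():
        return 0
    labels = measure.label(below, connectivity=2)
    count = 0
    for region in measure.regionprops(labels):
        r0, c0, r1, c1 = region.bbox
        length, width = r1 - r0, c1 - c0
        if width > 0 and length / width >= aspect:
            count += 1
    return count


def grade_wpoi(
    island_table: pd.DataFrame,
    sheet_mask: np.ndarray | None = None,
    sheet_base_row: int | None = None,
    um_per_px: float | None = None,
    cutoff: int = NUCLEI_CUTOFF,
    distance_cutoff_um: float = WPOI5_DISTANCE_UM,
    protrusion_aspect: float = PROTRUSION_ASPECT,
) -> int:
    """WPOI grade 1–5 for one image.

    ``sheet_mask``/``sheet_base_row`` are only needed to distinguish grades 1
    and 2 (front geometry); the island table alone decides grades 3–5.  The
    1 mm rule needs the table's ``min_distance_to_sheet_um`` column, which
    requires calibration — an island table built without ``um_per_px`` makes
    grade 5 undecidable and raises.
    """
    islands = _island_rows(island_table)
    n_islands = len(islands)
    if n_islands > 0:
        dist = islands["min_distance_to_sheet_um"].to_numpy(dtype=float)
        if np.isnan(dist).any():
            raise ValueError(
                "island distances are uncalibrated; provide um_per_px when "
                "building the island table (grade 5 undecidable)"
            )
        max_dist = float(dist.max())
        any_sing = bool(is_singular(islands["nuclei_count"].to_numpy(), cutoff).any())
    else:
        max_dist, any_sing = 0.0, False
    n_prot = 0
    if sheet_mask is not None and sheet_base_row is not None:
        n_prot = count_protrusions(sheet_mask, sheet_base_row, protrusion_aspect)
    return wpoi_from_features(n_islands, any_sing, max_dist, n_prot, distance_cutoff_um)


def grade_image(
    island_table: pd.DataFrame,
    image_depth_um: float,
    image_id: str = "image",
    sheet_mask: np.ndarray | None = None,
    sheet_base_row: int | None = None,
    cutoff: int = NUCLEI_CUTOFF,
    distance_cutoff_um: float = WPOI5_DISTANCE_UM,
) -> GradingResult:
    """Convenience: invasion index + SPOI + WPOI for one island table."""
    spoi, n_sing, n_clus, flag = compute_spoi(island_table, cutoff)
    return GradingResult(
        image_id=image_id,
        invasion_index=invasion_index(island_table, image_depth_um),
        wpoi=grade_wpoi(
            island_table, sheet_mask, sheet_base_row,
            cutoff=cutoff, distance_cutoff_um=distance_cutoff_um,
        ),
        spoi=spoi,
        n_singular=n_sing,
        n_clustered=n_clus,
        spoi_undefined_flag=flag,
    )


def spoi_fold_change(wf: ExperimentSummary, wof: ExperimentSummary) -> tuple[float, bool]:
    """Fold change of mean SPOI with fibroblasts (WF) over without (WOF).

    Returns ``(fold, undefined)``; a WOF mean of 0 yields ``(inf, True)`` and
    must be excluded from aggregates by the caller.
    """
    if wof.mean_spoi == 0:
        return float("inf"), True
    return wf.mean_spoi / wof.mean_spoi, False


def aggregate_experiment(
    field_results: list[GradingResult], experiment_id: str = "experiment"
) -> ExperimentSummary:
    """Average per-field grading results into one experiment-level summary.

    The sampling design takes triplicate images at three gel positions
    (center, quarter-left, quarter-right), i.e. nine fields per independent
    experiment which are averaged into a single sample point; a different
    field count triggers a warning, not an error.
    """
    if not field_results:
        raise ValueError("aggregate_experiment requires at least one field result")
    if len(field_results) != 9:
        warnings.warn(
            f"experiment {experiment_id!r}: expected 9 fields, got {len(field_results)}",
            stacklevel=2,
        )
    idx = np.array([f.invasion_index for f in field_results], dtype=float)
    spoi = np.array([f.spoi for f in field_results], dtype=float)
    wpoi = np.array([f.wpoi for f in field_results], dtype=int)

    def sem(v: np.ndarray) -> float:
        return float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0

    modes, counts = np.unique(wpoi, return_counts=True)
    return ExperimentSummary(
        experiment_id=experiment_id,
        n_fields=len(field_results),
        mean_invasion_index=float(idx.mean()),
        sem_invasion_index=sem(idx),
        mean_spoi=float(spoi.mean()),
        sem_spoi=sem(spoi),
        wpoi_mode=int(modes[np.argmax(counts)]),
        mean_wpoi=float(wpoi.mean()),
    )
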