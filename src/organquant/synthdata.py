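"""Synthetic ground-truth data for every pipeline input.

No public image/qPCR data accompany the quantification workflow this package
implements, so each input kind is emulated with exactly known ground truth:

* organ-culture section images (cytokeratin / PDPN / DAPI channels) with a
  sidecar recording every island's position, pixel area, nuclei count, depth
  and distance to the epithelial sheet, plus the invasion readouts the
  grading stage must recover;
* qPCR Ct tables driven by a latent per-population p-EMT intensity;
* 2D cell masks with known length-to-width ratios;
* pSMAD3 densitometry tables with known TGF-β responder labels;
* transcription-factor expression matrices with a planted phenotype-coupled
  column.

Geometry convention: row 0 is the top (air side); the epithelial sheet
occupies the top rows and invasion proceeds downward.  Foreground intensity
is 1.0 on a 0.0 background with optional additive Gaussian noise clipped to
[0, 1] — the simplest model that still exercises thresholding.  Nuclei are
disjoint discs of radius 3 px separated by >= 2 px so ground-truth counts
are unambiguous.  Identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw

from . import grading
from .imagequant import OrganImage
from .pemt import DEFAULT_PANEL, REFERENCE_GENE

__all__ = [
    "OrganImageSpec",
    "GroundTruth",
    "CtGeneratorSpec",
    "generate_organ_image",
    "generate_ct_table",
    "generate_cell_masks",
    "generate_densitometry",
    "generate_tf_matrix",
    "random_organ_spec",
]

NUCLEUS_RADIUS = 3  # px
NUCLEUS_PITCH = 2 * NUCLEUS_RADIUS + 2  # centre spacing => >=2 px gap between discs
ISLAND_CLEARANCE = 3  # px gap kept around every island
PROTRUSION_WIDTH = 5  # px
PROTRUSION_LENGTH = 15  # px (aspect 3, safely a "finger")


@dataclass(frozen=True)
class OrganImageSpec:
    """Parameters of one synthetic organ-culture section image.

    ``island_depths_px`` give each island centre's row offset below the sheet
    base; ``far_island_distance_um`` (WPOI-5 fixtures) overrides the last
    island's position so its top edge sits exactly that far below the sheet.
    Singular islands (listed first) carry ``nuclei_per_singular`` nuclei
    (< 15), clustered ones ``nuclei_per_clustered`` (>= 15).
    """

    width_px: int = 480
    height_px: int = 420
    um_per_px: float = 1.0
    sheet_thickness_px: int = 50
    n_singular_islands: int = 0
    n_clustered_islands: int = 0
    nuclei_per_singular: int = 8
    nuclei_per_clustered: int = 20
    island_depths_px: tuple[int, ...] = ()
    island_radii_px: tuple[int, ...] = ()
    front_protrusions: int = 0
    far_island_distance_um: float | None = None
    noise_sd: float = 0.0
    pdpn_sheet_intensity: float = 0.2
    pdpn_island_intensity: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.n_singular_islands + self.n_clustered_islands
        if len(self.island_depths_px) != n or len(self.island_radii_px) != n:
            raise ValueError(
                f"island_depths_px/island_radii_px must each have "
                f"{n} entries (n_singular + n_clustered)"
            )
        if not 1 <= self.nuclei_per_singular <= 14:
            raise ValueError("nuclei_per_singular must be in [1, 14]")
        if self.nuclei_per_clustered < 15:
            raise ValueError("nuclei_per_clustered must be >= 15")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sheet_thickness_px < 2 or self.sheet_thickness_px >= self.height_px:
            raise ValueError("sheet_thickness_px out of range")

    @property
    def n_islands(self) -> int:
        return self.n_singular_islands + self.n_clustered_islands


@dataclass
class GroundTruth:
    """Exact rendered geometry plus the invasion readouts it implies."""

    islands: pd.DataFrame  # center_row, center_col, radius_px, area_px2, nuclei_count,
    #                        depth_um, distance_to_sheet_um, is_singular
    sheet_base_row: int
    sheet_area_px2: int
    n_protrusions: int
    um_per_px: float
    expected_spoi: float
    expected_wpoi: int
    expected_invasion_index: float
    expected_depth_um: float
    spec: OrganImageSpec | None = None

    def to_island_table(self) -> pd.DataFrame:
        """Ground-truth records in the grading stage's island-table layout."""
        rows = [
            {
                "label": 0,
                "is_sheet": True,
                "area_px2": self.sheet_area_px2,
                "area_um2": self.sheet_area_px2 * self.um_per_px**2,
                "nuclei_count": -1,
                "is_singular": False,
                "depth_um": 0.0,
                "min_distance_to_sheet_um": 0.0,
            }
        ]
        for i, isl in self.islands.iterrows():
            rows.append(
                {
                    "label": i + 1,
                    "is_sheet": False,
                    "area_px2": int(isl["area_px2"]),
                    "area_um2": isl["area_px2"] * self.um_per_px**2,
                    "nuclei_count": int(isl["nuclei_count"]),
                    "is_singular": bool(isl["is_singular"]),
                    "depth_um": float(isl["depth_um"]),
                    "min_distance_to_sheet_um": float(isl["distance_to_sheet_um"]),
                }
            )
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        d = {
            "sheet_base_row": self.sheet_base_row,
            "sheet_area_px2": self.sheet_area_px2,
            "n_protrusions": self.n_protrusions,
            "um_per_px": self.um_per_px,
            "expected_spoi": self.expected_spoi,
            "expected_wpoi": self.expected_wpoi,
            "expected_invasion_index": self.expected_invasion_index,
            "expected_depth_um": self.expected_depth_um,
            "islands": self.islands.to_dict(orient="records"),
        }
        if self.spec is not None:
            d["spec"] = dataclasses.asdict(self.spec)
        return d


def _nucleus_offsets(radius_px: int, n_nuclei: int, rng: np.random.Generator) -> np.ndarray:
    """Pick n disjoint nucleus-centre offsets on a pitch-8 lattice inside a disc."""
    margin = radius_px - NUCLEUS_RADIUS - 1
    steps = np.arange(-margin, margin + 1, NUCLEUS_PITCH)
    dy, dx = np.meshgrid(steps, steps, indexing="ij")
    pts = np.stack([dy.ravel(), dx.ravel()], axis=1)
    pts = pts[np.hypot(pts[:, 0], pts[:, 1]) <= margin]
    if len(pts) < n_nuclei:
        raise ValueError(
            f"island radius {radius_px} px too small for {n_nuclei} disjoint "
            f"nuclei (fits {len(pts)})"
        )
    return pts[rng.permutation(len(pts))[:n_nuclei]]


def generate_organ_image(spec: OrganImageSpec) -> tuple[OrganImage, GroundTruth]:
    """Render one calibrated 3-channel image and its exact ground truth.

    Raises if the requested islands cannot be placed without touching each
    other or the sheet — overlapping ground-truth islands are never silently
    merged.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height_px, spec.width_px
    ck = np.zeros((H, W), dtype=float)
    pdpn = np.zeros((H, W), dtype=float)
    dapi = np.zeros((H, W), dtype=float)

    # --- epithelial sheet (top rows) plus optional finger protrusions
    T = spec.sheet_thickness_px
    base_row = T - 1
    sheet = np.zeros((H, W), dtype=bool)
    sheet[:T, :] = True
    sheet_extent = base_row
    if spec.front_protrusions:
        total_w = spec.front_protrusions * PROTRUSION_WIDTH
        if total_w * 2 >= W:
            raise ValueError("too many protrusions for image width")
        centers = np.linspace(0, W, spec.front_protrusions + 2)[1:-1].astype(int)
        for cx in centers:
            c0 = cx - PROTRUSION_WIDTH // 2
            sheet[T:T + PROTRUSION_LENGTH, c0:c0 + PROTRUSION_WIDTH] = True
        sheet_extent = base_row + PROTRUSION_LENGTH
    ck[sheet] = 1.0
    pdpn[sheet] = spec.pdpn_sheet_intensity

    # sheet nuclei on a fixed lattice (kept clear of the base rows)
    for r in range(5, max(6, T - NUCLEUS_RADIUS - 3), NUCLEUS_PITCH + 1):
        for c in range(5, W - 5, NUCLEUS_PITCH + 1):
            rr, cc = draw.disk((r, c), NUCLEUS_RADIUS, shape=(H, W))
            dapi[rr, cc] = 1.0

    # --- detached islands: singular first, then clustered
    n_islands = spec.n_islands
    depths = list(spec.island_depths_px)
    radii = list(spec.island_radii_px)
    if spec.far_island_distance_um is not None and n_islands > 0:
        far_px = int(round(spec.far_island_distance_um / spec.um_per_px))
        # place the last island so its rasterized top edge sits exactly far_px
        # below the base (the disc's pixel extent is not exactly the radius)
        probe_rr, _ = draw.disk((0, 0), radii[-1])
        depths[-1] = far_px - int(probe_rr.min())
    placed: list[tuple[int, int, int]] = []  # (row, col, radius)
    records = []
    for i in range(n_islands):
        r_px, d_px = radii[i], depths[i]
        c_row = base_row + d_px
        if c_row - r_px < sheet_extent + ISLAND_CLEARANCE:
            raise ValueError(
                f"island {i} (depth {d_px} px, radius {r_px} px) would touch the "
                "sheet/protrusions; increase its depth"
            )
        if c_row + r_px > H - 2:
            raise ValueError(f"island {i} does not fit inside the image height")
        if r_px + 2 > W // 2:
            raise ValueError(f"island {i} radius {r_px} px too large for image width")
        c_col = None
        for _ in range(300):
            cand = int(rng.integers(r_px + 2, W - r_px - 2))
            ok = all(
                np.hypot(c_row - pr, cand - pc) > r_px + prr + ISLAND_CLEARANCE
                for pr, pc, prr in placed
            )
            if ok:
                c_col = cand
                break
        if c_col is None:
            raise ValueError(
                f"could not place island {i} without overlap; requested density "
                "too high for the image width"
            )
        placed.append((c_row, c_col, r_px))
        rr, cc = draw.disk((c_row, c_col), r_px, shape=(H, W))
        ck[rr, cc] = 1.0
        pdpn[rr, cc] = spec.pdpn_island_intensity
        is_sing = i < spec.n_singular_islands
        n_nuc = spec.nuclei_per_singular if is_sing else spec.nuclei_per_clustered
        for dy, dx in _nucleus_offsets(r_px, n_nuc, rng):
            nr, nc = draw.disk((c_row + dy, c_col + dx), NUCLEUS_RADIUS, shape=(H, W))
            dapi[nr, nc] = 1.0
        max_row = int(rr.max())
        records.append(
            {
                "center_row": c_row,
                "center_col": c_col,
                "radius_px": r_px,
                "area_px2": int(len(rr)),
                "nuclei_count": n_nuc,
                "is_singular": is_sing,
                "depth_um": max(0, max_row - base_row) * spec.um_per_px,
                "distance_to_sheet_um": np.nan,  # filled below from the rendered masks
            }
        )

    # exact Euclidean island-to-sheet distances from the rendered geometry
    if records:
        dist = ndimage.distance_transform_edt(~sheet)
        for rec in records:
            rr, cc = draw.disk(
                (rec["center_row"], rec["center_col"]), rec["radius_px"], shape=(H, W)
            )
            rec["distance_to_sheet_um"] = float(dist[rr, cc].min()) * spec.um_per_px

    islands = pd.DataFrame(
        records,
        columns=[
            "center_row", "center_col", "radius_px", "area_px2", "nuclei_count",
            "is_singular", "depth_um", "distance_to_sheet_um",
        ],
    )

    # --- noise, applied after all geometry so the rng stream is stable
    if spec.noise_sd > 0:
        for ch in (ck, pdpn, dapi):
            ch += rng.normal(0.0, spec.noise_sd, size=ch.shape)
            np.clip(ch, 0.0, 1.0, out=ch)

    image = OrganImage(
        channels={"cytokeratin": ck, "pdpn": pdpn, "dapi": dapi},
        um_per_px=spec.um_per_px,
    )

    gt = GroundTruth(
        islands=islands,
        sheet_base_row=base_row,
        sheet_area_px2=int(sheet.sum()),
        n_protrusions=spec.front_protrusions,
        um_per_px=spec.um_per_px,
        expected_spoi=np.nan,
        expected_wpoi=0,
        expected_invasion_index=np.nan,
        expected_depth_um=float(islands["depth_um"].max()) if len(islands) else 0.0,
        spec=spec,
    )
    # expected readouts via the grading rules applied to the ground-truth records
    table = gt.to_island_table()
    spoi, _, _, _ = grading.compute_spoi(table)
    gt.expected_spoi = spoi
    gt.expected_invasion_index = grading.invasion_index(table, gt.expected_depth_um)
    max_dist = float(islands["distance_to_sheet_um"].max()) if len(islands) else 0.0
    gt.expected_wpoi = grading.wpoi_from_features(
        n_islands=len(islands),
        any_singular=bool(islands["is_singular"].any()) if len(islands) else False,
        max_island_distance_um=max_dist,
        n_protrusions=spec.front_protrusions,
    )
    return image, gt


@dataclass(frozen=True)
class CtGeneratorSpec:
    """Latent-gradient qPCR generator.

    Each population carries a latent p-EMT intensity in [0, 1]; at noise 0
    every panel gene's Ct is ``baseline_ct - level * dynamic_range_cycles``,
    so a higher latent level always means a lower Ct (higher expression).
    GAPDH sits at ``gapdh_ct`` for every population.
    """

    n_populations: int = 6
    pemt_levels: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    baseline_ct: float = 30.0
    gapdh_ct: float = 20.0
    dynamic_range_cycles: float = 5.0
    noise_sd_cycles: float = 0.0
    n_replicates: int = 3
    seed: int = 0
    panel: tuple[str, ...] = DEFAULT_PANEL

    def __post_init__(self) -> None:
        if self.n_populations < 2:
            raise ValueError(
                "need at least 2 populations (score normalization uses the "
                "across-population extremes)"
            )
        if len(self.pemt_levels) != self.n_populations:
            raise ValueError("pemt_levels must have one entry per population")
        if any(not 0.0 <= v <= 1.0 for v in self.pemt_levels):
            raise ValueError("pemt_levels must lie in [0, 1]")
        if self.noise_sd_cycles < 0 or self.n_replicates < 1:
            raise ValueError("noise_sd_cycles >= 0 and n_replicates >= 1 required")

    def population_ids(self) -> list[str]:
        return [f"HN{i + 1:02d}" for i in range(self.n_populations)]


def generate_ct_table(spec: CtGeneratorSpec) -> pd.DataFrame:
    """Long-format Ct table (population_id, gene_id, replicate, ct)."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for pop, level in zip(spec.population_ids(), spec.pemt_levels):
        for rep in range(1, spec.n_replicates + 1):
            for gene in spec.panel:
                ct = spec.baseline_ct - level * spec.dynamic_range_cycles
                ct += rng.normal(0.0, spec.noise_sd_cycles) if spec.noise_sd_cycles else 0.0
                rows.append((pop, gene, rep, ct))
            g = spec.gapdh_ct
            g += rng.normal(0.0, spec.noise_sd_cycles) if spec.noise_sd_cycles else 0.0
            rows.append((pop, REFERENCE_GENE, rep, g))
    return pd.DataFrame(rows, columns=["population_id", "gene_id", "replicate", "ct"])


def generate_cell_masks(
    n_cells: int,
    axis_ratios,
    seed: int = 0,
    minor_semi_axis_px: float = 9.0,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Rasterized filled ellipses with known major/minor axis ratios.

    ``axis_ratios`` is a scalar or a length-``n_cells`` vector of ratios >= 1
    (1 = disc, i.e. cuboidal cell outline).  Each cell is drawn at a random
    orientation.  Returns the binary masks and the ground-truth ratios.
    """
    ratios = np.broadcast_to(np.asarray(axis_ratios, dtype=float), (n_cells,)).copy()
    if (ratios < 1.0).any():
        raise ValueError("axis ratios must be >= 1")
    rng = np.random.default_rng(seed)
    masks = []
    size = int(2 * ratios.max() * minor_semi_axis_px) + 9  # common canvas, stackable
    for ratio in ratios:
        a = ratio * minor_semi_axis_px
        canvas = np.zeros((size, size), dtype=bool)
        theta = rng.uniform(0.0, np.pi)
        rr, cc = draw.ellipse(
            size // 2, size // 2, minor_semi_axis_px, a,
            shape=canvas.shape, rotation=theta,
        )
        canvas[rr, cc] = True
        masks.append(canvas)
    return masks, ratios


def generate_densitometry(
    n_responders: int,
    n_nonresponders: int,
    responder_fold_range: tuple[float, float] = (2.0, 4.0),
    seed: int = 0,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """pSMAD3/GAPDH densitometry pairs with known responder labels.

    Responder populations get a TGF-β fold change drawn uniformly from
    ``responder_fold_range`` (defaults to the 2–4-fold stimulation typical of
    responsive lines); non-responders get fold change exactly 1 at noise 0.
    Returns columns (population, psmad3_ctrl, psmad3_tgfb, is_responder).
    """
    if n_responders < 0 or n_nonresponders < 0 or n_responders + n_nonresponders == 0:
        raise ValueError("need a positive total number of populations")
    lo, hi = responder_fold_range
    if lo > hi or lo <= 0:
        raise ValueError("invalid responder_fold_range")
    rng = np.random.default_rng(seed)
    rows = []
    total = n_responders + n_nonresponders
    for i in range(total):
        responder = i < n_responders
        ctrl = rng.uniform(0.8, 1.2)
        fold = rng.uniform(lo, hi) if responder else 1.0
        tgfb = ctrl * fold
        if noise_sd:
            tgfb *= 1.0 + rng.normal(0.0, noise_sd)
        rows.append((f"HN{i + 1:02d}", ctrl, tgfb, responder))
    return pd.DataFrame(
        rows, columns=["population", "psmad3_ctrl", "psmad3_tgfb", "is_responder"]
    )


def generate_tf_matrix(
    phenotype,
    n_tfs: int = 40,
    planted_r: float = 0.95,
    seed: int = 0,
) -> tuple[pd.DataFrame, str]:
    """Expression matrix (populations × TFs) with one phenotype-coupled column.

    The planted transcription factor is built as ``r*z + sqrt(1-r²)*eps`` on
    the standardized phenotype z, giving a generative correlation of
    ``planted_r``; the remaining columns are independent standard normals.
    Returns the matrix and the planted TF's name.
    """
    phenotype = np.asarray(phenotype, dtype=float)
    n = len(phenotype)
    if n < 3:
        raise ValueError("need at least 3 populations")
    rng = np.random.default_rng(seed)
    z = (phenotype - phenotype.mean()) / phenotype.std()
    cols = {}
    planted_name = "TF_planted"
    eps = rng.standard_normal(n)
    cols[planted_name] = planted_r * z + np.sqrt(1.0 - planted_r**2) * eps
    for j in range(n_tfs - 1):
        cols[f"TF{j + 1:03d}"] = rng.standard_normal(n)
    index = [f"HN{i + 1:02d}" for i in range(n)]
    return pd.DataFrame(cols, index=index), planted_name


def random_organ_spec(
    rng: np.random.Generator,
    noise_sd: float = 0.0,
    allow_protrusions: bool = False,
) -> OrganImageSpec:
    """Draw a random valid image spec (used for parameter-recovery sweeps)."""
    n_sing = int(rng.integers(0, 4))
    n_clus = int(rng.integers(0, 4))
    radii, depths = [], []
    for _ in range(n_sing):
        radii.append(int(rng.integers(22, 26)))
    for _ in range(n_clus):
        radii.append(int(rng.integers(28, 33)))
    for r in radii:
        depths.append(int(rng.integers(r + 25, 330 - r)))
    return OrganImageSpec(
        width_px=480,
        height_px=420,
        sheet_thickness_px=50,
        n_singular_islands=n_sing,
        n_clustered_islands=n_clus,
        nuclei_per_singular=int(rng.integers(1, 15)),
        nuclei_per_clustered=int(rng.integers(15, 26)),
        island_depths_px=tuple(depths),
        island_radii_px=tuple(radii),
        front_protrusions=int(rng.integers(0, 3)) if allow_protrusions else 0,
        noise_sd=noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
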