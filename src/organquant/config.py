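"""Run configuration: a single YAML-backed block of paths, calibration and
thresholds; CLI flags override file values."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # paths
    images_dir: str | None = None
    ct_table: str | None = None
    densitometry: str | None = None
    tf_matrix: str | None = None
    output_dir: str = "organquant_out"
    # calibration
    um_per_px: float = 1.0
    # thresholds (documented defaults; every one is echoed to the provenance log)
    segmentation_method: str = "otsu"
    min_island_area: int = 25
    min_nucleus_area: int = 9
    nuclei_cutoff: int = 15
    wpoi_distance_um: float = 1000.0
    responder_fold_threshold: float = 1.5
    outlier_alpha: float = 0.05
    # misc
    seed: int = 0
    fields_per_experiment: int = 9

    def __post_init__(self) -> None:
        for name in ("um_per_px", "min_island_area", "min_nucleus_area",
                     "nuclei_cutoff", "wpoi_distance_um",
                     "responder_fold_threshold", "outlier_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    def asdict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Read a YAML config file and apply keyword overrides (CLI flags win)."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(RunConfig)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)
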