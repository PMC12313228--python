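"""Readers/writers: multi-page TIFF images, JSON ground-truth sidecars,
CSV tables, and the per-run provenance log."""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imagequant import CHANNELS, OrganImage
from .synthdata import GroundTruth

__all__ = [
    "write_organ_image",
    "read_organ_image",
    "read_sidecar",
    "write_island_table",
    "ProvenanceLog",
]


def write_organ_image(path, image: OrganImage, ground_truth: GroundTruth | None = None) -> Path:
    """Write a 3-page float32 TIFF (cytokeratin, pdpn, dapi) plus a JSON sidecar.

    The sidecar always records the calibration; with ground truth it also
    carries every generation parameter and the expected invasion readouts.
    """
    path = Path(path)
    stack = np.stack([image.channel(c) for c in CHANNELS]).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar: dict = {"um_per_px": image.um_per_px, "channel_order": list(CHANNELS)}
    if ground_truth is not None:
        sidecar["ground_truth"] = ground_truth.to_json_dict()
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, default=_jsonify))
    return path


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_sidecar(image_path) -> dict | None:
    sc = Path(image_path).with_suffix(".json")
    return json.loads(sc.read_text()) if sc.exists() else None


def read_organ_image(path, um_per_px: float | None = None) -> OrganImage:
    """Read a single- or multi-page TIFF/PNG into an OrganImage.

    Pages map to (cytokeratin, pdpn, dapi) in order; a 2D image becomes the
    cytokeratin channel with empty PDPN/DAPI.  Calibration comes from the
    argument, else the sidecar; missing both is an error because every
    µm-denominated readout needs it.
    """
    path = Path(path)
    arr = tifffile.imread(path) if path.suffix.lower() in {".tif", ".tiff"} else _read_other(path)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] not in (1, 3) and arr.shape[-1] in (3, 4):  # H x W x C layout
        arr = np.moveaxis(arr[..., :3], -1, 0)
    if arr.max() > 1.0:
        arr = arr / 255.0
    channels = {name: (arr[i] if i < arr.shape[0] else np.zeros_like(arr[0]))
                for i, name in enumerate(CHANNELS)}
    if um_per_px is None:
        sc = read_sidecar(path)
        if sc is None or "um_per_px" not in sc:
            raise ValueError(
                f"{path}: no calibration; pass um_per_px or provide a sidecar"
            )
        um_per_px = float(sc["um_per_px"])
    return OrganImage(channels=channels, um_per_px=um_per_px)


def _read_other(path: Path) -> np.ndarray:
    from imageio import v3 as iio  # PNG and friends

    return iio.imread(path)


def write_island_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


class ProvenanceLog:
    """Accumulates per-stage parameters, warnings and outputs; writes JSON.

    Every threshold a run uses is echoed here so no default stays silent, and
    every output file is listed with the configuration that produced it.
    """

    def __init__(self, config: dict | None = None):
        from . import __version__

        self.record: dict = {
            "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
            "software_version": __version__,
            "config": config or {},
            "stages": [],
            "outputs": [],
            "warnings": [],
        }

    def stage(self, name: str, **params) -> None:
        self.record["stages"].append({"stage": name, "params": params})

    def output(self, path, description: str = "") -> None:
        self.record["outputs"].append({"path": str(path), "description": description})

    def warn(self, message: str) -> None:
        self.record["warnings"].append(message)

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.record, indent=1, default=_jsonify))
        return path
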