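"""File I/O: plate images (PNG/TIFF, 8-bit RGB), ground-truth
sidecars (JSON/CSV), and YAML configuration."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .synthetic_plate import GroundTruth, PlateLayout, default_layout

__all__ = [
    "read_image",
    "write_image",
    "write_ground_truth",
    "read_ground_truth_csv",
    "layout_from_dict",
    "layout_to_dict",
    "load_layout_yaml",
]


def read_image(path) -> np.ndarray:
    """Load a PNG or TIFF plate photograph as an (H, W, 3) uint8 array."""
    with Image.open(path) as img:
        arr = np.asarray(img.convert("RGB"), dtype=np.uint8)
    return arr


def write_image(path, image: np.ndarray) -> None:
    """Write an 8-bit RGB array as PNG or TIFF (by file extension)."""
    if image.dtype != np.uint8 or image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) uint8 RGB array")
    Image.fromarray(image, mode="RGB").save(path)


def write_ground_truth(path, truth: GroundTruth) -> None:
    """Write the sidecar as JSON (``.json``) or CSV (anything else)."""
    path = Path(path)
    records = truth.to_records()
    if path.suffix.lower() == ".json":
        import json

        payload = {"seed": truth.seed, "spots": records, "sample": truth.sample}
        path.write_text(json.dumps(payload, indent=2))
    else:
        pd.DataFrame(records).to_csv(path, index=False)


def read_ground_truth_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def layout_to_dict(layout: PlateLayout) -> dict:
    return {
        "plate_width": layout.plate_width,
        "plate_height": layout.plate_height,
        "origin_y": layout.origin_y,
        "front_y": layout.front_y,
        "ag_zone_top_y": layout.ag_zone_top_y,
        "lanes": list(layout.lanes),
        "reference_lane": layout.reference_lane,
        "pixel_size": layout.pixel_size,
    }


def layout_from_dict(d: dict) -> PlateLayout:
    if "lanes" in d:
        return PlateLayout(
            plate_width=d["plate_width"],
            plate_height=d["plate_height"],
            origin_y=d["origin_y"],
            front_y=d["front_y"],
            ag_zone_top_y=d["ag_zone_top_y"],
            lanes=tuple(d["lanes"]),
            reference_lane=d["reference_lane"],
            pixel_size=d["pixel_size"],
        )
    # compact form: just a lane count plus optional overrides
    return default_layout(
        d.get("n_lanes", 4),
        **{k: v for k, v in d.items() if k != "n_lanes"},
    )


def load_layout_yaml(path) -> PlateLayout:
    with open(path) as fh:
        return layout_from_dict(yaml.safe_load(fh) or {})
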