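"""Image, detection-CSV and config I/O."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthgen as sg
from .ers import ExposureSchedule
from .pipeline import TargetRecord

__all__ = [
    "read_image",
    "write_image",
    "write_detections",
    "read_detections",
    "read_scene_spec",
    "read_params",
]

DETECTION_COLUMNS = ["label", "x_c", "y_c", "total_intensity", "n_pixels",
                     "first_row", "last_row", "finalize_row"]


def read_image(path) -> np.ndarray:
    """Read an 8- or 16-bit grayscale TIFF/PNG as a 2D array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(
            f"{path.name}: expected a single-channel grayscale image, "
            f"got shape {img.shape}")
    if img.dtype not in (np.uint8, np.uint16):
        raise ValueError(f"{path.name}: unsupported dtype {img.dtype}; "
                         "expected uint8 or uint16")
    return img


def write_image(path, frame: np.ndarray) -> None:
    path = Path(path)
    frame = np.asarray(frame)
    if frame.dtype not in (np.uint8, np.uint16):
        raise ValueError("frames are written as uint8 or uint16")
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, frame)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, frame)


def _fmt(v: float) -> str:
    return f"{v:.6g}"


def records_frame(records: list[TargetRecord],
                  with_timestamps: bool = False) -> pd.DataFrame:
    cols = DETECTION_COLUMNS + (["timestamp_s"] if with_timestamps else [])
    rows = []
    for r in records:
        row = {"label": r.label, "x_c": _fmt(r.centroid[0]),
               "y_c": _fmt(r.centroid[1]),
               "total_intensity": _fmt(r.total_intensity),
               "n_pixels": r.n_pixels, "first_row": r.row_span[0],
               "last_row": r.row_span[1], "finalize_row": r.finalized_at_row}
        if with_timestamps:
            row["timestamp_s"] = _fmt(r.timestamp_s)
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)


def write_detections(records: list[TargetRecord], path,
                     schedule: ExposureSchedule | None = None) -> None:
    """Write detections as CSV; timestamp column present iff a schedule was
    used (an empty record list still produces the header)."""
    df = records_frame(records, with_timestamps=schedule is not None)
    df.to_csv(path, index=False)


def read_detections(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _build_background(cfg: dict):
    kind = cfg.get("kind", "flat")
    args = {k: v for k, v in cfg.items() if k != "kind"}
    if "center" in args:
        args["center"] = tuple(args["center"])
    table = {"flat": sg.FlatBackground, "gradient": sg.GradientBackground,
             "clouds": sg.CloudBackground, "disk": sg.DiskBackground}
    if kind not in table:
        raise ValueError(f"unknown background kind: {kind!r}")
    return table[kind](**args)


def read_scene_spec(path, seed: int | None = None) -> sg.SceneSpec:
    """Load a YAML/JSON scene description into a SceneSpec."""
    path = Path(path)
    with open(path) as fh:
        cfg = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    spots = []
    for s in cfg.get("spots", []):
        if "peak" in s:
            spots.append(sg.PSFSpot.from_peak(s["peak"], s["x0"], s["y0"],
                                              s["sigma"]))
        else:
            spots.append(sg.PSFSpot(s["I0"], s["x0"], s["y0"], s["sigma"]))
    bg_cfg = cfg.get("background", {"kind": "flat"})
    if isinstance(bg_cfg, list):
        background = tuple(_build_background(b) for b in bg_cfg)
    else:
        background = _build_background(bg_cfg)
    noise = sg.NoiseSpec(**cfg.get("noise", {}))
    return sg.SceneSpec(
        W=int(cfg.get("W", 128)), H=int(cfg.get("H", 128)),
        bitdepth=int(cfg.get("bitdepth", 8)), spots=tuple(spots),
        background=background, noise=noise,
        seed=int(cfg["seed"] if seed is None else seed))


def read_params(path):
    """Load pipeline parameter overrides from YAML/JSON."""
    from . import pipeline as pl

    path = Path(path)
    with open(path) as fh:
        cfg = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    thr = cfg.get("threshold", {"kind": "adaptive", "value": 5.0})
    policy = (pl.absolute_threshold(thr["value"]) if thr["kind"] == "absolute"
              else pl.adaptive_threshold(thr.get("value", 5.0)))
    lab = pl.LabelingParams(**cfg.get("labeling", {}))
    return pl.PipelineParams(L_bg=int(cfg.get("L_bg", 15)), threshold=policy,
                             labeling=lab, recovery=bool(cfg.get("recovery", True)))
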