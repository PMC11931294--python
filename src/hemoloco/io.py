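"""Disk formats: per-band TIFF stacks with JSON sidecars, CSV traces and tables,
PNG masks, and JSON line ROIs.

Layout of a stack directory::

    stack/
      band_494nm.tif   # multi-page TIFF, one page per frame
      band_560nm.tif
      ...
      stack.json       # frame rate, band list, seed, ground-truth pointer

Hemoglobin maps are written analogously (hbo.tif / hbr.tif / hbt.tif +
hemo.json). Masks are single-channel 0/255 PNGs with a JSON sidecar carrying
the label, origin and parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .roi import RoiMask
from .spectral import HemoStack, OpticalFrameStack, WavelengthBand

__all__ = [
    "save_stack",
    "load_stack",
    "save_hemo",
    "load_hemo",
    "save_trace_csv",
    "load_trace_csv",
    "save_mask_png",
    "load_mask_png",
    "save_line_json",
    "load_line_json",
]


def _band_filename(band: WavelengthBand) -> str:
    return f"band_{band.center:g}nm.tif"


def save_stack(stack: OpticalFrameStack, out_dir, seed: "int | None" = None,
               ground_truth_path: "str | None" = None) -> Path:
    """Write one multi-page TIFF per band plus a ``stack.json`` sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for i, band in enumerate(stack.bands):
        name = _band_filename(band)
        tifffile.imwrite(out / name, stack.intensities[i].astype(np.float32))
        files.append(name)
    sidecar = {
        "frame_rate_hz": stack.frame_rate,
        "bands": [[b.center, b.half_bandwidth] for b in stack.bands],
        "files": files,
        "seed": seed,
        "ground_truth": ground_truth_path,
    }
    (out / "stack.json").write_text(json.dumps(sidecar, indent=2))
    return out


def load_stack(in_dir) -> OpticalFrameStack:
    src = Path(in_dir)
    meta = json.loads((src / "stack.json").read_text())
    bands = tuple(WavelengthBand(c, hw) for c, hw in meta["bands"])
    planes = [tifffile.imread(src / f).astype(float) for f in meta["files"]]
    return OpticalFrameStack(
        intensities=np.stack(planes), frame_rate=meta["frame_rate_hz"], bands=bands
    )


def save_hemo(hemo: HemoStack, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "hbo.tif", hemo.hbo.astype(np.float32))
    tifffile.imwrite(out / "hbr.tif", hemo.hbr.astype(np.float32))
    tifffile.imwrite(out / "hbt.tif", hemo.hbt.astype(np.float32))
    sidecar = {"frame_rate_hz": hemo.frame_rate, "units": "uM", "provenance": hemo.provenance}
    (out / "hemo.json").write_text(json.dumps(sidecar, indent=2))
    return out


def load_hemo(in_dir) -> HemoStack:
    src = Path(in_dir)
    meta = json.loads((src / "hemo.json").read_text())
    return HemoStack(
        hbo=tifffile.imread(src / "hbo.tif").astype(float),
        hbr=tifffile.imread(src / "hbr.tif").astype(float),
        frame_rate=meta["frame_rate_hz"],
        provenance=meta.get("provenance", {}),
    )


def save_trace_csv(path, values: np.ndarray, rate: float, value_col: str = "value") -> Path:
    """Write a sampled trace as CSV with ``time_s`` and a value column."""
    path = Path(path)
    t = np.arange(len(values)) / rate
    pd.DataFrame({"time_s": t, value_col: np.asarray(values)}).to_csv(path, index=False)
    return path


def load_trace_csv(path, value_col: "str | None" = None) -> tuple[np.ndarray, float]:
    """Read a trace CSV back; returns (values, rate inferred from time_s)."""
    df = pd.read_csv(path)
    if value_col is None:
        value_col = [c for c in df.columns if c != "time_s"][0]
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("trace needs at least two samples to infer the rate")
    rate = 1.0 / np.median(np.diff(t))
    return df[value_col].to_numpy(float), float(round(rate, 6))


def save_mask_png(mask: RoiMask, path, params: "dict | None" = None) -> Path:
    path = Path(path)
    iio.imwrite(path, (mask.mask.astype(np.uint8) * 255))
    sidecar = {"label": mask.label, "origin": mask.origin, "params": params or {}}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_mask_png(path) -> RoiMask:
    path = Path(path)
    raster = np.asarray(iio.imread(path))
    if raster.ndim == 3:
        raster = raster[..., 0]
    meta = json.loads(path.with_suffix(".json").read_text())
    return RoiMask(mask=raster > 127, label=meta["label"], origin=meta["origin"])


def save_line_json(path, start: tuple[float, float], end: tuple[float, float]) -> Path:
    path = Path(path)
    path.write_text(json.dumps({"start": list(start), "end": list(end)}))
    return path


def load_line_json(path) -> tuple[tuple[float, float], tuple[float, float]]:
    meta = json.loads(Path(path).read_text())
    return tuple(meta["start"]), tuple(meta["end"])
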