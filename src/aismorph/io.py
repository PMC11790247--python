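"""File formats: multi-page TIFF + sidecar JSON, ROI CSV, ephys CSV,
manifest JSON, tidy measurement CSV.

Conventions:

* images are multi-page TIFFs with one channel per page; physical metadata
  lives in a sidecar ``<stem>.json`` with ``pixel_size_um`` and
  ``channel_labels``;
* ROIs are CSVs with columns ``x_px,y_px`` ordered from the somatic end;
* ephys sweeps are one CSV per sweep (``time_ms,voltage_mV``) plus a
  protocol JSON; floats in tidy outputs are written with 6 significant
  digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .ephys_features import Sweep, SweepSet
from .straighten import ImageStack, PolylineROI

FLOAT_FORMAT = "%.6g"


def save_image_stack(path, stack: ImageStack) -> Path:
    path = Path(path)
    tifffile.imwrite(path, stack.pixels.astype(np.float32))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "pixel_size_um": stack.pixel_size,
        "channel_labels": stack.channel_labels,
    }, indent=2))
    return path


def load_image_stack(path) -> ImageStack:
    path = Path(path)
    pixels = tifffile.imread(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar metadata {sidecar}")
    meta = json.loads(sidecar.read_text())
    return ImageStack(np.asarray(pixels, dtype=float), meta["pixel_size_um"],
                      list(meta["channel_labels"]))


def save_roi(path, roi: PolylineROI) -> Path:
    path = Path(path)
    pd.DataFrame(roi.vertices, columns=["x_px", "y_px"]).to_csv(
        path, index=False, float_format=FLOAT_FORMAT)
    return path


def load_roi(path) -> PolylineROI:
    df = pd.read_csv(path)
    return PolylineROI(df[["x_px", "y_px"]].to_numpy(dtype=float))


def save_manifest(path, manifest) -> Path:
    path = Path(path)
    path.write_text(json.dumps(manifest.to_jsonable(), indent=2))
    return path


def save_measurements(path, df: pd.DataFrame) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def save_sweeps(directory, sweeps: SweepSet, stem: str = "sweep") -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(sweeps.sweeps):
        pd.DataFrame({"time_ms": s.time_ms, "voltage_mV": s.voltage_mv}
                     ).to_csv(directory / f"{stem}_{i:03d}.csv", index=False,
                              float_format=FLOAT_FORMAT)
    (directory / "protocol.json").write_text(json.dumps({
        "currents_pa": [s.current_pa for s in sweeps.sweeps],
        "step_onset_ms": sweeps.step_onset_ms,
        "step_duration_ms": sweeps.step_duration_ms,
        "sample_rate_khz": sweeps.sample_rate_khz,
    }, indent=2))
    return directory


def load_sweeps(directory, stem: str = "sweep") -> SweepSet:
    directory = Path(directory)
    meta = json.loads((directory / "protocol.json").read_text())
    sweeps = []
    for i, current in enumerate(meta["currents_pa"]):
        df = pd.read_csv(directory / f"{stem}_{i:03d}.csv")
        sweeps.append(Sweep(float(current), df["time_ms"].to_numpy(),
                            df["voltage_mV"].to_numpy()))
    return SweepSet(sweeps, meta["step_onset_ms"], meta["step_duration_ms"],
                    meta["sample_rate_khz"])
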