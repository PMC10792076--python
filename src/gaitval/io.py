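"""File formats: TRC marker files, CSV dialects, ground-truth JSON, YAML.

The simulator writes (and the pipelines read back):

* ``.trc`` — tab-separated marker trajectories with the conventional header
  (DataRate / NumFrames / Units), metres, for the 3D stream;
* 2D pixel CSV — ``frame,time,<name>_x,<name>_y`` columns per camera;
* GRF CSV — ``time,Fz1,Fz2`` at the force-plate rate;
* ground-truth JSON sidecar — events, parameters and normalized curves;
* YAML — cohort / camera / study configuration files.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
import pandas as pd
import yaml

from .errors import DataError
from .synthetic import TrialRecording

__all__ = ["write_trc", "read_trc", "write_pixels_csv", "read_pixels_csv",
           "write_grf_csv", "read_grf_csv", "write_ground_truth_json",
           "read_ground_truth_json", "write_trial", "load_yaml_config",
           "dump_yaml_config"]


# ---------------------------------------------------------------------------
# TRC


def write_trc(path, markers: dict, fs: float, units: str = "m") -> None:
    """Write marker trajectories in the TRC dialect (tab-separated)."""
    names = list(markers)
    if not names:
        raise DataError("no markers to write")
    n = markers[names[0]].shape[0]
    path = pathlib.Path(path)
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
        fh.write(f"{fs:g}\t{fs:g}\t{n}\t{len(names)}\t{units}\t{fs:g}\t1\t{n}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t\t\n")
        fh.write("\t\t" + "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}"
                                    for i in range(len(names))) + "\n")
        for i in range(n):
            row = [str(i + 1), f"{i / fs:.6f}"]
            for name in names:
                row.extend(f"{v:.6f}" for v in markers[name][i])
            fh.write("\t".join(row) + "\n")


def read_trc(path) -> tuple[dict, float]:
    """Read a TRC file back into (markers, sampling rate)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6:
        raise DataError("truncated TRC file")
    meta = lines[2].split("\t")
    fs = float(meta[0])
    n_markers = int(meta[3])
    names = [s for s in lines[3].split("\t")[2:] if s][:n_markers]
    data = []
    for line in lines[5:]:
        if not line.strip():
            continue
        data.append([float(v) for v in line.split("\t")[2:]])
    arr = np.asarray(data)
    if arr.shape[1] != 3 * len(names):
        raise DataError("TRC column count does not match the marker list")
    markers = {name: arr[:, 3 * i:3 * i + 3] for i, name in enumerate(names)}
    return markers, fs


# ---------------------------------------------------------------------------
# CSV dialects


def write_pixels_csv(path, pixels: dict, fs: float) -> None:
    names = list(pixels)
    if not names:
        raise DataError("no pixel trajectories to write")
    n = pixels[names[0]].shape[0]
    cols = {"frame": np.arange(n), "time": np.arange(n) / fs}
    for name in names:
        cols[f"{name}_x"] = pixels[name][:, 0]
        cols[f"{name}_y"] = pixels[name][:, 1]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.4f")


def read_pixels_csv(path) -> tuple[dict, float]:
    df = pd.read_csv(path)
    if "time" not in df or len(df) < 2:
        raise DataError("pixel CSV needs a time column and at least 2 frames")
    fs = 1.0 / float(df["time"].iloc[1] - df["time"].iloc[0])
    out = {}
    for col in df.columns:
        if col.endswith("_x"):
            name = col[:-2]
            out[name] = np.column_stack([df[f"{name}_x"], df[f"{name}_y"]])
    return out, fs


def write_grf_csv(path, grf: dict, fs: float) -> None:
    plates = list(grf)
    if not plates:
        raise DataError("no force signals to write")
    n = grf[plates[0]].shape[0]
    cols = {"time": np.arange(n) / fs}
    cols.update({p: grf[p] for p in plates})
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.4f")


def read_grf_csv(path) -> tuple[dict, float]:
    df = pd.read_csv(path)
    if "time" not in df or len(df) < 2:
        raise DataError("GRF CSV needs a time column and at least 2 samples")
    fs = 1.0 / float(df["time"].iloc[1] - df["time"].iloc[0])
    return {c: df[c].to_numpy() for c in df.columns if c != "time"}, fs


# ---------------------------------------------------------------------------
# ground truth JSON


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_ground_truth_json(path, ground_truth: dict) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(ground_truth), fh, indent=1)


def read_ground_truth_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_trial(out_dir, trial: TrialRecording, stem: str = "trial") -> dict:
    """Write one trial's streams to a directory; returns the paths used."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["trc"] = out / f"{stem}_markers3d.trc"
    write_trc(paths["trc"], trial.markers_3d, trial.fs_3d)
    if trial.grf_vertical:
        paths["grf"] = out / f"{stem}_grf.csv"
        write_grf_csv(paths["grf"], trial.grf_vertical, trial.fs_grf)
    for cam_side, pix in trial.pixels_2d.items():
        key = f"pixels_{cam_side}"
        paths[key] = out / f"{stem}_{key}.csv"
        write_pixels_csv(paths[key], pix, trial.fs_2d)
    if trial.ground_truth is not None:
        paths["truth"] = out / f"{stem}_truth.json"
        write_ground_truth_json(paths["truth"], trial.ground_truth)
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# YAML configs


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise DataError("configuration file must contain a mapping")
    return data


def dump_yaml_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_jsonable(config), fh, sort_keys=True)
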