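"""File formats and analysis configuration.

Trajectories travel as tabular text (columns ``t_s, x_m[, y_m, z_m]``, with
metadata in ``#``-prefixed JSON header lines) or as HDF5 (bit-exact round
trip). Image stacks are multi-page TIFF with acquisition metadata
(frame_rate, pixel_size) taken from a JSON sidecar when absent from the
tags — a missing frame rate is an error, never guessed.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .core import InvalidArgumentError, ProbeContext, Trajectory

__all__ = [
    "AnalysisConfig", "read_trajectory", "write_trajectory",
    "read_image_stack", "write_image_stack", "ImageStack",
]

_META_PREFIX = "# microrheo-meta: "


@dataclass
class AnalysisConfig:
    """Everything an analysis needs to be re-run: probe, conventions, grids.

    Serialises losslessly to JSON; every pipeline output embeds the config
    it was produced with.
    """

    radius_a: float = 3e-6
    temperature_T: float = 298.15
    solvent_viscosity_eta_s: float = 0.89e-3
    convention: str = "paper"
    detrend_model: str = "linear"
    amplitude_threshold: float = 2e-10
    lag_points_per_decade: int = 16
    freq_points_per_decade: int = 10
    window_fraction: float = 0.1
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def context(self) -> ProbeContext:
        return ProbeContext(self.radius_a, self.temperature_T,
                            self.solvent_viscosity_eta_s)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisConfig":
        return cls(**json.loads(text))

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        return cls.from_json(Path(path).read_text())


def _traj_metadata(traj: Trajectory) -> dict:
    return {
        "frame_rate": traj.frame_rate,
        "axes": list(traj.axes),
        "radius_a": traj.context.radius_a,
        "temperature_T": traj.context.temperature_T,
        "solvent_viscosity_eta_s": traj.context.solvent_viscosity_eta_s,
        "dropped_frames": ([] if traj.dropped_frames is None
                           else np.asarray(traj.dropped_frames).tolist()),
    }


def write_trajectory(traj: Trajectory, path) -> Path:
    """Write a trajectory as CSV (suffix .csv/.txt/.tsv) or HDF5 (.h5/.hdf5)."""
    path = Path(path)
    meta = _traj_metadata(traj)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("t_s", data=traj.t)
            f.create_dataset("positions_m", data=traj.positions)
            f.attrs["meta"] = json.dumps(meta)
            f.attrs["provenance"] = json.dumps(traj.provenance, default=repr)
    elif path.suffix in (".csv", ".txt", ".tsv"):
        sep = "\t" if path.suffix == ".tsv" else ","
        cols = ["t_s"] + [f"{a}_m" for a in traj.axes]
        with path.open("w") as f:
            f.write(_META_PREFIX + json.dumps(meta) + "\n")
            f.write(sep.join(cols) + "\n")
            for i in range(traj.n_samples):
                row = [repr(float(traj.t[i]))] + \
                      [repr(float(v)) for v in traj.positions[i]]
                f.write(sep.join(row) + "\n")
    else:
        raise InvalidArgumentError(f"unsupported trajectory format {path.suffix!r}")
    return path


def read_trajectory(path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`.

    Validates units and a uniform, strictly increasing time base. Plain CSV
    files without the metadata header are accepted only when they carry the
    standard ``t_s, x_m[, y_m, z_m]`` columns (SI units implied by the
    names); files with pixel-unit columns and no declared pixel size are
    rejected.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            t = f["t_s"][:]
            pos = f["positions_m"][:]
            meta = json.loads(f.attrs["meta"])
    else:
        text = path.read_text().splitlines()
        meta = None
        if text and text[0].startswith(_META_PREFIX):
            meta = json.loads(text[0][len(_META_PREFIX):])
            text = text[1:]
        sep = "\t" if path.suffix == ".tsv" else ","
        header = [c.strip() for c in text[0].split(sep)]
        if header[0] != "t_s":
            raise InvalidArgumentError(
                f"first column must be 't_s' (seconds), got {header[0]!r}")
        for c in header[1:]:
            if not c.endswith("_m"):
                raise InvalidArgumentError(
                    f"column {c!r} does not declare metres ('_m'); if this is "
                    f"a legacy pixel-unit file, convert it with an explicit "
                    f"pixel size first")
        data = np.array([[float(v) for v in line.split(sep)]
                         for line in text[1:] if line.strip()])
        t, pos = data[:, 0], data[:, 1:]
        if meta is None:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise InvalidArgumentError("time column is not strictly increasing")
            meta = {"frame_rate": 1.0 / float(np.mean(dt)),
                    "axes": [c[:-2] for c in header[1:]],
                    "radius_a": 3e-6, "temperature_T": 298.15,
                    "solvent_viscosity_eta_s": 0.89e-3, "dropped_frames": []}
    ctx = ProbeContext(meta["radius_a"], meta["temperature_T"],
                       meta["solvent_viscosity_eta_s"])
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise InvalidArgumentError("time column is not strictly increasing")
    dropped = np.array(meta.get("dropped_frames", []), dtype=int)
    return Trajectory(t=t, positions=pos, frame_rate=meta["frame_rate"],
                      context=ctx, axes=tuple(meta["axes"]),
                      provenance={"source": str(path)},
                      dropped_frames=dropped if dropped.size else None)


@dataclass
class ImageStack:
    frames: np.ndarray
    frame_rate: float
    pixel_size: float
    metadata: dict = field(default_factory=dict)


def write_image_stack(frames: np.ndarray, path, frame_rate: float,
                      pixel_size: float, **extra_meta) -> Path:
    """Write a uint8/uint16 stack as multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    frames = np.asarray(frames)
    if frames.dtype not in (np.uint8, np.uint16):
        raise InvalidArgumentError("image stacks must be 8- or 16-bit unsigned")
    tifffile.imwrite(path, frames)
    sidecar = {"frame_rate": frame_rate, "pixel_size": pixel_size, **extra_meta}
    path.with_suffix(".json").write_text(json.dumps(sidecar))
    return path


def read_image_stack(path) -> ImageStack:
    """Read a multi-page TIFF with its acquisition metadata.

    Metadata comes from the JSON sidecar (same stem, ``.json``); a missing
    frame rate is an error. Truncated files raise an error naming the last
    readable frame; RGB input is rejected (single channel expected).
    """
    path = Path(path)
    try:
        frames = tifffile.imread(path)
    except Exception:
        # salvage page by page to report the last good frame
        good = []
        try:
            with tifffile.TiffFile(path) as tf:
                for page in tf.pages:
                    good.append(page.asarray())
        except Exception:
            pass
        raise InvalidArgumentError(
            f"could not read {path.name}: file truncated or corrupt after "
            f"frame {len(good) - 1}") from None
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise InvalidArgumentError(
            f"expected a single-channel stack, got shape {frames.shape} "
            f"(RGB/multi-channel input is not supported)")
    if frames.dtype not in (np.uint8, np.uint16):
        raise InvalidArgumentError(f"expected 8/16-bit frames, got {frames.dtype}")
    sidecar_path = path.with_suffix(".json")
    meta = {}
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
    if "frame_rate" not in meta:
        raise InvalidArgumentError(
            f"no frame_rate for {path.name}: provide a JSON sidecar "
            f"{sidecar_path.name} with at least {{'frame_rate': ...}} — "
            f"frame rates are never guessed")
    return ImageStack(frames=frames, frame_rate=float(meta["frame_rate"]),
                      pixel_size=float(meta.get("pixel_size", np.nan)),
                      metadata=meta)
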