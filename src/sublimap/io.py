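"""Readers and writers: TIFF volume stacks with YAML sidecars, pose
records, cylindrical volumes and CSV feature maps.

A volume series on disk is a directory of multi-page TIFF stacks (pages =
z slices) plus a ``series.yaml`` sidecar listing voxel spacing and one
timestamp per frame.  Cylindrical volumes are stored the same way (pages =
h slices) with the grid spec in the sidecar and the validity mask as a
second stack.  Feature maps go out both as 2D TIFF and long-format CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import CylindricalGridSpec, CylindricalVolume
from .pose import CircleDetection, VialPose
from .volume import CartesianVolume

__all__ = [
    "write_volume_series",
    "read_volume_series",
    "write_pose",
    "read_pose",
    "write_cylindrical",
    "read_cylindrical",
    "write_map_csv",
    "read_map_csv",
    "write_map_tiff",
]


def write_volume_series(directory: str | Path, volumes: list[CartesianVolume]) -> Path:
    """Write frames as ``frame_%04d.tif`` plus a ``series.yaml`` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = []
    for i, vol in enumerate(volumes):
        name = f"frame_{i:04d}.tif"
        tifffile.imwrite(directory / name, np.asarray(vol.data, dtype=np.float32), photometric="minisblack")
        frames.append({"file": name, "timestamp_s": float(vol.timestamp)})
    sidecar = {"spacing_um": float(volumes[0].spacing), "frames": frames}
    (directory / "series.yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))
    return directory / "series.yaml"


def read_volume_series(directory: str | Path) -> list[CartesianVolume]:
    """Read a volume series written by :func:`write_volume_series`.

    Frames must share one shape and spacing and carry strictly increasing
    timestamps; violations raise with the offending frame named (no silent
    sorting).
    """
    directory = Path(directory)
    sidecar = yaml.safe_load((directory / "series.yaml").read_text())
    spacing = float(sidecar["spacing_um"])
    volumes: list[CartesianVolume] = []
    prev_t = -np.inf
    shape = None
    for entry in sidecar["frames"]:
        if "timestamp_s" not in entry:
            raise ValueError(f"frame {entry.get('file')} is missing its timestamp")
        data = tifffile.imread(directory / entry["file"])
        if shape is None:
            shape = data.shape
        elif data.shape != shape:
            raise ValueError(
                f"frame {entry['file']} has shape {data.shape}, expected {shape}"
            )
        t = float(entry["timestamp_s"])
        if t <= prev_t:
            raise ValueError(f"frame {entry['file']} breaks timestamp ordering")
        prev_t = t
        volumes.append(CartesianVolume(data=data, spacing=spacing, timestamp=t))
    return volumes


def write_pose(path: str | Path, pose: VialPose) -> None:
    record = {
        "point_um": [float(v) for v in pose.point],
        "direction": [float(v) for v in pose.direction],
        "detections": [
            {
                "height_index": d.height_index,
                "center_um": [float(d.center[0]), float(d.center[1])],
                "radius_um": float(d.radius),
                "votes": int(d.votes),
            }
            for d in pose.detections
        ],
    }
    Path(path).write_text(json.dumps(record, indent=2))


def read_pose(path: str | Path) -> VialPose:
    record = json.loads(Path(path).read_text())
    detections = [
        CircleDetection(
            height_index=d["height_index"],
            center=tuple(d["center_um"]),
            radius=d["radius_um"],
            votes=d["votes"],
        )
        for d in record.get("detections", [])
    ]
    return VialPose(
        point=np.array(record["point_um"]),
        direction=np.array(record["direction"]),
        detections=detections,
    )


def write_cylindrical(directory: str | Path, cvol: CylindricalVolume, stem: str = "cyl") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / f"{stem}.tif", np.asarray(cvol.data, dtype=np.float32), photometric="minisblack")
    tifffile.imwrite(directory / f"{stem}_valid.tif", cvol.valid.astype(np.uint8), photometric="minisblack")
    meta = dataclasses.asdict(cvol.spec)
    meta.update(timestamp_s=float(cvol.timestamp), fill_value=float(cvol.fill_value))
    (directory / f"{stem}.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def read_cylindrical(directory: str | Path, stem: str = "cyl") -> CylindricalVolume:
    directory = Path(directory)
    meta = yaml.safe_load((directory / f"{stem}.yaml").read_text())
    timestamp = meta.pop("timestamp_s")
    fill = meta.pop("fill_value")
    meta["origin_um"] = tuple(meta["origin_um"])
    spec = CylindricalGridSpec(**meta)
    data = tifffile.imread(directory / f"{stem}.tif")
    valid = tifffile.imread(directory / f"{stem}_valid.tif").astype(bool)
    return CylindricalVolume(data=data, spec=spec, timestamp=timestamp, valid=valid, fill_value=fill)


def write_map_csv(path: str | Path, value_map: np.ndarray, value_name: str = "value") -> None:
    """2D (h, phi) map to long-format CSV with columns h, phi, value."""
    n_h, n_phi = value_map.shape
    hh, pp = np.meshgrid(np.arange(n_h), np.arange(n_phi), indexing="ij")
    df = pd.DataFrame({"h": hh.ravel(), "phi": pp.ravel(), value_name: np.asarray(value_map).ravel()})
    df.to_csv(path, index=False)


def read_map_csv(path: str | Path, value_name: str = "value") -> np.ndarray:
    df = pd.read_csv(path)
    n_h = int(df["h"].max()) + 1
    n_phi = int(df["phi"].max()) + 1
    out = np.full((n_h, n_phi), np.nan)
    out[df["h"].to_numpy(), df["phi"].to_numpy()] = df[value_name].to_numpy()
    return out


def write_map_tiff(path: str | Path, value_map: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(value_map, dtype=np.float32), photometric="minisblack")
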