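"""Plain-text readers and writers for the pipeline's data formats.

Traces and rasters travel as CSV with a ``#``-prefixed key=value header line
(rows = neurons, columns = frames); topologies as whitespace edge lists;
ventral-root pairs as two-column CSV with a sample-rate header; puncta as
coordinate CSVs and optional two-channel OME-TIFF renderings; reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .events import EventRaster, FluorescenceRecording
from .rhythm import VRTracePair

__all__ = [
    "save_traces",
    "load_traces",
    "save_raster",
    "load_raster",
    "save_topology",
    "load_topology",
    "save_vr_pair",
    "load_vr_pair",
    "save_spots",
    "load_spots",
    "save_scene_tiff",
    "load_scene_tiff",
    "save_json",
]


def _write_matrix(path: Path, matrix: np.ndarray, header: dict) -> None:
    items = " ".join(f"{k}={v}" for k, v in header.items() if v is not None)
    with open(path, "w") as fh:
        fh.write(f"# {items}\n")
        np.savetxt(fh, matrix, delimiter=",", fmt="%.10g")


def _read_matrix(path: Path) -> tuple[np.ndarray, dict]:
    with open(path) as fh:
        first = fh.readline()
        header = {}
        if first.startswith("#"):
            for item in first[1:].split():
                k, _, v = item.partition("=")
                header[k] = v
            matrix = np.loadtxt(fh, delimiter=",", ndmin=2)
        else:
            fh.seek(0)
            matrix = np.loadtxt(fh, delimiter=",", ndmin=2)
    return matrix, header


def save_traces(path: str | Path, recording: FluorescenceRecording) -> None:
    _write_matrix(
        Path(path),
        recording.values,
        {"dt_s": recording.dt_s, "cluster_id": recording.cluster_id},
    )


def load_traces(path: str | Path) -> FluorescenceRecording:
    matrix, header = _read_matrix(Path(path))
    return FluorescenceRecording(
        matrix,
        dt_s=float(header.get("dt_s", 0.1)),
        cluster_id=header.get("cluster_id"),
    )


def save_raster(path: str | Path, raster: EventRaster) -> None:
    _write_matrix(
        Path(path),
        raster.onsets,
        {"dt_s": raster.dt_s, "cluster_id": raster.cluster_id},
    )


def load_raster(path: str | Path) -> EventRaster:
    matrix, header = _read_matrix(Path(path))
    return EventRaster(
        matrix.astype(np.uint8),
        dt_s=float(header.get("dt_s", 0.1)),
        cluster_id=header.get("cluster_id"),
    )


def save_topology(path: str | Path, adjacency: np.ndarray) -> None:
    adjacency = np.asarray(adjacency)
    edges = np.argwhere(np.triu(adjacency, k=1) > 0)
    with open(path, "w") as fh:
        fh.write(f"# n_neurons={adjacency.shape[0]}\n")
        for i, j in edges:
            fh.write(f"{i} {j}\n")


def load_topology(path: str | Path) -> np.ndarray:
    with open(path) as fh:
        first = fh.readline()
        n = int(first.partition("=")[2]) if first.startswith("#") else None
        edges = [tuple(map(int, line.split())) for line in fh if line.strip()]
    if n is None:
        n = max(max(e) for e in edges) + 1 if edges else 0
    adjacency = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        adjacency[i, j] = adjacency[j, i] = 1
    return adjacency


def save_vr_pair(path: str | Path, pair: VRTracePair) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz={pair.sample_rate_hz}\n")
        fh.write("left,right\n")
        np.savetxt(
            fh, np.column_stack([pair.left, pair.right]), delimiter=",", fmt="%.8g"
        )


def load_vr_pair(path: str | Path) -> VRTracePair:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError("ventral-root CSV must begin with a sample-rate header")
        rate = float(first.partition("=")[2])
        data = pd.read_csv(fh)
    return VRTracePair(
        left=data["left"].to_numpy(),
        right=data["right"].to_numpy(),
        sample_rate_hz=rate,
    )


def save_spots(path: str | Path, table: pd.DataFrame) -> None:
    """Write a spot/coordinate table (columns include channel, x_um, y_um)."""
    table.to_csv(path, index=False)


def load_spots(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_scene_tiff(path: str | Path, stack: np.ndarray, pixel_size_um: float) -> None:
    """Write a (2, H, W) two-channel stack as OME-TIFF with pixel size metadata."""
    tifffile.imwrite(
        str(path),
        np.asarray(stack, dtype=np.float32),
        ome=True,
        metadata={
            "axes": "CYX",
            "PhysicalSizeX": pixel_size_um,
            "PhysicalSizeY": pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeYUnit": "µm",
        },
    )


def load_scene_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def save_json(path: str | Path, payload: dict) -> None:
    def default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serialisable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=default)
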