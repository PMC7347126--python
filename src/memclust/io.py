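"""Reading and writing image stacks and result tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imaging import (
    DensityTimeSeries,
    FrameStack,
    PowerLawFit,
    RegimeSegmentation,
    SizeDistribution,
    to_grayscale,
)

__all__ = [
    "read_stack",
    "write_stack",
    "cluster_table",
    "distribution_table",
    "density_table",
    "write_json",
]


def read_stack(
    path: str | Path, frame_interval: float, pixel_size: float
) -> FrameStack:
    """Load a multi-frame TIFF, or a directory of numbered PNG/TIFF frames.

    Frames are converted to grayscale; timestamps are ``k * frame_interval``.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise FileNotFoundError(f"no image frames found in {path}")
        import imageio.v3 as iio

        frames = [to_grayscale(np.asarray(iio.imread(p), dtype=float)) for p in files]
    else:
        data = np.asarray(tifffile.imread(path), dtype=float)
        if data.ndim == 2:
            data = data[None]
        frames = [to_grayscale(f) for f in data]
    frames = np.stack(frames)
    timestamps = np.arange(frames.shape[0]) * float(frame_interval)
    return FrameStack(frames=frames, timestamps=timestamps, pixel_size=pixel_size)


def write_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a stack as a multi-frame 32-bit TIFF."""
    tifffile.imwrite(Path(path), stack.frames.astype(np.float32))


def cluster_table(labeling, pixel_size: float, frame: int = 0) -> pd.DataFrame:
    """Per-cluster table: frame, label, size in px and um^2, centroid."""
    rows = []
    labels = labeling.labels
    for k, size in enumerate(labeling.sizes, start=1):
        ys, xs = np.nonzero(labels == k)
        rows.append(
            {
                "frame": frame,
                "label": k,
                "size_px": int(size),
                "size_um2": float(size) * pixel_size**2,
                "centroid_x": float(xs.mean()),
                "centroid_y": float(ys.mean()),
            }
        )
    return pd.DataFrame(rows)


def distribution_table(dist: SizeDistribution) -> pd.DataFrame:
    edges = np.asarray(dist.bin_edges)
    return pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "count": dist.counts,
            "density": dist.densities,
        }
    )


def density_table(series: DensityTimeSeries) -> pd.DataFrame:
    return pd.DataFrame({"time_s": series.timestamps, "density": series.density})


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (PowerLawFit, RegimeSegmentation)):
            return o.__dict__
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"cannot serialize {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
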