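"""File formats: multi-page TIFF movies with metadata, CSV tables, YAML configs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .imaging import DiameterTrace, MModeImage, MovieStack

__all__ = [
    "write_movie",
    "read_movie",
    "write_mmode_png",
    "write_trace_csv",
    "load_config",
    "save_config",
]


def write_movie(path, movie: MovieStack) -> None:
    """Write a movie as an ImageJ-style multi-page TIFF (one page per frame).

    Frame rate is stored as the frame interval, pixel size in the resolution
    tags (pixels per µm), so stacks open with correct scaling in ImageJ.
    """
    frames = np.ascontiguousarray(movie.frames, dtype=np.float32)
    tifffile.imwrite(
        str(path),
        frames,
        imagej=True,
        resolution=(1.0 / movie.pixel_size, 1.0 / movie.pixel_size),
        metadata={
            "axes": "TYX",
            "finterval": 1.0 / movie.frame_rate,
            "unit": "um",
            "fps": movie.frame_rate,
        },
    )


def read_movie(path) -> MovieStack:
    """Read a multi-page TIFF written by :func:`write_movie`."""
    with tifffile.TiffFile(str(path)) as tif:
        frames = tif.asarray()
        meta = tif.imagej_metadata or {}
        frame_rate = None
        if meta.get("fps"):
            frame_rate = float(meta["fps"])
        elif meta.get("finterval"):
            frame_rate = 1.0 / float(meta["finterval"])
        page = tif.pages[0]
        pixel_size = 1.0
        if "XResolution" in page.tags:
            num, den = page.tags["XResolution"].value
            if num:
                pixel_size = den / num
    if frames.ndim == 2:
        frames = frames[None]
    if frame_rate is None:
        raise ValueError(f"{path}: no frame-rate metadata found")
    return MovieStack(frames=frames.astype(np.float32), frame_rate=frame_rate,
                      pixel_size=pixel_size)


def write_mmode_png(path, mmode: MModeImage) -> None:
    """Save an M-mode image as a grayscale PNG (time runs top to bottom)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.imsave(str(path), mmode.rows, cmap="gray")


def write_trace_csv(path, trace: DiameterTrace) -> None:
    """Write a diameter trace as CSV: frame, time_s, diameter_um, flag."""
    import pandas as pd

    pd.DataFrame(
        {
            "frame": np.arange(len(trace.values)),
            "time_s": trace.times,
            "diameter_um": trace.values,
            "flag": trace.quality_flags,
        }
    ).to_csv(str(path), index=False)


def load_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def save_config(path, config: dict) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))
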