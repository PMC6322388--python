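"""Shared readers/writers: TIFF rasters, unit-annotated CSVs, run logs."""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .synth_fibers import FiberImage

__all__ = [
    "read_image",
    "write_image",
    "read_stack",
    "write_stack",
    "write_table",
    "read_table",
    "write_run_log",
]


def write_image(path: str | Path, image: FiberImage) -> None:
    """Write a single-page 32-bit float grayscale TIFF with pixel size tags."""
    res = 1.0 / image.pixel_size_um  # pixels per micron
    tifffile.imwrite(
        path,
        image.pixels.astype(np.float32),
        resolution=(res, res),
        metadata={"unit": "um", "pixel_size_um": image.pixel_size_um},
    )


def read_image(path: str | Path, pixel_size_um: float | None = None) -> FiberImage:
    """Read a grayscale TIFF; pixel size from metadata unless overridden."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray().astype(np.float64)
        if pixel_size_um is None:
            pixel_size_um = _pixel_size_from_tiff(tf)
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-page 2D image")
    return FiberImage(pixels=np.clip(data, 0.0, None),
                      pixel_size_um=pixel_size_um)


def _pixel_size_from_tiff(tf: "tifffile.TiffFile") -> float:
    meta = tf.shaped_metadata or tf.imagej_metadata
    if meta:
        block = meta[0] if isinstance(meta, (list, tuple)) else meta
        if isinstance(block, dict) and "pixel_size_um" in block:
            return float(block["pixel_size_um"])
    page = tf.pages[0]
    xres = page.tags.get("XResolution")
    if xres is not None:
        num, den = xres.value
        if num:
            return den / num
    raise ValueError("TIFF carries no pixel-size metadata; pass pixel_size_um")


def write_stack(path: str | Path, frames: np.ndarray,
                pixel_size_um: float) -> None:
    """Write a (T, H, W) stack as a multi-page 32-bit float TIFF."""
    res = 1.0 / pixel_size_um
    tifffile.imwrite(
        path,
        frames.astype(np.float32),
        photometric="minisblack",
        resolution=(res, res),
        metadata={"unit": "um", "pixel_size_um": pixel_size_um, "axes": "TYX"},
    )


def read_stack(path: str | Path,
               pixel_size_um: float | None = None) -> tuple[np.ndarray, float]:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray().astype(np.float64)
        if pixel_size_um is None:
            pixel_size_um = _pixel_size_from_tiff(tf)
    if data.ndim == 2:
        data = data[None]
    return data, pixel_size_um


def write_table(path: str | Path, df: pd.DataFrame,
                units: dict[str, str] | None = None, index: bool = False) -> None:
    """Write a CSV; a `# units:` comment line documents column units."""
    path = Path(path)
    with open(path, "w") as fh:
        if units:
            fh.write("# units: " + ", ".join(f"{k}={v}" for k, v in units.items())
                     + "\n")
        df.to_csv(fh, index=index)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=index_col)


def write_run_log(out_dir: str | Path, subcommand: str, config: dict,
                  seed: int | None, warnings: list[str] | None = None) -> Path:
    """Emit the reproducibility log next to the outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    log = {
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "package_version": __version__,
        "subcommand": subcommand,
        "config": config,
        "config_hash": hashlib.sha256(blob).hexdigest()[:16],
        "seed": seed,
        "warnings": warnings or [],
    }
    path = out_dir / "run_log.json"
    with open(path, "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return path
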