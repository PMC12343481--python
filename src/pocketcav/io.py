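"""File I/O: TIFF stacks, micrographs, CSV tables and YAML configuration.

Intensities are normalized to [0, 1] on load regardless of the 8/16-bit
source and written back as 8-bit grayscale.
"""

from __future__ import annotations

import glob
import os
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .detection import DetectionParams, FrameSequence, SegmentationResult
from .phantoms import PhantomConfig

__all__ = [
    "read_stack",
    "write_stack",
    "read_image",
    "write_image",
    "read_frame_sequence",
    "write_mask_stack",
    "areas_table",
    "write_areas_csv",
    "load_config",
    "save_config",
]


def _normalize(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        return data.astype(np.float64) / np.iinfo(data.dtype).max
    return np.clip(data.astype(np.float64), 0.0, 1.0)


def _to_uint8(data: np.ndarray) -> np.ndarray:
    return (np.clip(np.asarray(data, dtype=np.float64), 0.0, 1.0) * 255).round().astype(np.uint8)


def read_stack(path: str | os.PathLike | list[str]) -> np.ndarray:
    """Read a multi-page TIFF stack, or a glob/list of single-frame files.

    Returns a float (n, h, w) array in [0, 1].
    """
    if isinstance(path, (list, tuple)):
        frames = [read_image(p) for p in path]
        return np.stack(frames)
    path = str(path)
    if any(ch in path for ch in "*?["):
        files = sorted(glob.glob(path))
        if not files:
            raise FileNotFoundError(f"no frames match {path!r}")
        return np.stack([read_image(p) for p in files])
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return _normalize(data)


def write_stack(path: str | os.PathLike, frames: np.ndarray) -> None:
    """Write frames as an 8-bit multi-page grayscale TIFF (one page/frame)."""
    tifffile.imwrite(str(path), _to_uint8(frames), photometric="minisblack")


def write_mask_stack(path: str | os.PathLike, masks: np.ndarray) -> None:
    """Write binary masks as an 8-bit TIFF stack (foreground = 255)."""
    tifffile.imwrite(
        str(path),
        (np.asarray(masks, dtype=bool) * np.uint8(255)),
        photometric="minisblack",
    )


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a single grayscale TIFF/PNG image as float in [0, 1]."""
    path = str(path)
    data = tifffile.imread(path) if path.lower().endswith((".tif", ".tiff")) else iio.imread(path)
    if data.ndim == 3:  # collapse accidental RGB
        data = data.mean(axis=-1)
    return _normalize(data)


def write_image(path: str | os.PathLike, image: np.ndarray) -> None:
    """Write a single grayscale image (8-bit TIFF or PNG by extension)."""
    path = str(path)
    data = _to_uint8(image)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, data, photometric="minisblack")
    else:
        iio.imwrite(path, data)


def read_frame_sequence(
    path: str | os.PathLike,
    frame_interval_us: float,
    pixel_size_um: float,
    t0_index: int = 0,
) -> FrameSequence:
    """Load a TIFF stack (or frame glob) as a calibrated FrameSequence."""
    return FrameSequence(
        frames=read_stack(path),
        frame_interval_us=frame_interval_us,
        pixel_size_um=pixel_size_um,
        t0_index=t0_index,
    )


def areas_table(result: SegmentationResult) -> pd.DataFrame:
    """Per-frame area table: frame_index, time_us, A_PB_mm2, A_SC_mm2."""
    return pd.DataFrame(
        {
            "frame_index": np.arange(len(result.times_us)),
            "time_us": result.times_us,
            "A_PB_mm2": result.a_pb_mm2,
            "A_SC_mm2": result.a_sc_mm2,
        }
    )


def write_areas_csv(path: str | os.PathLike, result: SegmentationResult) -> None:
    areas_table(result).to_csv(path, index=False)


def load_config(path: str | os.PathLike) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("configuration file must contain a mapping")
    return data


def save_config(path: str | os.PathLike, config: object) -> None:
    """Serialize a config dataclass (or dict) to YAML.

    Written and re-read configurations round-trip identically.
    """
    data = config if isinstance(config, dict) else asdict(config)  # type: ignore[arg-type]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def detection_params_from_config(config: dict) -> DetectionParams:
    fields = DetectionParams.__dataclass_fields__
    return DetectionParams(**{k: v for k, v in config.items() if k in fields})


def phantom_config_from_config(config: dict) -> PhantomConfig:
    fields = PhantomConfig.__dataclass_fields__
    return PhantomConfig(**{k: v for k, v in config.items() if k in fields})
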