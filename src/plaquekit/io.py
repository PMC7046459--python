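"""TIFF / sidecar / table input-output.

Images travel as single- or multi-page TIFF with a JSON sidecar
(``<image>.json`` next to the file) carrying the physical pixel size and
channel names; an explicit pixel size passed by the caller wins over the
sidecar, with a logged mismatch.  Expression matrices are genes × samples
TSV with a header row of sample ids; gene sets are GMT.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .grids import ImageGrid, ZStack

logger = logging.getLogger(__name__)

__all__ = [
    "read_pixel_size",
    "read_image",
    "read_multichannel",
    "read_stack",
    "write_image",
    "write_multichannel",
    "write_stack",
    "write_mask",
    "write_labels",
    "read_expression",
    "write_expression",
    "read_groups",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_pixel_size(path, pixel_size_um: float | None = None) -> tuple[float, dict]:
    """Resolve pixel size for an image from flag or sidecar (flag wins)."""
    path = Path(path)
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if pixel_size_um is not None:
        side = meta.get("pixel_size_um")
        if side is not None and not np.isclose(side, pixel_size_um):
            logger.warning(
                "pixel size flag %s um overrides sidecar %s um for %s",
                pixel_size_um,
                side,
                path.name,
            )
        return float(pixel_size_um), meta
    if "pixel_size_um" in meta:
        return float(meta["pixel_size_um"]), meta
    raise ValueError(f"no pixel size for {path}: supply a flag or a JSON sidecar")


def read_image(path, pixel_size_um: float | None = None, channel: str | None = None) -> ImageGrid:
    px, _ = read_pixel_size(path, pixel_size_um)
    data = tifffile.imread(path)
    if data.ndim == 3 and data.shape[0] == 1:
        data = data[0]
    if data.ndim != 2:
        raise ValueError(f"{path} is not a single 2D image (shape {data.shape})")
    return ImageGrid(data, px, channel=channel)


def read_multichannel(path, pixel_size_um: float | None = None) -> dict[str, ImageGrid]:
    """Read a multi-page TIFF whose sidecar names the channels."""
    px, meta = read_pixel_size(path, pixel_size_um)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    names = meta.get("channels") or [f"ch{i}" for i in range(data.shape[0])]
    if len(names) != data.shape[0]:
        raise ValueError(f"{path}: {data.shape[0]} pages but {len(names)} channel names")
    return {n: ImageGrid(data[i], px, channel=n) for i, n in enumerate(names)}


def read_stack(
    path, pixel_size_um: float | None = None, slice_spacing_um: float | None = None
) -> ZStack:
    px, meta = read_pixel_size(path, pixel_size_um)
    spacing = slice_spacing_um or meta.get("slice_spacing_um", 1.0)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return ZStack(data, px, slice_spacing_um=float(spacing), channel=meta.get("channel"))


def _write_sidecar(path: Path, pixel_size_um: float, **extra) -> None:
    meta = {"pixel_size_um": pixel_size_um, **extra}
    _sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n")


def write_image(img: ImageGrid, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(img.data, dtype=np.float32), photometric="minisblack")
    _write_sidecar(path, img.pixel_size_um, channel=img.channel)


def write_multichannel(channels: dict[str, ImageGrid], path) -> None:
    path = Path(path)
    names = list(channels)
    stack = np.stack([np.asarray(channels[n].data, dtype=np.float32) for n in names])
    tifffile.imwrite(path, stack, photometric="minisblack")
    _write_sidecar(path, channels[names[0]].pixel_size_um, channels=names)


def write_stack(stack: ZStack, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.data, dtype=np.float32), photometric="minisblack")
    _write_sidecar(
        path, stack.pixel_size_um, slice_spacing_um=stack.slice_spacing_um, channel=stack.channel
    )


def write_mask(mask, path) -> None:
    """Write a boolean mask as 8-bit TIFF (255 = positive)."""
    path = Path(path)
    tifffile.imwrite(path, (np.asarray(mask.data, dtype=np.uint8) * 255), photometric="minisblack")
    _write_sidecar(path, mask.pixel_size_um)


def write_labels(labels, path) -> None:
    """Write a label map as 16-bit TIFF."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(labels.data, dtype=np.uint16), photometric="minisblack")
    _write_sidecar(path, labels.pixel_size_um)


def read_expression(path) -> pd.DataFrame:
    """Genes × samples TSV with gene ids in the first column."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index.name = "gene"
    return matrix


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_groups(path) -> pd.Series:
    """Two-column sample → group file (TSV, with or without header)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if str(df.iloc[0, 0]).lower() in ("sample", "sample_id"):
        df = df.iloc[1:]
    return pd.Series(
        df.iloc[:, 1].astype(str).values,
        index=pd.Index(df.iloc[:, 0].astype(str).values, name="sample"),
    )
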