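"""Segmentation primitives for stained-section morphometry.

Implements the whole-slide quantification building blocks: white top-hat
background suppression followed by a local mean threshold, morphological
cleanup, connected components with physical size exclusion, shape-feature
filtering of elongated objects, RGB/HSV colour-classifier segmentation for
brightfield silver/IHC stains, Iba1-based tissue masking, z-projections,
pooled percentile thresholds, and threshold-based 3D plaque density.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure, morphology
from skimage.color import rgb2hsv

from .grids import BinaryMask, ImageGrid, LabelMap, ZStack

logger = logging.getLogger(__name__)

__all__ = [
    "ShapeLimits",
    "ColorRange",
    "ColorClassifier",
    "object_table",
    "segment_fluorescence",
    "filter_by_shape",
    "color_classify",
    "tissue_mask",
    "max_projection",
    "control_background_threshold",
    "percentile_threshold_mask",
    "apply_mask_cleanup",
    "plaque_density_3d",
]

#: Columns of the per-object feature table, in output order.
OBJECT_COLUMNS = [
    "label",
    "area_um2",
    "centroid_row_um",
    "centroid_col_um",
    "perimeter_um",
    "shape_factor",
    "roundness",
    "solidity",
]


@dataclass(frozen=True)
class ShapeLimits:
    """Lower bounds on shape features used to eliminate elongated objects.

    All three features live in (0, 1] for convex blobs (up to rasterization
    slack): ``shape_factor`` = 4πA/P² (circularity), ``roundness`` =
    4A/(π·major_axis²), ``solidity`` = A / convex-hull area.  A bound left as
    ``None`` is not applied.
    """

    shape_factor: float | None = None
    roundness: float | None = None
    solidity: float | None = None

    def __post_init__(self) -> None:
        for name in ("shape_factor", "roundness", "solidity"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} bound must lie in [0, 1], got {v}")

    @property
    def any(self) -> bool:
        return any(v is not None for v in (self.shape_factor, self.roundness, self.solidity))


#: Default bounds applied to the Lamp1 and methoxy-X04 channels.
DEFAULT_SHAPE_LIMITS = ShapeLimits(solidity=0.5, roundness=0.2)


def _disk(radius_px: int) -> np.ndarray:
    return morphology.disk(max(int(radius_px), 1))


def object_table(labels: LabelMap) -> pd.DataFrame:
    """Compute per-object physical areas and shape features.

    Returns a DataFrame with :data:`OBJECT_COLUMNS`; empty label maps give an
    empty (but well-typed) table.
    """
    px = labels.pixel_size_um
    rows = []
    for rp in measure.regionprops(labels.data):
        area_px = rp.area
        perim_px = rp.perimeter
        major = rp.axis_major_length
        shape_factor = 4 * math.pi * area_px / perim_px**2 if perim_px > 0 else 1.0
        roundness = 4 * area_px / (math.pi * major**2) if major > 0 else 1.0
        rows.append(
            {
                "label": rp.label,
                "area_um2": area_px * px**2,
                "centroid_row_um": rp.centroid[0] * px,
                "centroid_col_um": rp.centroid[1] * px,
                "perimeter_um": perim_px * px,
                "shape_factor": shape_factor,
                "roundness": roundness,
                "solidity": rp.solidity,
            }
        )
    return pd.DataFrame(rows, columns=OBJECT_COLUMNS)


def _relabel(mask_or_labels: np.ndarray, keep: set[int], pixel_size_um: float) -> LabelMap:
    """Zero out labels not in ``keep`` and relabel contiguously, preserving order."""
    out = np.zeros_like(mask_or_labels, dtype=np.int32)
    for new, old in enumerate(sorted(keep), start=1):
        out[mask_or_labels == old] = new
    lm = LabelMap(out, pixel_size_um)
    return _flag_border(lm)


def _flag_border(labels: LabelMap) -> LabelMap:
    edge = np.concatenate(
        [labels.data[0, :], labels.data[-1, :], labels.data[:, 0], labels.data[:, -1]]
    )
    touching = tuple(sorted(int(v) for v in np.unique(edge) if v > 0))
    return LabelMap(labels.data, labels.pixel_size_um, border_touching=touching)


def _remove_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Drop 8-connected components with fewer than ``min_px`` pixels."""
    if min_px <= 1 or not mask.any():
        return mask
    lab, n = ndi.label(mask, structure=np.ones((3, 3), dtype=bool))
    counts = np.bincount(lab.ravel())
    keep = counts >= min_px
    keep[0] = False
    return keep[lab]


def min_size_px(min_size_um2: float, pixel_size_um: float) -> int:
    """Pixel-count threshold for a physical minimum object size.

    Uses ``ceil`` so that an object strictly below the physical cutoff can
    never survive through favourable rounding.
    """
    return int(math.ceil(min_size_um2 / pixel_size_um**2))


def segment_fluorescence(
    img: ImageGrid,
    tophat_radius_um: float = 25.0,
    local_window_um: float = 75.0,
    local_offset: float = 0.0,
    min_size_um2: float = 34.0,
    shape_limits: ShapeLimits | None = None,
) -> tuple[LabelMap, pd.DataFrame]:
    """Segment bright fluorescent objects against slowly varying background.

    Pipeline: white top-hat with a disk structuring element of
    ``tophat_radius_um``; local mean threshold over ``local_window_um`` plus
    ``local_offset`` (a pixel is foreground where the top-hat response is
    strictly above its local mean plus the offset); binary opening then
    closing with a 1-pixel disk; 8-connected components; removal of objects
    below ``min_size_um2``; optional shape filtering.

    Returns the contiguous label map and its object table.
    """
    if tophat_radius_um <= 0 or local_window_um <= 0:
        raise ValueError("tophat_radius_um and local_window_um must be positive")
    if min_size_um2 < 0:
        raise ValueError("min_size_um2 must be >= 0")
    px = img.pixel_size_um
    window_px = int(round(local_window_um / px))
    if window_px < 3:
        raise ValueError(
            f"local window of {local_window_um} um is {window_px} px at "
            f"{px} um/px; must be at least 3 px"
        )
    if window_px % 2 == 0:
        window_px += 1
    data = np.asarray(img.data, dtype=np.float64)
    tophat = morphology.white_tophat(data, footprint=_disk(round(tophat_radius_um / px)))
    local_mean = ndi.uniform_filter(tophat, size=window_px, mode="reflect")
    binary = tophat > local_mean + local_offset
    binary = morphology.opening(binary, footprint=_disk(1))
    binary = morphology.closing(binary, footprint=_disk(1))
    return label_and_filter(
        BinaryMask(binary, px), min_size_um2=min_size_um2, shape_limits=shape_limits
    )


def label_and_filter(
    mask: BinaryMask,
    min_size_um2: float = 0.0,
    shape_limits: ShapeLimits | None = None,
) -> tuple[LabelMap, pd.DataFrame]:
    """8-connected components of a mask with size and shape exclusion."""
    lab, _ = ndi.label(mask.data, structure=np.ones((3, 3), dtype=bool))
    labels = LabelMap(lab, mask.pixel_size_um)
    if min_size_um2 > 0 and labels.n_objects:
        thr = min_size_px(min_size_um2, mask.pixel_size_um)
        counts = np.bincount(labels.data.ravel())
        keep = {int(i) for i in np.nonzero(counts >= thr)[0] if i > 0}
        labels = _relabel(labels.data, keep, mask.pixel_size_um)
    table = object_table(labels)
    if shape_limits is not None and shape_limits.any:
        labels, table = filter_by_shape(labels, table, shape_limits)
    return _flag_border(labels), table


def filter_by_shape(
    labels: LabelMap, table: pd.DataFrame, limits: ShapeLimits
) -> tuple[LabelMap, pd.DataFrame]:
    """Drop objects failing any provided shape lower bound; relabel contiguously."""
    if table.empty or not limits.any:
        return labels, table
    keep = pd.Series(True, index=table.index)
    for feat in ("shape_factor", "roundness", "solidity"):
        bound = getattr(limits, feat)
        if bound is not None:
            keep &= table[feat] >= bound
    kept_labels = set(table.loc[keep, "label"].astype(int))
    new_labels = _relabel(labels.data, kept_labels, labels.pixel_size_um)
    return new_labels, object_table(new_labels)


@dataclass(frozen=True)
class ColorRange:
    """An inclusive box in RGB or HSV space.

    ``space`` is ``"rgb"`` (channels in the image's own intensity units) or
    ``"hsv"`` with H in [0, 360) degrees and S, V in [0, 1].  ``low`` and
    ``high`` are per-channel bounds; a channel bound of ``None`` is
    unconstrained.
    """

    space: str
    low: tuple[float | None, float | None, float | None]
    high: tuple[float | None, float | None, float | None]
    positive: bool = True

    def __post_init__(self) -> None:
        if self.space not in ("rgb", "hsv"):
            raise ValueError(f"space must be 'rgb' or 'hsv', got {self.space!r}")
        for lo, hi in zip(self.low, self.high):
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"inverted range: low {lo} > high {hi}")

    def contains(self, rgb: np.ndarray, hsv: np.ndarray) -> np.ndarray:
        arr = rgb if self.space == "rgb" else hsv
        inside = np.ones(arr.shape[:2], dtype=bool)
        for c, (lo, hi) in enumerate(zip(self.low, self.high)):
            if lo is not None:
                inside &= arr[..., c] >= lo
            if hi is not None:
                inside &= arr[..., c] <= hi
        return inside


@dataclass(frozen=True)
class ColorClassifier:
    """A set of positive and negative colour boxes for brightfield stains.

    A pixel is classified positive when it falls inside at least one positive
    range and inside no negative range — the scheme used to pick out black or
    amber plaque hues on Campbell-Switzer silver stains.
    """

    ranges: tuple[ColorRange, ...] = field(default=())

    def __post_init__(self) -> None:
        if not any(r.positive for r in self.ranges):
            raise ValueError("classifier needs at least one positive range")


def color_classify(
    red: ImageGrid,
    green: ImageGrid,
    blue: ImageGrid,
    classifier: ColorClassifier,
    min_size_um2: float = 0.0,
    cleanup: bool = False,
) -> BinaryMask:
    """Classify pixels of an RGB brightfield image by colour boxes.

    HSV is derived by the standard hexcone transform with hue scaled to
    degrees.  When ``cleanup`` is set, binary opening/closing with a 1-px
    disk and the physical size exclusion are applied to the raw class mask.
    """
    if not (red.shape == green.shape == blue.shape):
        raise ValueError("RGB channels must share shape")
    rgb = np.stack([red.data, green.data, blue.data], axis=-1).astype(np.float64)
    peak = rgb.max()
    hsv = rgb2hsv(rgb / peak if peak > 0 else rgb)
    hsv = hsv * np.array([360.0, 1.0, 1.0])  # hue in degrees
    pos = np.zeros(red.shape, dtype=bool)
    neg = np.zeros(red.shape, dtype=bool)
    for r in classifier.ranges:
        hit = r.contains(rgb, hsv)
        if r.positive:
            pos |= hit
        else:
            neg |= hit
    mask = pos & ~neg
    if cleanup:
        mask = morphology.opening(mask, footprint=_disk(1))
        mask = morphology.closing(mask, footprint=_disk(1))
    if min_size_um2 > 0:
        mask = _remove_small(mask, min_size_px(min_size_um2, red.pixel_size_um))
    return BinaryMask(mask, red.pixel_size_um)


def tissue_mask(
    iba1: ImageGrid, threshold: float | None = None, closing_radius_um: float = 10.0
) -> BinaryMask:
    """Detect total tissue area by thresholding the Iba1 channel.

    A global threshold (mean of the image when not supplied) is followed by
    binary closing and hole filling so the mask is a small set of solid
    regions.  Blank images yield an empty mask rather than an error.
    """
    data = np.asarray(iba1.data, dtype=np.float64)
    if threshold is None:
        threshold = float(data.mean())
    binary = data > threshold
    if binary.any():
        r = max(int(round(closing_radius_um / iba1.pixel_size_um)), 1)
        binary = morphology.closing(binary, footprint=_disk(r))
        binary = ndi.binary_fill_holes(binary)
    return BinaryMask(binary, iba1.pixel_size_um)


def max_projection(stack: ZStack) -> ImageGrid:
    """Per-pixel maximum intensity projection across slices."""
    return ImageGrid(stack.data.max(axis=0), stack.pixel_size_um, channel=stack.channel)


def control_background_threshold(
    controls: list[ImageGrid], percentile: float = 99.99
) -> float:
    """Background-exclusion threshold from stain-negative control images.

    Pools every pixel of every control image and returns the requested
    percentile (linear interpolation between order statistics) — by default
    the value exceeding 99.99% of all control intensities.
    """
    if not controls:
        raise ValueError("need at least one control image")
    pooled = np.concatenate([np.asarray(c.data, dtype=np.float64).ravel() for c in controls])
    if pooled.size == 0:
        raise ValueError("control pixel pool is empty")
    return float(np.percentile(pooled, percentile))


def apply_mask_cleanup(mask: np.ndarray, pixel_size_um: float, min_size_um2: float) -> BinaryMask:
    """Opening, closing (1-px disk) and physical size exclusion of a mask."""
    out = morphology.opening(mask, footprint=_disk(1))
    out = morphology.closing(out, footprint=_disk(1))
    if min_size_um2 > 0:
        out = _remove_small(out, min_size_px(min_size_um2, pixel_size_um))
    return BinaryMask(out, pixel_size_um)


def percentile_threshold_mask(
    images: list[ImageGrid],
    positive_masks: list[BinaryMask],
    percentile: float,
    min_size_um2: float = 9.0,
    cleanup: bool = True,
) -> tuple[list[BinaryMask], float]:
    """Re-threshold a batch of images at a pooled within-mask percentile.

    One global threshold is computed from the pixels inside the positive
    masks pooled across *all* images of the batch; each image is then
    re-thresholded (``>=``, restricted to its positive mask) at that value,
    followed by morphological cleanup and size exclusion.

    Returns the per-image masks and the threshold used.
    """
    if len(images) != len(positive_masks):
        raise ValueError("images and masks must pair up")
    if not 0.0 <= percentile <= 100.0:
        raise ValueError(f"percentile must lie in [0, 100], got {percentile}")
    pooled = np.concatenate(
        [
            np.asarray(img.data, dtype=np.float64)[m.data]
            for img, m in zip(images, positive_masks)
        ]
        or [np.empty(0)]
    )
    if pooled.size == 0:
        raise ValueError("pooled positive mask is empty; no positive pixels in batch")
    thr = float(np.percentile(pooled, percentile))
    out = []
    for img, m in zip(images, positive_masks):
        raw = (np.asarray(img.data, dtype=np.float64) >= thr) & m.data
        if cleanup:
            out.append(apply_mask_cleanup(raw, img.pixel_size_um, min_size_um2))
        else:
            out.append(BinaryMask(raw, img.pixel_size_um))
    return out, thr


def plaque_density_3d(
    volume: ZStack, threshold: float, min_voxels: int = 1
) -> tuple[int, float]:
    """Threshold-based plaque count per mm³ in a two-photon volume.

    Voxels above ``threshold`` are grouped by 26-connectivity; components
    with at least ``min_voxels`` voxels count as plaques.  Returns
    ``(count, count per mm³)``.
    """
    nz, ny, nx = volume.data.shape
    volume_mm3 = (
        nz * volume.slice_spacing_um * ny * volume.pixel_size_um * nx * volume.pixel_size_um
    ) / 1e9
    if volume_mm3 <= 0:
        raise ValueError("imaged volume is zero")
    binary = np.asarray(volume.data, dtype=np.float64) > threshold
    lab, n = ndi.label(binary, structure=np.ones((3, 3, 3), dtype=bool))
    if min_voxels > 1 and n:
        counts = np.bincount(lab.ravel())
        n = int(np.sum(counts[1:] >= min_voxels))
    return int(n), float(n) / volume_mm3
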