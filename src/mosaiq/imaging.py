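"""Channel handling and binary mask construction for colony images.

The downstream segregation and lineage scores are area-based: every
quantity is a pixel count on a cleaned boolean mask.  This module turns a
multi-channel fluorescence image (red = CRISPRi/mCherry population,
green = WT-GFP population, blue = nuclear stain or lineage marker) into
per-channel masks by thresholding, removing small objects, and filling
small interior holes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

#: canonical channel roles, in storage order
CHANNEL_ROLES = ("red", "green", "blue")

# 8-connectivity structuring element used for all component labelling
_STRUCT8 = np.ones((3, 3), dtype=bool)


class DegenerateChannelError(ValueError):
    """Raised when automatic thresholding is impossible (constant channel)."""


@dataclass
class ColonyImage:
    """A multi-channel 2-D colony image.

    Parameters
    ----------
    channels : ndarray, shape (n_channels, H, W)
        Non-negative intensities, one plane per channel.
    roles : mapping role -> plane index
        Must cover ``red``, ``green`` and ``blue``.
    um_per_pixel : float, optional
        Physical pixel size; purely metadata, never required.
    """

    channels: np.ndarray
    roles: Mapping[str, int] = field(
        default_factory=lambda: {"red": 0, "green": 1, "blue": 2}
    )
    um_per_pixel: float | None = None

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 3:
            raise ValueError("channels must be a (n_channels, H, W) array")
        if np.any(self.channels < 0):
            raise ValueError("intensities must be non-negative")
        for role in CHANNEL_ROLES:
            if role not in self.roles:
                raise ValueError(f"missing channel role assignment: {role!r}")
            if not 0 <= self.roles[role] < self.channels.shape[0]:
                raise ValueError(f"role {role!r} points at a missing plane")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    def plane(self, role: str) -> np.ndarray:
        return self.channels[self.roles[role]]


@dataclass
class BinaryMask:
    """A cleaned boolean pixel set for one channel, with provenance."""

    grid: np.ndarray
    source_channel: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")

    @property
    def area(self) -> int:
        """Number of true pixels."""
        return int(self.grid.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


def split_channels(image: ColonyImage) -> dict[str, np.ndarray]:
    """Return one intensity plane per role, unmodified.

    Raises a ``ValueError`` naming the missing role if the image does not
    carry all of red/green/blue (ColonyImage enforces this at
    construction; the check here covers images built with partial role
    maps through other paths).
    """
    missing = [r for r in CHANNEL_ROLES if r not in image.roles]
    if missing:
        raise ValueError(f"missing channel role assignment: {missing}")
    return {role: image.plane(role) for role in CHANNEL_ROLES}


def _remove_small_objects(mask: np.ndarray, min_object_px: int) -> np.ndarray:
    """Drop 8-connected foreground components with area < ``min_object_px``."""
    if min_object_px <= 0:
        return mask
    labels, n = ndi.label(mask, structure=_STRUCT8)
    if n == 0:
        return mask
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    keep = counts >= min_object_px
    keep[0] = False
    return keep[labels]


def _fill_small_holes(mask: np.ndarray, min_hole_px: int) -> np.ndarray:
    """Fill enclosed background components smaller than ``min_hole_px``.

    A hole is a background component (8-connectivity) that does not touch
    the image border.
    """
    if min_hole_px <= 0:
        return mask
    labels, n = ndi.label(~mask, structure=_STRUCT8)
    if n == 0:
        return mask
    border = np.unique(
        np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
    )
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    fill = (counts < min_hole_px) & (np.arange(n + 1) > 0)
    fill[border] = False
    if fill.any():
        mask = mask | fill[labels]
    return mask


def make_mask(
    channel: np.ndarray,
    method: str = "otsu",
    fixed_value: float | None = None,
    min_object_px: int = 64,
    min_hole_px: int = 64,
    source_channel: str = "",
) -> BinaryMask:
    """Threshold a channel and clean the result.

    Pixels strictly above the threshold become foreground; 8-connected
    foreground components smaller than ``min_object_px`` are removed;
    enclosed background components smaller than ``min_hole_px`` are
    filled.

    Parameters
    ----------
    method : {"otsu", "fixed"}
        ``otsu`` derives the threshold from the intensity histogram and
        rejects constant channels; ``fixed`` uses ``fixed_value``.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.size == 0:
        raise ValueError("empty channel")
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("method='fixed' requires fixed_value")
        threshold = float(fixed_value)
    elif method == "otsu":
        if fixed_value is not None:
            raise ValueError("fixed_value only applies to method='fixed'")
        if np.ptp(channel) == 0:
            raise DegenerateChannelError(
                "channel is constant; Otsu thresholding undefined"
            )
        threshold = float(threshold_otsu(channel))
    else:
        raise ValueError(f"unknown threshold method: {method!r}")

    grid = channel > threshold
    grid = _remove_small_objects(grid, min_object_px)
    grid = _fill_small_holes(grid, min_hole_px)
    return BinaryMask(
        grid=grid,
        source_channel=source_channel,
        provenance={
            "method": method,
            "threshold": threshold,
            "min_object_px": int(min_object_px),
            "min_hole_px": int(min_hole_px),
        },
    )


# ---------------------------------------------------------------------------
# readers / writers


def write_colony_tiff(path: str | Path, image: ColonyImage) -> None:
    """Write a colony image as 16-bit multi-channel TIFF (R, G, B order)."""
    planes = np.stack([image.plane(r) for r in CHANNEL_ROLES])
    data = np.clip(np.rint(planes), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), data, photometric="rgb", planarconfig="separate")


def read_colony_tiff(path: str | Path, um_per_pixel: float | None = None) -> ColonyImage:
    data = tifffile.imread(str(path))
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a multi-channel TIFF")
    # accept planar (C,H,W) or interleaved (H,W,C)
    if data.shape[0] not in (3, 4) and data.shape[-1] in (3, 4):
        data = np.moveaxis(data, -1, 0)
    return ColonyImage(channels=data[:3].astype(float), um_per_pixel=um_per_pixel)


def read_colony_pngs(
    paths: Mapping[str, str | Path], um_per_pixel: float | None = None
) -> ColonyImage:
    """Assemble a colony image from single-channel files keyed by role."""
    missing = [r for r in CHANNEL_ROLES if r not in paths]
    if missing:
        raise ValueError(f"missing channel role assignment: {missing}")
    planes = [np.asarray(iio.imread(str(paths[r])), dtype=float) for r in CHANNEL_ROLES]
    shapes = {p.shape for p in planes}
    if len(shapes) != 1:
        raise ValueError(f"channel planes disagree in shape: {shapes}")
    return ColonyImage(channels=np.stack(planes), um_per_pixel=um_per_pixel)


def write_mask_png(path: str | Path, mask: BinaryMask) -> None:
    """Write the mask as 8-bit PNG (0/255) plus a JSON provenance sidecar."""
    path = Path(path)
    iio.imwrite(str(path), (mask.grid.astype(np.uint8) * 255))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {"source_channel": mask.source_channel, "area_px": mask.area,
             **mask.provenance},
            indent=2,
        )
    )


def read_mask_png(path: str | Path) -> BinaryMask:
    grid = np.asarray(iio.imread(str(path))) > 0
    provenance: dict = {}
    sidecar = Path(path).with_suffix(".json")
    if sidecar.exists():
        provenance = json.loads(sidecar.read_text())
    return BinaryMask(grid=grid, source_channel=provenance.get("source_channel", ""),
                      provenance=provenance)
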