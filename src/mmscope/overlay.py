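"""Debug overlays: label contours drawn on the original frame.

Channel contours are drawn in one colour; bacteria get one colour per
stable label so a tracked cell keeps its colour across frames.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
from skimage.color import gray2rgb
from skimage.segmentation import find_boundaries

from .bacteria import BacteriaSet
from .channels import ChannelSet

#: fixed palette cycled by label id (RGB, 0-255)
_PALETTE = np.array(
    [
        [230, 25, 75], [60, 180, 75], [0, 130, 200], [245, 130, 48],
        [145, 30, 180], [70, 240, 240], [240, 50, 230], [210, 245, 60],
        [250, 190, 212], [0, 128, 128], [220, 190, 255], [170, 110, 40],
    ],
    dtype=np.uint8,
)


def _to_rgb(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=np.float64)
    span = img.max() - img.min()
    norm = (img - img.min()) / span if span else np.zeros_like(img)
    return (gray2rgb(norm) * 255).astype(np.uint8)


def render_overlay(
    image: np.ndarray,
    channels: Optional[ChannelSet] = None,
    bacteria: Optional[BacteriaSet] = None,
) -> np.ndarray:
    """RGB image with channel contours (yellow) and per-label cell contours."""
    rgb = _to_rgb(image)
    if channels is not None:
        rgb[find_boundaries(channels.labels, mode="outer")] = (255, 225, 25)
    if bacteria is not None:
        for b in bacteria.bacteria:
            edge = find_boundaries(b.mask, mode="inner")
            rgb[edge] = _PALETTE[b.id % len(_PALETTE)]
    return rgb


def save_overlay(
    path: str | Path,
    image: np.ndarray,
    channels: Optional[ChannelSet] = None,
    bacteria: Optional[BacteriaSet] = None,
) -> None:
    """Write the overlay as a PNG."""
    iio.imwrite(Path(path), render_overlay(image, channels, bacteria))
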