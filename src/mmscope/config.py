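"""Pipeline configuration.

Every length-dimensioned default is multiplied by a single ``scale_factor``
so that the same configuration adapts to a different objective
magnification: lengths scale linearly, areas quadratically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple


@dataclass
class PipelineConfig:
    """All tunable parameters of the detection/tracking pipeline.

    Defaults are expressed at scale_factor = 1, corresponding to channels
    roughly 100-400 px long and bacteria a few pixels wide.  Accessor
    properties return the scale-adjusted values used by the algorithms.
    """

    scale_factor: float = 1.0

    # --- channel detection -------------------------------------------------
    #: Frangi ridge-filter scales (px); channel walls are a few px wide.
    frangi_scales: Tuple[float, ...] = (1.0, 1.5, 2.0, 2.5, 3.0)
    #: accepted channel axis-vector length range (px)
    channel_length_range: Tuple[float, float] = (100.0, 400.0)
    #: accepted perpendicular channel width range (px)
    channel_width_range: Tuple[float, float] = (5.0, 40.0)
    #: accepted outline connected-component area range (px^2)
    channel_area_range: Tuple[float, float] = (500.0, 50_000.0)
    #: radius of the disk used to close gaps in channel outlines (px)
    outline_dilation_radius: float = 2.0
    #: minimum number of detected channels for a frame to be accepted
    min_channels: int = 3
    #: dilation applied to final channel masks; slight over-stamping keeps
    #: channel-detection recall near 1 (compensates the interior erosion
    #: introduced by outline dilation)
    channel_mask_dilation: float = 3.0

    # --- bacteria detection ------------------------------------------------
    #: rolling-ball background radius (px), ~2x the bacterium width
    rolling_ball_radius: float = 10.0
    #: scale-normalised Laplacian-of-Gaussian scales (px)
    log_scales: Tuple[float, ...] = (1.5, 2.0, 2.5, 3.0, 3.5)
    #: minimum distance-transform value for watershed markers (px)
    marker_distance: float = 3.0
    #: accepted bacterium width range (px)
    bacteria_width_range: Tuple[float, float] = (2.0, 15.0)
    #: accepted bacterium area range (px^2)
    bacteria_area_range: Tuple[float, float] = (20.0, 2_000.0)
    #: MAD multiplier for the width/intensity split criteria
    split_k: float = 2.0
    #: both split criteria must fire within this skeleton window (px)
    split_window: int = 3

    # --- tracking ----------------------------------------------------------
    p_no_change: float = 0.90
    p_division: float = 0.07
    p_lysis: float = 0.03
    #: relative area-change scale of the Gaussian penalty
    area_sigma: float = 0.2
    #: centroid-displacement scale (px); None = half the mean cell length
    centroid_sigma: float | None = None
    #: per-cell division cap per frame interval
    division_cap: int = 2
    #: below this normalised-correlation peak the frame shift falls back to 0
    min_peak_correlation: float = 0.30
    #: which projection end of the channel axis is the dead end
    dead_end: str = "low"

    # --- quantification ----------------------------------------------------
    n_fluo: int = 0
    #: optional physical calibration written alongside pixel units
    um_per_px: float | None = None

    def s(self, value: float) -> float:
        """Scale a length-dimensioned value."""
        return value * self.scale_factor

    def s2(self, value: float) -> float:
        """Scale an area-dimensioned value."""
        return value * self.scale_factor**2

    # scaled accessors ------------------------------------------------------
    @property
    def frangi_scales_px(self) -> Tuple[float, ...]:
        return tuple(self.s(x) for x in self.frangi_scales)

    @property
    def channel_length_px(self) -> Tuple[float, float]:
        return (self.s(self.channel_length_range[0]), self.s(self.channel_length_range[1]))

    @property
    def channel_width_px(self) -> Tuple[float, float]:
        return (self.s(self.channel_width_range[0]), self.s(self.channel_width_range[1]))

    @property
    def channel_area_px2(self) -> Tuple[float, float]:
        return (self.s2(self.channel_area_range[0]), self.s2(self.channel_area_range[1]))

    @property
    def log_scales_px(self) -> Tuple[float, ...]:
        return tuple(self.s(x) for x in self.log_scales)

    @property
    def bacteria_width_px(self) -> Tuple[float, float]:
        return (self.s(self.bacteria_width_range[0]), self.s(self.bacteria_width_range[1]))

    @property
    def bacteria_area_px2(self) -> Tuple[float, float]:
        return (self.s2(self.bacteria_area_range[0]), self.s2(self.bacteria_area_range[1]))

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        total = self.p_no_change + self.p_division + self.p_lysis
        if not (self.p_no_change > 0 and self.p_division > 0 and self.p_lysis > 0):
            raise ValueError("event priors must be positive")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"event priors must sum to 1 (got {total})")
        if self.dead_end not in ("low", "high"):
            raise ValueError("dead_end must be 'low' or 'high'")
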