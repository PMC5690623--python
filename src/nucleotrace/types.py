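"""Shared domain types for the HCS viability pipeline.

Two fluorescence channels are used throughout: Hoechst 33342 (chromatin;
uniform in viable nuclei, bright and condensed in apoptotic nuclei) and
propidium iodide (PI; nuclear signal only after plasma-membrane rupture,
i.e. necrosis).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np


class Channel(str, enum.Enum):
    HOECHST = "hoechst"
    PI = "pi"


class CellState(enum.IntEnum):
    """Per-frame phenotype of one nucleus.

    Integer values encode the irreversibility ordering used by the
    feasibility validation: a cell may only move to an equal or higher
    state (viable -> apoptotic, viable -> necrotic, apoptotic -> necrotic
    as secondary necrosis; never backwards).
    """

    VIABLE = 0
    APOPTOTIC = 1
    NECROTIC = 2


#: Sentinel state for frames with no measurement (gap or extension).
UNKNOWN = None

STATE_NAMES = {
    CellState.VIABLE: "viable",
    CellState.APOPTOTIC: "apoptotic",
    CellState.NECROTIC: "necrotic",
}
STATE_FROM_NAME = {v: k for k, v in STATE_NAMES.items()}


@dataclass
class ImagePlane:
    """One 2-D intensity frame with acquisition metadata.

    Attributes
    ----------
    pixels : 2-D array of non-negative intensities.
    channel : which stain the frame shows.
    frame_index : position in the time series (frames are acquired at a
        constant interval; the reference acquisition used 1 h).
    well_id, field_id : plate-position identifiers.
    pixel_size_nm : physical pixel size (reference instrument: 645 nm).
    """

    pixels: np.ndarray
    channel: Channel
    frame_index: int = 0
    well_id: str = "A1"
    field_id: str = "f0"
    pixel_size_nm: float = 645.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("ImagePlane.pixels must be 2-D")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "ImagePlane":
        """Copy of this plane with new pixel data, metadata preserved."""
        return ImagePlane(
            pixels=pixels,
            channel=self.channel,
            frame_index=self.frame_index,
            well_id=self.well_id,
            field_id=self.field_id,
            pixel_size_nm=self.pixel_size_nm,
        )


@dataclass
class NucleusDetection:
    """One segmented nucleus in one frame.

    Hoechst statistics (area, mean, min, max, SD) are the classifier
    features; ``pi_mean`` is measured over the same pixel support and
    separates viable from necrotic nuclei.
    """

    label: int
    frame_index: int
    channel: Channel
    centroid: tuple[float, float]  # (row, col), 0-based
    area_px: int
    hoechst_mean: float
    hoechst_min: float
    hoechst_max: float
    hoechst_sd: float
    pi_mean: float
    well_id: str = "A1"
    field_id: str = "f0"

    @property
    def features(self) -> np.ndarray:
        """Feature vector in the fixed order (area, mean, min, max, sd)."""
        return np.array(
            [
                self.area_px,
                self.hoechst_mean,
                self.hoechst_min,
                self.hoechst_max,
                self.hoechst_sd,
            ],
            dtype=float,
        )


FEATURE_COLUMNS = ("area_px", "h_mean", "h_min", "h_max", "h_sd")
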