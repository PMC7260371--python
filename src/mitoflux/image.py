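"""Multichannel well-image container.

A :class:`WellImage` holds the four fluorescence channels acquired from one
well of a flux plate after the assay — nuclear stain (Hoechst),
mitochondrial stain (MitoTracker), membrane-potential dye (TMRE) and
superoxide dye (MitoSOX) — as 2-D nonnegative intensity arrays with a
micron pixel calibration, plus the well-centre geometry used to restrict
counting to the sensed central region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import ValidationError

CHANNELS = ("nuclear", "mito", "tmre", "mitosox")


@dataclass
class WellImage:
    well_id: str
    channels: dict[str, np.ndarray]
    pixel_size_um: float
    well_center_px: tuple[float, float] | None = None  # (row, col)
    well_radius_px: float | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        shapes = {ch: a.shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValidationError(f"channel shapes differ: {shapes}")
        for ch, arr in self.channels.items():
            if arr.ndim != 2:
                raise ValidationError(f"channel {ch!r} must be 2-D")
            if np.any(arr < 0):
                raise ValidationError(f"channel {ch!r} has negative intensities")
        if self.well_center_px is None and self.channels:
            h, w = self.shape
            self.well_center_px = ((h - 1) / 2.0, (w - 1) / 2.0)
        if self.well_radius_px is None and self.channels:
            h, w = self.shape
            self.well_radius_px = min(h, w) / 2.0 - 2.0

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def has(self, channel: str) -> bool:
        return channel in self.channels

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]


def write_well_tiffs(image: WellImage, out_dir: str | Path) -> list[Path]:
    """Write one 16-bit grayscale TIFF per channel, named ``{well}_{channel}.tif``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ch, arr in image.channels.items():
        data = np.clip(np.round(arr), 0, 65535).astype(np.uint16)
        p = out_dir / f"{image.well_id}_{ch}.tif"
        tifffile.imwrite(p, data)
        paths.append(p)
    return paths


def read_well_tiffs(
    well_id: str,
    image_dir: str | Path,
    pixel_size_um: float,
    well_center_px: tuple[float, float] | None = None,
    well_radius_px: float | None = None,
) -> WellImage:
    """Load the channels present for one well from ``{well}_{channel}.tif`` files."""
    image_dir = Path(image_dir)
    channels = {}
    for ch in CHANNELS:
        p = image_dir / f"{well_id}_{ch}.tif"
        if p.exists():
            channels[ch] = tifffile.imread(p).astype(np.float64)
    if not channels:
        raise FileNotFoundError(f"no channel TIFFs for well {well_id} in {image_dir}")
    return WellImage(
        well_id=well_id,
        channels=channels,
        pixel_size_um=pixel_size_um,
        well_center_px=well_center_px,
        well_radius_px=well_radius_px,
    )
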