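"""End-to-end scan processing: tiles in, deduplicated localisation table out.

Chains the per-tile image processing (normalise, flat-field, median-filter
subtraction), per-tile spot localisation, phase-correlation stitching of the
processed tiles, and duplicate removal in the overlap regions.  Large-feature
subtraction happens per tile, before stitching, so tile borders never leak
filter artefacts into neighbouring tiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import imgproc, locfind
from .imgproc import FlatField, Mosaic
from .locfind import DetectionConfig


@dataclass
class ScanResult:
    """Output of :func:`analyze_scan`."""

    mosaic: Mosaic
    localizations: pd.DataFrame
    per_tile: list[pd.DataFrame]
    pitch_um: float

    @property
    def covered_area_mm2(self) -> float:
        return self.mosaic.covered_area_mm2(self.pitch_um)

    def density_per_100um2(self) -> float:
        """Localisation count per 100 um^2 of covered mosaic area."""
        area_units = self.mosaic.covered_pixels * self.pitch_um ** 2 / 100.0
        return len(self.localizations) / area_units


def process_tile(tile,
                 flatfield: FlatField | None = None,
                 median_kernel: int = 17) -> np.ndarray:
    """Normalise, flat-field correct and median-subtract one tile."""
    if flatfield is not None:
        corrected = imgproc.flatfield_correct(tile, flatfield)
    else:
        corrected = imgproc.normalize_frame(tile)
    return imgproc.remove_large_features(corrected, kernel=median_kernel)


def analyze_scan(tiles,
                 nominal_offsets,
                 pitch_um: float,
                 flatfield: FlatField | None = None,
                 det_cfg: DetectionConfig = DetectionConfig(),
                 median_kernel: int = 17,
                 refine_offsets: bool = True,
                 dedupe_radius_px: float = 2.0,
                 channel_id: str | None = None) -> ScanResult:
    """Run the full read-out chain on one channel scan.

    Localisation runs on each processed tile independently; stitching (on the
    processed tiles) only has to provide the tile origins used to map
    localisations into the mosaic frame and to merge duplicates from
    overlapping tiles.
    """
    processed = [process_tile(t, flatfield, median_kernel) for t in tiles]
    mosaic = imgproc.stitch(processed, nominal_offsets, refine=refine_offsets)
    per_tile = [locfind.localize_frame(p, det_cfg, pitch_um=pitch_um,
                                       tile_id=k, channel_id=channel_id)
                for k, p in enumerate(processed)]
    table = locfind.dedupe_mosaic(per_tile, mosaic.tile_origins,
                                  radius_px=dedupe_radius_px, pitch_um=pitch_um)
    return ScanResult(mosaic=mosaic, localizations=table, per_tile=per_tile,
                      pitch_um=pitch_um)
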