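"""Frame normalisation, flat-field correction, large-feature removal and
phase-correlation stitching.

The processing chain applied to every recorded tile before spot detection is

1. normalise to the background camera counts (robustly, via the frame
   median, so sparse bright spots do not bias the level);
2. divide by the flat-field gain image, built as a pixel-wise median over a
   stack of frames taken at distinct sample positions;
3. subtract a 17-px spatial median filter of the result, which removes
   smooth large-scale structure (out-of-focus objects, residual gain) while
   leaving diffraction-limited spots essentially untouched;
4. stitch tiles into a channel-scale mosaic with phase correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation


@dataclass
class Frame:
    """One 2D intensity image with its physical calibration."""

    pixels: np.ndarray
    pitch_um: float
    stage_position_um: tuple[float, float] = (0.0, 0.0)
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("Frame pixels must be a 2D array")
        if not np.isfinite(self.pixels).all():
            raise ValueError("Frame pixels must be finite")
        if self.pitch_um <= 0:
            raise ValueError("pitch must be > 0")


@dataclass
class FlatField:
    """Per-pixel gain image, median-normalised to 1."""

    gain: np.ndarray
    n_source_frames: int

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if (self.gain <= 0).any():
            raise ValueError("flat-field gain must be strictly positive everywhere")


@dataclass
class Mosaic:
    """Stitched channel-scale image."""

    image: np.ndarray
    tile_origins: np.ndarray  # (n_tiles, 2) integer (row, col) in mosaic frame
    coverage_mask: np.ndarray

    @property
    def covered_pixels(self) -> int:
        return int(self.coverage_mask.sum())

    def covered_area_mm2(self, pitch_um: float) -> float:
        return self.covered_pixels * pitch_um ** 2 * 1e-6


def _pixels(frame) -> np.ndarray:
    return np.asarray(frame.pixels if hasattr(frame, "pixels") else frame,
                      dtype=float)


def time_average(frames) -> np.ndarray:
    """Pixel-wise arithmetic mean of a stack of same-shape frames.

    For independent noise this reduces the noise standard deviation by
    sqrt(n); saving time-averaged frames is how the instrument trades frame
    rate for SNR.
    """
    arrays = [_pixels(f) for f in frames]
    if len(arrays) < 1:
        raise ValueError("need at least one frame")
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("all frames must share one shape")
    return np.mean(arrays, axis=0)


def background_level(image) -> float:
    """Robust background estimate: the frame median (insensitive to sparse
    spots, unlike the mean)."""
    return float(np.median(_pixels(image)))


def normalize_frame(frame) -> np.ndarray:
    """Normalise a frame to its background camera counts (output level ~ 1)."""
    img = _pixels(frame)
    level = background_level(img)
    if level <= 0:
        raise ValueError("cannot normalise: non-positive background level")
    return img / level


def build_flatfield(frames, min_frames: int = 60) -> FlatField:
    """Build the experimental flat-field from frames at distinct positions.

    Each frame is first normalised to its own background level, then the
    pixel-wise median across the stack is taken -- sparse per-frame spots do
    not survive the median -- and renormalised to median 1.
    """
    arrays = [normalize_frame(f) for f in frames]
    if len(arrays) < 2:
        raise ValueError("flat-field construction needs at least 2 frames")
    if len(arrays) < min_frames:
        warnings.warn(f"building flat-field from {len(arrays)} frames; "
                      f"{min_frames} or more are recommended", stacklevel=2)
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("all frames must share one shape")
    gain = np.median(np.stack(arrays), axis=0)
    gain = gain / np.median(gain)
    return FlatField(gain=gain, n_source_frames=len(arrays))


def flatfield_correct(frame, flatfield: FlatField, normalize: bool = True) -> np.ndarray:
    """Divide the (normalised) frame by the flat-field gain."""
    img = normalize_frame(frame) if normalize else _pixels(frame)
    gain = flatfield.gain
    if img.shape != gain.shape:
        raise ValueError("frame and flat-field shapes differ")
    if (gain <= 0).any():
        raise ValueError("flat-field gain must be strictly positive")
    return img / gain


def remove_large_features(image, kernel: int = 17) -> np.ndarray:
    """Subtract a spatial median filter (default 17 px) from the image.

    Structures smoother/larger than the kernel (out-of-focus objects,
    residual illumination) are removed and the output baseline is zero;
    diffraction-limited spots (~2-3 px FWHM) pass through with their contrast
    essentially unchanged.  Reflect padding at the borders.
    """
    img = _pixels(image)
    if kernel < 3 or kernel % 2 == 0:
        raise ValueError("kernel must be an odd integer >= 3")
    if kernel > min(img.shape):
        raise ValueError("kernel larger than the image")
    return img - ndimage.median_filter(img, size=kernel, mode="reflect")


# ---------------------------------------------------------------------------
# Stitching
# ---------------------------------------------------------------------------

def register_pair(ref: np.ndarray, mov: np.ndarray,
                  upsample_factor: int = 1) -> np.ndarray:
    """Phase-correlation shift that moves ``mov`` onto ``ref``.

    Plain (unnormalised) cross-correlation is used: for sparse spot fields on
    a flat background it weights the correlation peak by spot energy instead
    of whitening it into the noise floor.
    """
    shift, _, _ = phase_cross_correlation(ref - ref.mean(), mov - mov.mean(),
                                          normalization=None,
                                          upsample_factor=upsample_factor)
    return np.asarray(shift, dtype=float)


def _shift_score(crop_i: np.ndarray, crop_j: np.ndarray,
                 shift: np.ndarray) -> float:
    """Pearson correlation of the two crops after shifting ``crop_j`` by the
    integer part of ``shift``; -inf when the shifted overlap is too small."""
    dr, dc = int(round(shift[0])), int(round(shift[1]))
    h, w = crop_i.shape
    ri0, rj0 = max(dr, 0), max(-dr, 0)
    ci0, cj0 = max(dc, 0), max(-dc, 0)
    hh, ww = h - abs(dr), w - abs(dc)
    if hh < 4 or ww < 4:
        return -np.inf
    a = crop_i[ri0:ri0 + hh, ci0:ci0 + ww].ravel()
    b = crop_j[rj0:rj0 + hh, cj0:cj0 + ww].ravel()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return -np.inf
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def _pair_overlap(shape_i, shape_j, off_i, off_j):
    r0 = max(off_i[0], off_j[0])
    c0 = max(off_i[1], off_j[1])
    r1 = min(off_i[0] + shape_i[0], off_j[0] + shape_j[0])
    c1 = min(off_i[1] + shape_i[1], off_j[1] + shape_j[1])
    return r0, c0, r1, c1


def stitch(tiles,
           nominal_offsets,
           refine: bool = True,
           subpixel: bool = False,
           min_overlap_px: int = 16,
           max_shift_px: float = 16.0,
           score_significance: float = 5.0) -> Mosaic:
    """Stitch tiles into a mosaic, refining offsets by phase correlation.

    Pairwise shifts between nominally overlapping tiles are refined on the
    nominal overlap crops; tile origins are then solved globally by least
    squares over all pairwise constraints (anchored on the first tile) and
    rounded to integer pixels.  Overlap regions are composited with an
    unweighted mean.  A refined shift is accepted only if it stays within
    ``max_shift_px`` of the nominal offset (stage errors are small; a larger
    apparent shift means the correlation locked onto the wrong feature
    pairing) and the Pearson correlation of the re-aligned overlap clears
    ``score_significance`` standard errors (1/sqrt(n_pixels)) of a
    noise-only correlation while improving on the nominal alignment;
    otherwise the pair falls back to its nominal offset and a summary
    warning is emitted.
    """
    arrays = [_pixels(t) for t in tiles]
    n = len(arrays)
    if n == 0:
        raise ValueError("need at least one tile")
    nominal = np.asarray(nominal_offsets, dtype=float).reshape(n, 2)
    if n == 1:
        img = arrays[0]
        return Mosaic(image=img.copy(),
                      tile_origins=np.zeros((1, 2), dtype=int),
                      coverage_mask=np.ones_like(img, dtype=bool))

    # pairwise constraints rel[j] - rel[i]
    pairs = []  # (i, j, d_row, d_col)
    n_fallback = 0
    for i in range(n):
        for j in range(i + 1, n):
            r0, c0, r1, c1 = _pair_overlap(arrays[i].shape, arrays[j].shape,
                                           nominal[i], nominal[j])
            if r1 - r0 < min_overlap_px or c1 - c0 < min_overlap_px:
                continue
            rel = nominal[j] - nominal[i]
            if refine:
                ri0, ci0 = int(round(r0 - nominal[i][0])), int(round(c0 - nominal[i][1]))
                rj0, cj0 = int(round(r0 - nominal[j][0])), int(round(c0 - nominal[j][1]))
                h, w = int(round(r1 - r0)), int(round(c1 - c0))
                crop_i = arrays[i][ri0:ri0 + h, ci0:ci0 + w]
                crop_j = arrays[j][rj0:rj0 + h, cj0:cj0 + w]
                try:
                    shift = register_pair(crop_i, crop_j,
                                          upsample_factor=10 if subpixel else 1)
                except (ValueError, ZeroDivisionError):
                    shift = None
                if shift is not None and np.abs(shift).max() > max_shift_px:
                    shift = None
                if shift is not None:
                    # crop_j samples the scene displaced by the true-offset
                    # error; the shift registering crop_j onto crop_i is that
                    # error.  Accept it only if it genuinely re-aligns the
                    # overlap better than the nominal offsets do.
                    refined_score = _shift_score(crop_i, crop_j, shift)
                    nominal_score = _shift_score(crop_i, crop_j,
                                                 np.zeros(2))
                    floor = score_significance / math.sqrt(crop_i.size)
                    if refined_score < floor or refined_score < nominal_score:
                        shift = None
                if shift is None:
                    n_fallback += 1
                else:
                    rel = rel + shift
            pairs.append((i, j, rel[0], rel[1]))
    if n_fallback:
        warnings.warn(f"{n_fallback} tile pair(s) had no reliable correlation "
                      "peak; nominal offsets used for them", stacklevel=2)

    if not pairs:
        warnings.warn("no overlapping tile pairs; using nominal offsets",
                      stacklevel=2)
        origins = nominal.copy()
    else:
        # least squares: origin[j] - origin[i] = rel_ij, origin[0] = 0
        a = np.zeros((len(pairs) + 1, n))
        b_r = np.zeros(len(pairs) + 1)
        b_c = np.zeros(len(pairs) + 1)
        for k, (i, j, dr, dc) in enumerate(pairs):
            a[k, i], a[k, j] = -1.0, 1.0
            b_r[k], b_c[k] = dr, dc
        a[-1, 0] = 1.0  # anchor
        rows = np.linalg.lstsq(a, b_r, rcond=None)[0]
        cols = np.linalg.lstsq(a, b_c, rcond=None)[0]
        origins = np.stack([rows, cols], axis=1)
        origins += nominal[0] - origins[0]

    if not subpixel:
        origins = np.round(origins)
    origins = origins - origins.min(axis=0)
    origins_int = np.round(origins).astype(int)

    mosaic_shape = (int(max(o[0] + t.shape[0] for o, t in zip(origins_int, arrays))),
                    int(max(o[1] + t.shape[1] for o, t in zip(origins_int, arrays))))
    acc = np.zeros(mosaic_shape)
    cnt = np.zeros(mosaic_shape)
    for (orow, ocol), tile in zip(origins_int, arrays):
        acc[orow:orow + tile.shape[0], ocol:ocol + tile.shape[1]] += tile
        cnt[orow:orow + tile.shape[0], ocol:ocol + tile.shape[1]] += 1.0
    covered = cnt > 0
    image = np.zeros(mosaic_shape)
    image[covered] = acc[covered] / cnt[covered]
    return Mosaic(image=image, tile_origins=origins_int, coverage_mask=covered)
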