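"""Spot detection, sub-pixel localisation and contrast measurement.

Detection operates on the processed image (flat-fielded, unit-background,
median-filter-subtracted, hence zero baseline) with a two-stage noise model:

* a *global* noise level from the median absolute deviation (MAD, scaled by
  1.4826 to a Gaussian-equivalent sigma);
* a *local* noise map: the RMS of all pixels inside a 65-px sliding window
  that fall within 2.5x the global estimate, so spots themselves do not
  inflate the noise under them.

Candidates are connected clusters of |SNR| > 4 pixels containing at least
three supra-threshold pixels inside a 3x3 window; each candidate is then
localised with the radial-symmetry-centres algorithm (closed-form, no PSF
model fit) and its peak and integrated contrast are measured.  SNR is taken
on the magnitude of the image so both bright and dark interferometric spots
are found.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree


class LocalizationError(ValueError):
    """Raised when a candidate cannot be localised (flat/degenerate ROI)."""


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds and kernels of the detection stage."""

    snr_threshold: float = 4.0
    min_cluster_pixels: int = 3
    cluster_window: int = 3
    local_noise_kernel: int = 65
    outlier_factor: float = 2.5
    mad_to_sigma: float = 1.4826
    noise_floor_frac: float = 0.25   # local sigma floored at this x global
    min_inlier_frac: float = 0.10    # window fallback threshold
    roi_window: int = 9
    merge_radius_px: float = 3.0
    border_margin_px: int = 8  # median-filter edge artefact exclusion zone

    def __post_init__(self) -> None:
        if min(self.snr_threshold, self.outlier_factor, self.mad_to_sigma) <= 0:
            raise ValueError("thresholds must be > 0")
        for k in (self.cluster_window, self.local_noise_kernel, self.roi_window):
            if k < 3 or k % 2 == 0:
                raise ValueError("kernels must be odd integers >= 3")


@dataclass
class NoiseMap:
    """Local per-pixel noise sigma plus the global MAD-based estimate."""

    local_sigma: np.ndarray
    global_sigma: float

    def __post_init__(self) -> None:
        if (self.local_sigma <= 0).any():
            raise ValueError("local sigma must be strictly positive everywhere")


def global_noise(image, mad_to_sigma: float = 1.4826) -> float:
    """Global noise sigma from the median absolute deviation.

    sigma = mad_to_sigma * median(|x - median(x)|); 1.4826 makes the
    estimator consistent for Gaussian noise.  Returns 0 for a constant image
    (downstream SNR is then undefined and callers must refuse to proceed).
    """
    img = np.asarray(image, dtype=float)
    return mad_to_sigma * float(np.median(np.abs(img - np.median(img))))


def local_noise(image, global_sigma: float,
                cfg: DetectionConfig = DetectionConfig()) -> NoiseMap:
    """Sliding-window RMS noise map with outlier exclusion.

    Per pixel, the RMS of all values within the ``local_noise_kernel`` window
    whose magnitude is at most ``outlier_factor`` x the global sigma; windows
    with fewer than ``min_inlier_frac`` inliers fall back to the global
    value.  The map is floored at ``noise_floor_frac`` x global sigma so the
    SNR division cannot blow up.
    """
    if global_sigma <= 0:
        raise ValueError("global sigma must be > 0")
    img = np.asarray(image, dtype=float)
    k = cfg.local_noise_kernel
    inlier = np.abs(img) <= cfg.outlier_factor * global_sigma
    sq = np.where(inlier, img * img, 0.0)
    sum_sq = ndimage.uniform_filter(sq, size=k, mode="reflect")
    frac = ndimage.uniform_filter(inlier.astype(float), size=k, mode="reflect")
    with np.errstate(invalid="ignore", divide="ignore"):
        rms = np.sqrt(sum_sq / frac)
    rms[frac < cfg.min_inlier_frac] = global_sigma
    rms = np.maximum(rms, cfg.noise_floor_frac * global_sigma)
    return NoiseMap(local_sigma=rms, global_sigma=float(global_sigma))


def snr_map(image, noise: NoiseMap) -> np.ndarray:
    """Pixel-wise |image| / local sigma."""
    return np.abs(np.asarray(image, dtype=float)) / noise.local_sigma


@dataclass(frozen=True)
class Candidate:
    row: int
    col: int
    peak_snr: float
    n_pixels: int


def detect_candidates(snr: np.ndarray,
                      cfg: DetectionConfig = DetectionConfig()) -> list[Candidate]:
    """Segment candidate spots from an SNR image.

    A pixel is supra-threshold when its SNR exceeds ``snr_threshold``;
    8-connected clusters are kept only if some ``cluster_window`` (3x3)
    window over the cluster holds at least ``min_cluster_pixels``
    supra-threshold pixels.  Candidates closer than ``merge_radius_px`` are
    merged, keeping the higher-peak-SNR one.  A ``border_margin_px`` frame
    around the image is excluded: boundary padding of the median filter
    leaves residuals there that mimic spots.
    """
    snr = np.asarray(snr, dtype=float)
    mask = snr > cfg.snr_threshold
    m = cfg.border_margin_px
    if m > 0:
        mask[:m, :] = False
        mask[-m:, :] = False
        mask[:, :m] = False
        mask[:, -m:] = False
    if not mask.any():
        return []
    labels, n_lab = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    window_counts = ndimage.uniform_filter(
        mask.astype(float), size=cfg.cluster_window, mode="constant") \
        * cfg.cluster_window ** 2
    cands: list[Candidate] = []
    objects = ndimage.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        comp = labels[sl] == lab
        if window_counts[sl][comp].max() < cfg.min_cluster_pixels - 0.5:
            continue
        local_snr = np.where(comp, snr[sl], -np.inf)
        r, c = np.unravel_index(np.argmax(local_snr), local_snr.shape)
        cands.append(Candidate(row=int(r + sl[0].start), col=int(c + sl[1].start),
                               peak_snr=float(local_snr[r, c]),
                               n_pixels=int(comp.sum())))
    if len(cands) > 1 and cfg.merge_radius_px > 0:
        cands = sorted(cands, key=lambda c: -c.peak_snr)
        pts = np.array([(c.row, c.col) for c in cands], dtype=float)
        tree = cKDTree(pts)
        keep = np.ones(len(cands), dtype=bool)
        for i in range(len(cands)):
            if not keep[i]:
                continue
            for j in tree.query_ball_point(pts[i], cfg.merge_radius_px):
                if j > i:
                    keep[j] = False
        cands = [c for c, k in zip(cands, keep) if k]
    return cands


def _radial_center(roi: np.ndarray) -> tuple[float, float]:
    """Radial-symmetry centre of an ROI (x, y in ROI pixel coordinates).

    Closed-form least squares: every inter-pixel gradient midpoint defines a
    line through it along the local gradient; for a radially symmetric spot
    all such lines pass through the centre.  The returned point minimises the
    weighted sum of squared perpendicular distances to those lines, with
    weights proportional to gradient magnitude squared over the distance to
    the gradient-weighted centroid.
    """
    I = np.asarray(roi, dtype=float)
    ny, nx = I.shape
    if ny < 3 or nx < 3:
        raise LocalizationError("ROI too small for localisation")
    xm = np.arange(nx - 1) + 0.5
    ym = np.arange(ny - 1) + 0.5
    XM, YM = np.meshgrid(xm, ym)
    # diagonal (Roberts-cross) derivatives on the midpoint grid,
    # 3x3 boxcar-smoothed, rotated back into (x, y)
    dIdu = I[:-1, 1:] - I[1:, :-1]
    dIdv = I[:-1, :-1] - I[1:, 1:]
    fdu = ndimage.uniform_filter(dIdu, 3)
    fdv = ndimage.uniform_filter(dIdv, 3)
    gx = fdu - fdv
    gy = -(fdu + fdv)
    g2 = gx * gx + gy * gy
    s = g2.sum()
    if s <= 0 or not np.isfinite(s):
        raise LocalizationError("flat ROI: no gradient information")
    xc0 = (g2 * XM).sum() / s
    yc0 = (g2 * YM).sum() / s
    d = np.maximum(np.hypot(XM - xc0, YM - yc0), 0.1)
    w = g2 / d
    gnorm2 = np.maximum(g2, np.finfo(float).tiny)
    a11 = w * (gy * gy) / gnorm2
    a22 = w * (gx * gx) / gnorm2
    a12 = -w * (gx * gy) / gnorm2
    A = np.array([[a11.sum(), a12.sum()], [a12.sum(), a22.sum()]])
    b = np.array([(a11 * XM + a12 * YM).sum(), (a12 * XM + a22 * YM).sum()])
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    if not np.isfinite(det) or abs(det) <= 1e-12 * max(1.0, float(np.abs(A).max()) ** 2):
        raise LocalizationError("singular normal matrix in radial-symmetry solve")
    xc, yc = np.linalg.solve(A, b)
    if not (np.isfinite(xc) and np.isfinite(yc)):
        raise LocalizationError("non-finite localisation")
    return float(xc), float(yc)


def _extract_roi(image: np.ndarray, row: int, col: int,
                 window: int) -> tuple[np.ndarray, int, int]:
    half = window // 2
    r0, r1 = max(row - half, 0), min(row + half + 1, image.shape[0])
    c0, c1 = max(col - half, 0), min(col + half + 1, image.shape[1])
    if r1 - r0 < 5 or c1 - c0 < 5:
        raise LocalizationError("candidate too close to the image border")
    return image[r0:r1, c0:c1], r0, c0


def localize_radial_symmetry(image, center: tuple[int, int],
                             window: int = 9) -> tuple[float, float]:
    """Sub-pixel (x, y) of the spot near ``center`` = (row, col).

    The ROI (default 9x9, clipped at borders) is sign-flipped for dark spots
    so the same radially symmetric model applies to both contrast signs.
    """
    img = np.asarray(image, dtype=float)
    row, col = int(center[0]), int(center[1])
    roi, r0, c0 = _extract_roi(img, row, col, window)
    if img[row, col] < 0:
        roi = -roi
    xc, yc = _radial_center(roi)
    return xc + c0, yc + r0


def measure_contrast(image, center: tuple[float, float],
                     window: int = 9,
                     subpixel_peak: bool = True) -> tuple[float, float]:
    """Peak and integrated contrast of a spot on a zero-baseline image.

    ``center`` is (x, y), typically the sub-pixel localisation.  The peak
    contrast is the spot amplitude at its sub-pixel maximum, obtained from a
    log-quadratic interpolation of the 3x3 neighbourhood of the brightest
    pixel (exact for a Gaussian profile, so the value does not depend on
    where the spot falls within a pixel); with ``subpixel_peak=False`` it is
    simply the largest |value| in the 3x3 neighbourhood.  The integrated
    contrast is the magnitude of the ROI sum above the zero baseline
    (units: contrast x px^2).  Both are reported as magnitudes.
    """
    img = np.asarray(image, dtype=float)
    x, y = float(center[0]), float(center[1])
    col, row = int(round(x)), int(round(y))
    if not (0 <= row < img.shape[0] and 0 <= col < img.shape[1]):
        raise ValueError("centre outside the image")
    roi, r0, c0 = _extract_roi(img, row, col, window)
    sign = 1.0 if img[row, col] >= 0 else -1.0
    signed = sign * roi
    # brightest pixel within the ROI, then its 3x3 neighbourhood
    rr, cc = np.unravel_index(np.argmax(signed), signed.shape)
    rr = int(np.clip(rr, 1, signed.shape[0] - 2))
    cc = int(np.clip(cc, 1, signed.shape[1] - 2))
    patch = signed[rr - 1:rr + 2, cc - 1:cc + 2]
    peak = float(patch.max())
    if subpixel_peak and (patch > 0).all():
        interp = _log_quadratic_peak(patch)
        if interp is not None:
            peak = interp
    integrated = float(abs(signed.sum()))
    return abs(peak), integrated


def _log_quadratic_peak(patch3: np.ndarray) -> float | None:
    """Peak of a 2D quadratic fitted to log(values) on a 3x3 patch.

    Exact for Gaussian spots of any width and sub-pixel position.  Returns
    None when the fitted surface has no interior maximum (noise-dominated or
    saturated shapes), in which case the caller keeps the pixel maximum.
    """
    L = np.log(patch3)
    dx = np.array([-1, 0, 1], dtype=float)
    X, Y = np.meshgrid(dx, dx)
    design = np.stack([np.ones(9), X.ravel(), Y.ravel(),
                       X.ravel() ** 2, Y.ravel() ** 2,
                       (X * Y).ravel()], axis=1)
    coef, *_ = np.linalg.lstsq(design, L.ravel(), rcond=None)
    a0, bx, by, cxx, cyy, cxy = coef
    H = np.array([[2 * cxx, cxy], [cxy, 2 * cyy]])
    # maximum requires a negative-definite Hessian
    if H[0, 0] >= 0 or np.linalg.det(H) <= 0:
        return None
    try:
        sol = np.linalg.solve(H, -np.array([bx, by]))
    except np.linalg.LinAlgError:
        return None
    if np.abs(sol).max() > 1.0:
        return None
    px, py = sol
    val = (a0 + bx * px + by * py + cxx * px ** 2 + cyy * py ** 2
           + cxy * px * py)
    return float(np.exp(val))


LOCALIZATION_COLUMNS = ["channel", "tile", "x_px", "y_px", "x_um", "y_um",
                        "snr", "peak_contrast", "integrated_contrast"]


def localize_frame(image,
                   cfg: DetectionConfig = DetectionConfig(),
                   pitch_um: float | None = None,
                   tile_id: int | str | None = None,
                   channel_id: str | None = None) -> pd.DataFrame:
    """Full per-frame detection + localisation + contrast measurement.

    ``image`` must be the processed zero-baseline frame.  Candidates that
    fail sub-pixel localisation (flat/degenerate ROI) are dropped.  Returns a
    localisation table; positions are in pixels and, when ``pitch_um`` is
    given, micrometres.
    """
    img = np.asarray(image, dtype=float)
    sigma = global_noise(img, cfg.mad_to_sigma)
    if sigma <= 0:
        raise ValueError("global noise is zero (constant image); SNR undefined")
    noise = local_noise(img, sigma, cfg)
    snr = snr_map(img, noise)
    rows = []
    for cand in detect_candidates(snr, cfg):
        try:
            x, y = localize_radial_symmetry(img, (cand.row, cand.col),
                                            cfg.roi_window)
        except LocalizationError:
            continue
        if not (0 <= round(y) < img.shape[0] and 0 <= round(x) < img.shape[1]):
            continue  # border candidate localised outside the frame
        try:
            peak, integ = measure_contrast(img, (x, y), cfg.roi_window)
        except LocalizationError:
            continue
        rows.append(dict(channel=channel_id, tile=tile_id, x_px=x, y_px=y,
                         x_um=x * pitch_um if pitch_um else np.nan,
                         y_um=y * pitch_um if pitch_um else np.nan,
                         snr=cand.peak_snr, peak_contrast=peak,
                         integrated_contrast=integ))
    return pd.DataFrame(rows, columns=LOCALIZATION_COLUMNS)


def dedupe_mosaic(tables: list[pd.DataFrame],
                  tile_origins: np.ndarray,
                  radius_px: float = 2.0,
                  pitch_um: float | None = None) -> pd.DataFrame:
    """Merge per-tile localisations into one mosaic-frame table.

    Tile-local positions are mapped into mosaic coordinates via
    ``tile_origins`` ((row, col) per tile); detections within ``radius_px``
    of a higher-SNR detection (the same physical spot seen in two
    overlapping tiles) are merged into it, keeping the higher-SNR record.
    """
    mapped = []
    for table, (orow, ocol) in zip(tables, np.asarray(tile_origins)):
        t = table.copy()
        t["x_px"] = t["x_px"] + ocol
        t["y_px"] = t["y_px"] + orow
        mapped.append(t)
    merged = pd.concat(mapped, ignore_index=True) if mapped else pd.DataFrame(
        columns=LOCALIZATION_COLUMNS)
    if len(merged) == 0:
        return merged
    merged = merged.sort_values("snr", ascending=False).reset_index(drop=True)
    pts = merged[["y_px", "x_px"]].to_numpy()
    tree = cKDTree(pts)
    keep = np.ones(len(merged), dtype=bool)
    for i in range(len(merged)):
        if not keep[i]:
            continue
        for j in tree.query_ball_point(pts[i], radius_px):
            if j > i:
                keep[j] = False
    out = merged[keep].reset_index(drop=True)
    if pitch_um is not None:
        out["x_um"] = out["x_px"] * pitch_um
        out["y_um"] = out["y_px"] * pitch_um
    return out
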