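"""Synthetic data with known ground truth.

This module emulates the statistical structure of the platform's raw data so
that every downstream operation can be benchmarked against a known answer:

* raw camera frames: flat-top illumination with a smooth gain inhomogeneity,
  Poisson shot noise (optionally averaged over ``n_averaged`` raw exposures,
  mirroring how the instrument saves 100-frame averages), and
  diffraction-limited spots of prescribed fractional contrast at random
  sub-pixel positions;
* raster-scanned tile grids with configurable overlap and stage jitter;
* Langmuir immunocapture binding time courses;
* chip x marker capture-density matrices for EV fingerprinting, with
  non-specific background on every channel and an isotype-control (IgG1)
  channel that sees only the non-specific component.

All random draws derive from a single seed via ``numpy`` seed sequences, with
one child stream per tile, so identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .instrument import DEFAULT_INSTRUMENT, InstrumentConfig

SPOT_CLASSES = ("substrate_defect", "liposome", "particle", "EV")

TRUTH_COLUMNS = ["x_px", "y_px", "contrast", "class_label", "in_frame"]


@dataclass(frozen=True)
class GroundTruthSpot:
    """A seeded diffraction-limited spot.

    ``x``/``y`` are 0-based pixel coordinates (x = column index) and may be
    fractional; ``contrast`` is the peak fractional amplitude relative to the
    local background.
    """

    x: float
    y: float
    contrast: float
    class_label: str = "particle"

    def __post_init__(self) -> None:
        if self.contrast <= 0:
            raise ValueError("contrast must be strictly positive")
        if self.class_label not in SPOT_CLASSES:
            raise ValueError(f"class_label must be one of {SPOT_CLASSES}")


def render_spot(contrast: float,
                position: tuple[float, float],
                cfg: InstrumentConfig = DEFAULT_INSTRUMENT,
                radius: int | None = None) -> tuple[np.ndarray, tuple[int, int]]:
    """Render one spot as an additive fractional-amplitude stamp.

    The in-focus PSF is approximated by a 2D Gaussian with
    sigma = 0.21 lambda / NA (about 1 px at the default geometry).  The stamp
    holds dimensionless fractional amplitudes: a frame simulator multiplies it
    by the local background so that the rendered peak equals
    ``contrast x background``.

    Parameters
    ----------
    contrast:
        Peak fractional amplitude (> 0).
    position:
        (x, y) sub-pixel spot centre, x = column.
    radius:
        Half-size of the stamp in pixels; default covers 4 sigma.

    Returns
    -------
    (stamp, (row0, col0)):
        The stamp array and the frame coordinates of its top-left pixel.
    """
    if contrast <= 0:
        raise ValueError("contrast must be strictly positive")
    x, y = float(position[0]), float(position[1])
    sigma = cfg.psf_sigma_px
    if radius is None:
        radius = int(math.ceil(4.0 * sigma)) + 1
    cx, cy = int(round(x)), int(round(y))
    row0, col0 = cy - radius, cx - radius
    n = 2 * radius + 1
    yy, xx = np.mgrid[row0:row0 + n, col0:col0 + n]
    r2 = (xx - x) ** 2 + (yy - y) ** 2
    stamp = contrast * np.exp(-r2 / (2.0 * sigma ** 2))
    return stamp, (row0, col0)


def gain_field(shape: tuple[int, int],
               rng: np.random.Generator,
               amplitude: float = 0.10,
               vignette_depth: float = 0.05) -> np.ndarray:
    """Smooth, strictly positive illumination/optical-path gain field.

    A sum of up to three low-order 2D polynomials (normalised to unit peak
    deviation, scaled by ``amplitude``) plus a circular flat-top vignette
    mimics gain inhomogeneities of the optical system and imperfections in
    the sample illumination.
    """
    ny, nx = shape
    yv = np.linspace(-1.0, 1.0, ny)[:, None]
    xv = np.linspace(-1.0, 1.0, nx)[None, :]
    coeffs = rng.uniform(-1.0, 1.0, size=3)
    poly = coeffs[0] * xv + coeffs[1] * yv + coeffs[2] * (xv * yv)
    peak = np.abs(poly).max()
    if peak > 0:
        poly = poly / peak
    r = np.hypot(xv, yv)
    # flat-top vignette: flat inside ~70% of the half-diagonal, smooth roll-off
    edge = np.clip((r - 0.7) / 0.6, 0.0, 1.0)
    vignette = 1.0 - vignette_depth * edge ** 2 * (3 - 2 * edge)
    gain = (1.0 + amplitude * poly) * vignette
    if gain.min() <= 0:
        raise ValueError("gain field not strictly positive; reduce amplitude")
    return gain


def _truth_frame(records: list[dict]) -> pd.DataFrame:
    if not records:
        return pd.DataFrame(columns=TRUTH_COLUMNS)
    return pd.DataFrame.from_records(records, columns=TRUTH_COLUMNS)


def simulate_frame(spots: list[GroundTruthSpot],
                   cfg: InstrumentConfig = DEFAULT_INSTRUMENT,
                   gain: np.ndarray | None = None,
                   shot_noise: bool = True,
                   n_averaged: int = 1,
                   seed: int | None = None,
                   rng: np.random.Generator | None = None,
                   ) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate one raw (optionally time-averaged) camera frame.

    The noiseless mean is ``background_counts * gain * (1 + sum of stamps)``.
    With ``shot_noise`` on, the returned frame is the mean of ``n_averaged``
    independent Poisson exposures (drawn exactly as Poisson(n * mean)/n),
    matching instruments that save time-averaged frames.

    Spots whose centre lies outside the frame are not rendered; they are kept
    in the truth table with ``in_frame = False`` and a warning is emitted.

    Returns the frame (float64 counts) and the truth table.
    """
    if n_averaged < 1:
        raise ValueError("n_averaged must be >= 1")
    shape = tuple(cfg.frame_shape)
    if gain is None:
        gain = np.ones(shape)
    gain = np.asarray(gain, dtype=float)
    if gain.shape != shape:
        raise ValueError("gain field shape must match frame_shape")
    if gain.min() <= 0:
        raise ValueError("gain field must be strictly positive")
    if rng is None:
        rng = np.random.default_rng(seed)

    fractional = np.zeros(shape)
    records = []
    n_out = 0
    for s in spots:
        in_frame = (0 <= s.x <= shape[1] - 1) and (0 <= s.y <= shape[0] - 1)
        records.append(dict(x_px=s.x, y_px=s.y, contrast=s.contrast,
                            class_label=s.class_label, in_frame=in_frame))
        if not in_frame:
            n_out += 1
            continue
        stamp, (row0, col0) = render_spot(s.contrast, (s.x, s.y), cfg)
        r0, c0 = max(row0, 0), max(col0, 0)
        r1 = min(row0 + stamp.shape[0], shape[0])
        c1 = min(col0 + stamp.shape[1], shape[1])
        if r1 > r0 and c1 > c0:
            fractional[r0:r1, c0:c1] += stamp[r0 - row0:r1 - row0, c0 - col0:c1 - col0]
    if n_out:
        warnings.warn(f"{n_out} spot(s) outside the frame were not rendered",
                      stacklevel=2)

    mean = cfg.background_counts * gain * (1.0 + fractional)
    if shot_noise:
        frame = rng.poisson(n_averaged * mean).astype(float) / n_averaged
    else:
        frame = mean
    return frame, _truth_frame(records)


def random_spots(n: int,
                 shape: tuple[int, int],
                 rng: np.random.Generator,
                 contrast_sampler,
                 min_separation_px: float = 0.0,
                 margin_px: float = 2.0,
                 class_label: str = "particle") -> list[GroundTruthSpot]:
    """Draw ``n`` uniformly placed spots, optionally enforcing a minimum
    pairwise separation (rejection sampling; used for isolated-spot suites)."""
    spots: list[GroundTruthSpot] = []
    xs: list[float] = []
    ys: list[float] = []
    attempts = 0
    while len(spots) < n:
        attempts += 1
        if attempts > 1000 * max(n, 1):
            raise RuntimeError("could not place spots with requested separation")
        x = rng.uniform(margin_px, shape[1] - 1 - margin_px)
        y = rng.uniform(margin_px, shape[0] - 1 - margin_px)
        if min_separation_px > 0 and xs:
            d2 = (np.array(xs) - x) ** 2 + (np.array(ys) - y) ** 2
            if d2.min() < min_separation_px ** 2:
                continue
        xs.append(x)
        ys.append(y)
        spots.append(GroundTruthSpot(x=x, y=y, contrast=float(contrast_sampler(rng)),
                                     class_label=class_label))
    return spots


def lognormal_contrast(mu: float, sigma: float):
    """Contrast sampler: log-normal law; degenerate (sigma = 0) gives exp(mu)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")

    def sample(rng: np.random.Generator) -> float:
        if sigma == 0:
            return math.exp(mu)
        return float(rng.lognormal(mu, sigma))

    return sample


@dataclass
class SimulatedScan:
    """A raster scan of overlapping tiles with exact ground truth.

    ``tiles`` are simulated frames; ``nominal_offsets`` are the (row, col)
    pixel positions the stage reports, ``true_offsets`` where the tiles
    actually sit (nominal plus jitter).  ``truth`` is the global spot table in
    mosaic pixel coordinates (one row per unique seeded spot); ``tile_truth``
    lists, per tile, the spots whose centre falls inside that tile, in
    tile-local coordinates.
    """

    tiles: list[np.ndarray]
    nominal_offsets: np.ndarray
    true_offsets: np.ndarray
    truth: pd.DataFrame
    tile_truth: list[pd.DataFrame]
    gain: np.ndarray
    cfg: InstrumentConfig
    seed: int | None
    mosaic_shape: tuple[int, int]

    @property
    def scanned_area_mm2(self) -> float:
        h, w = self.mosaic_shape
        return h * w * self.cfg.pitch_um ** 2 * 1e-6

    @property
    def seeded_density_per_100um2(self) -> float:
        """Seeded spot count per 100 um^2 of scanned (mosaic) area."""
        area_units = self.mosaic_shape[0] * self.mosaic_shape[1] \
            * self.cfg.pitch_um ** 2 / 100.0
        return len(self.truth) / area_units


def simulate_scan(channel_area_mm2: float,
                  spot_density_per_100um2: float,
                  contrast_law: tuple[float, float] = (math.log(0.03), 0.5),
                  cfg: InstrumentConfig = DEFAULT_INSTRUMENT,
                  overlap: float = 0.1,
                  offset_jitter_px: int = 3,
                  gain_amplitude: float = 0.10,
                  shot_noise: bool = True,
                  n_averaged: int = 100,
                  class_label: str = "particle",
                  seed: int | None = None) -> SimulatedScan:
    """Simulate a tile scan covering (at least) ``channel_area_mm2``.

    Spots are seeded as a homogeneous Poisson process over the mosaic with the
    requested density (counts per 100 um^2); their contrasts follow a
    log-normal law ``contrast_law = (mu, sigma)``.  Adjacent tiles overlap by
    ``overlap`` of the frame; true tile positions are jittered by up to
    ``offset_jitter_px`` pixels around the nominal raster grid, which is what
    phase-correlation stitching has to recover.  A single camera-fixed gain
    field multiplies every tile.
    """
    if channel_area_mm2 <= 0:
        raise ValueError("channel_area_mm2 must be > 0")
    if spot_density_per_100um2 < 0:
        raise ValueError("spot density must be >= 0")
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must be in [0, 1)")

    shape = tuple(cfg.frame_shape)
    stride = (max(1, int(round(shape[0] * (1.0 - overlap)))),
              max(1, int(round(shape[1] * (1.0 - overlap)))))
    area_um2 = channel_area_mm2 * 1e6
    if area_um2 <= cfg.fov_area_um2:
        if area_um2 < cfg.fov_area_um2:
            warnings.warn("requested area smaller than one field of view; "
                          "producing a single-tile scan", stacklevel=2)
        n_rows = n_cols = 1
    else:
        # near-square grid, smallest cover of the requested area
        def mosaic_px(n, axis):
            return shape[axis] + (n - 1) * stride[axis]

        n_rows = n_cols = 1
        while (mosaic_px(n_rows, 0) * mosaic_px(n_cols, 1)) * cfg.pitch_um ** 2 < area_um2:
            if mosaic_px(n_rows, 0) <= mosaic_px(n_cols, 1):
                n_rows += 1
            else:
                n_cols += 1

    ss = np.random.SeedSequence(seed)
    scene_rng = np.random.default_rng(ss.spawn(1)[0])
    tile_seeds = ss.spawn(n_rows * n_cols)

    nominal = np.array([(r * stride[0], c * stride[1])
                        for r in range(n_rows) for c in range(n_cols)], dtype=int)
    if offset_jitter_px > 0 and len(nominal) > 1:
        jitter = scene_rng.integers(-offset_jitter_px, offset_jitter_px + 1,
                                    size=nominal.shape)
        jitter[0] = 0  # anchor the first tile
    else:
        jitter = np.zeros_like(nominal)
    true_off = nominal + jitter

    mosaic_shape = (int(true_off[:, 0].max()) + shape[0],
                    int(true_off[:, 1].max()) + shape[1])
    mosaic_area_units = mosaic_shape[0] * mosaic_shape[1] * cfg.pitch_um ** 2 / 100.0
    n_spots = int(scene_rng.poisson(spot_density_per_100um2 * mosaic_area_units))
    sampler = lognormal_contrast(*contrast_law)
    gx = scene_rng.uniform(0, mosaic_shape[1] - 1, size=n_spots)
    gy = scene_rng.uniform(0, mosaic_shape[0] - 1, size=n_spots)
    contrasts = np.array([sampler(scene_rng) for _ in range(n_spots)])
    truth = pd.DataFrame({"x_px": gx, "y_px": gy, "contrast": contrasts,
                          "class_label": class_label, "in_frame": True})

    gain = gain_field(shape, scene_rng, amplitude=gain_amplitude)

    tiles: list[np.ndarray] = []
    tile_truth: list[pd.DataFrame] = []
    for k, (orow, ocol) in enumerate(true_off):
        lx = gx - ocol
        ly = gy - orow
        margin = 6.0
        render = (lx > -margin) & (lx < shape[1] - 1 + margin) \
            & (ly > -margin) & (ly < shape[0] - 1 + margin)
        spots = [GroundTruthSpot(x=float(lx[i]), y=float(ly[i]),
                                 contrast=float(contrasts[i]),
                                 class_label=class_label)
                 for i in np.flatnonzero(render)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # partially-rendered edge spots
            frame, local_truth = simulate_frame(
                spots, cfg, gain=gain, shot_noise=shot_noise,
                n_averaged=n_averaged,
                rng=np.random.default_rng(tile_seeds[k]))
        tiles.append(frame)
        inside = local_truth[local_truth["in_frame"]].reset_index(drop=True)
        tile_truth.append(inside)

    return SimulatedScan(tiles=tiles, nominal_offsets=nominal,
                         true_offsets=true_off, truth=truth,
                         tile_truth=tile_truth, gain=gain, cfg=cfg, seed=seed,
                         mosaic_shape=mosaic_shape)


def simulate_flatfield_stack(n_frames: int,
                             cfg: InstrumentConfig = DEFAULT_INSTRUMENT,
                             gain: np.ndarray | None = None,
                             spots_per_frame: int = 50,
                             contrast_law: tuple[float, float] = (math.log(0.03), 0.5),
                             shot_noise: bool = True,
                             n_averaged: int = 100,
                             seed: int | None = None) -> list[np.ndarray]:
    """Frames at distinct sample locations sharing one gain field, for
    flat-field construction: each frame carries its own random sparse spots,
    which a pixel-wise median across the stack must reject."""
    ss = np.random.SeedSequence(seed)
    top = np.random.default_rng(ss.spawn(1)[0])
    if gain is None:
        gain = gain_field(tuple(cfg.frame_shape), top)
    sampler = lognormal_contrast(*contrast_law)
    frames = []
    for child in ss.spawn(n_frames):
        rng = np.random.default_rng(child)
        spots = random_spots(spots_per_frame, tuple(cfg.frame_shape), rng, sampler)
        frame, _ = simulate_frame(spots, cfg, gain=gain, shot_noise=shot_noise,
                                  n_averaged=n_averaged, rng=rng)
        frames.append(frame)
    return frames


# ---------------------------------------------------------------------------
# Binding kinetics
# ---------------------------------------------------------------------------

def langmuir_mean(t_h: np.ndarray,
                  concentration: float,
                  n_max: float,
                  k_on: float,
                  k_off: float) -> np.ndarray:
    """Expected bound count under irreversible-read-out Langmuir kinetics.

    N(t) = N_eq (1 - exp(-t/tau)) with N_eq = N_max C/(C+K), K = k_off/k_on
    and tau = 1/(k_on C + k_off).  ``k_on`` is an effective association rate
    per (concentration unit) per hour; ``k_off`` per hour.
    """
    t = np.asarray(t_h, dtype=float)
    if np.any(t < 0):
        raise ValueError("timepoints must be non-negative")
    if min(concentration, n_max, k_on) < 0 or k_off < 0:
        raise ValueError("rates, capacity and concentration must be >= 0")
    rate = k_on * concentration + k_off
    if rate == 0:
        return np.zeros_like(t)
    n_eq = n_max * (k_on * concentration) / rate
    return n_eq * (1.0 - np.exp(-rate * t))


def rates_from_equilibrium(concentration: float, k_half: float,
                           tau_h: float) -> tuple[float, float]:
    """Convert (half-saturation K, relaxation time tau at concentration C)
    into the (k_on, k_off) pair used by :func:`langmuir_mean`."""
    if tau_h <= 0:
        raise ValueError("tau must be > 0")
    k_on = 1.0 / (tau_h * (concentration + k_half))
    return k_on, k_half * k_on


def simulate_binding(concentration: float,
                     n_max: float,
                     k_on: float,
                     k_off: float,
                     timepoints_h,
                     shot_noise: bool = True,
                     flow_rate_ul_h: float | None = None,
                     channel_id: str | None = None,
                     seed: int | None = None):
    """Simulate a captured-particle time course.

    Observed counts are Poisson around the Langmuir mean (noiseless with
    ``shot_noise=False``); the mean is monotone non-decreasing in time.
    Returns a :class:`iscatflow.kinetics.BindingSeries`.
    """
    from .kinetics import BindingSeries  # local import to avoid a cycle

    t = np.asarray(timepoints_h, dtype=float)
    mean = langmuir_mean(t, concentration, n_max, k_on, k_off)
    if shot_noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(mean).astype(float)
    else:
        counts = mean
    return BindingSeries(timepoints_h=t, counts=counts,
                         concentration=concentration,
                         flow_rate_ul_h=flow_rate_ul_h, channel_id=channel_id)


# ---------------------------------------------------------------------------
# Fingerprint datasets
# ---------------------------------------------------------------------------

ISOTYPE_CONTROL = "IgG1"
TETRASPANINS = ("CD9", "CD63", "CD81")


def simulate_fingerprint_dataset(expression: pd.DataFrame,
                                 nonspecific_per_100um2: float,
                                 n_chips: int = 3,
                                 area_100um2: float = 2000.0,
                                 seed: int | None = None) -> pd.DataFrame:
    """Simulate raw capture-density fingerprints for several cell lines.

    ``expression`` is a cell-line x marker table of mean *specific* capture
    densities (counts per 100 um^2); the marker panel must contain the three
    tetraspanins (CD9, CD63, CD81).  Every channel additionally captures a
    non-specific background; the isotype-control channel (IgG1, added
    automatically if absent) captures only that background.  Per chip and
    marker the observed density is Poisson(area x (expression + nonspecific))
    divided by the scanned area (default 0.2 mm^2 = 2000 units of 100 um^2).

    Returns a tidy DataFrame with ``n_chips`` replicate rows per cell line,
    a ``cell_line`` column and one column per marker, suitable for
    :func:`iscatflow.fingerprint.FingerprintMatrix.from_frame`.
    """
    if nonspecific_per_100um2 < 0:
        raise ValueError("nonspecific density must be >= 0")
    if (expression.to_numpy() < 0).any():
        raise ValueError("expression densities must be >= 0")
    if n_chips < 1:
        raise ValueError("n_chips must be >= 1")
    markers = [m for m in expression.columns if m != ISOTYPE_CONTROL]
    missing = [m for m in TETRASPANINS if m not in markers]
    if missing:
        raise ValueError(f"marker panel must include the tetraspanins; missing {missing}")

    rng = np.random.default_rng(seed)
    rows = []
    for cell_line, expr in expression.iterrows():
        for _ in range(n_chips):
            row = {"cell_line": cell_line}
            row[ISOTYPE_CONTROL] = rng.poisson(
                area_100um2 * nonspecific_per_100um2) / area_100um2
            for m in markers:
                lam = area_100um2 * (float(expr[m]) + nonspecific_per_100um2)
                row[m] = rng.poisson(lam) / area_100um2
            rows.append(row)
    return pd.DataFrame(rows, columns=["cell_line", ISOTYPE_CONTROL, *markers])
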