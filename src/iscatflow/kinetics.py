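"""Time-resolved binding analysis.

Captured-particle counts N(t) in an immunocapture channel follow, to a good
approximation, first-order Langmuir kinetics towards an equilibrium level
set by the analyte concentration C:

    N(t) = N_eq (1 - exp(-t/tau)),    N_eq(C) = N_max C / (C + K),

with N_max the surface capacity and K the half-saturation concentration.
This module assembles binding series from time-ordered scans, finds the
steady state, fits the equilibrium dose-response to the Langmuir isotherm,
estimates the linear (low-concentration) range, and resolves intra-channel
density gradients along the flow direction -- the signature of
mass-transport-limited capture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge."""


@dataclass
class BindingSeries:
    """Bound-particle counts versus time for one channel."""

    timepoints_h: np.ndarray
    counts: np.ndarray
    concentration: float  # particles/mL
    flow_rate_ul_h: float | None = None
    channel_id: str | None = None

    def __post_init__(self) -> None:
        self.timepoints_h = np.asarray(self.timepoints_h, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.timepoints_h.shape != self.counts.shape:
            raise ValueError("timepoints and counts must have the same length")
        if np.any(np.diff(self.timepoints_h) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(self.timepoints_h < 0):
            raise ValueError("timepoints must be non-negative")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")


def binding_series(scans: list[pd.DataFrame],
                   timepoints_h,
                   concentration: float,
                   flow_rate_ul_h: float | None = None,
                   channel_id: str | None = None,
                   label: str = "signal") -> BindingSeries:
    """Assemble a binding series from time-ordered classified scan tables.

    Counts are the number of ``label``-class localisations per scan (tables
    without a label column are counted whole).
    """
    t = np.asarray(timepoints_h, dtype=float)
    if len(scans) != len(t):
        raise ValueError("one scan table per timepoint required")
    counts = []
    for s in scans:
        if "label" in s.columns:
            counts.append(int((s["label"] == label).sum()))
        else:
            counts.append(len(s))
    return BindingSeries(timepoints_h=t, counts=np.asarray(counts, dtype=float),
                         concentration=concentration,
                         flow_rate_ul_h=flow_rate_ul_h, channel_id=channel_id)


def detect_steady_state(series: BindingSeries,
                        window_h: float = 2.0,
                        tol: float = 0.05) -> float | None:
    """Earliest time after which the series has plateaued.

    Operational rule: at the earliest timepoint t_i such that, for every
    later window start t_k >= t_i, the counts within [t_k, t_k + window]
    span less than ``tol`` of their window mean, the series is declared
    steady.  Returns that t_i, or None if the criterion is never met.
    """
    t, n = series.timepoints_h, series.counts
    if len(t) < 3:
        raise ValueError("need at least 3 timepoints")
    eps = 1e-12
    flat = np.zeros(len(t), dtype=bool)
    eligible = np.zeros(len(t), dtype=bool)
    for i in range(len(t)):
        in_win = (t >= t[i]) & (t <= t[i] + window_h + 1e-9)
        vals = n[in_win]
        if len(vals) < 2:
            continue  # trailing window with a single point: no change observable
        eligible[i] = True
        ref = max(vals.mean(), eps)
        flat[i] = (vals.max() - vals.min()) / ref < tol
    if not eligible.any():
        return None
    # earliest index from which every later *eligible* window is flat
    ok_from_here = np.flip(np.logical_and.accumulate(
        np.flip(np.where(eligible, flat, True))))
    idx = np.flatnonzero(ok_from_here & eligible)
    return float(t[idx[0]]) if idx.size else None


@dataclass
class LangmuirFit:
    """Langmuir isotherm fit N(C) = N_max C / (C + K)."""

    n_max: float
    k_half: float  # particles/mL at half saturation
    covariance: np.ndarray
    r_squared: float

    def predict(self, concentration) -> np.ndarray:
        c = np.asarray(concentration, dtype=float)
        return self.n_max * c / (c + self.k_half)


def fit_langmuir(concentrations, counts) -> LangmuirFit:
    """Nonlinear least-squares Langmuir fit of an equilibrium dose-response.

    Parameters are constrained positive; initial guesses are
    N_max = max(counts) and K = median(concentrations).
    """
    c = np.asarray(concentrations, dtype=float)
    n = np.asarray(counts, dtype=float)
    if len(np.unique(c)) < 3:
        raise ValueError("need >= 3 distinct concentrations")

    def model(cc, n_max, k):
        return n_max * cc / (cc + k)

    p0 = (max(n.max(), 1e-12), max(np.median(c), 1e-12))
    try:
        popt, pcov = optimize.curve_fit(model, c, n, p0=p0,
                                        bounds=([0.0, 1e-300], [np.inf, np.inf]),
                                        maxfev=20000)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"Langmuir fit did not converge: {exc}") from exc
    resid = n - model(c, *popt)
    ss_tot = ((n - n.mean()) ** 2).sum()
    r2 = 1.0 - (resid ** 2).sum() / ss_tot if ss_tot > 0 else 1.0
    return LangmuirFit(n_max=float(popt[0]), k_half=float(popt[1]),
                       covariance=pcov, r_squared=float(r2))


@dataclass
class LinearRange:
    slope: float  # counts per (particles/mL)
    r_squared: float
    upper_concentration: float
    n_points: int


def linear_range(concentrations, counts,
                 r2_threshold: float = 0.99) -> LinearRange:
    """Largest low-concentration prefix that is linear through the origin.

    Points are sorted by concentration; the longest prefix (>= 3 points)
    whose zero-intercept least-squares fit keeps R^2 at or above the
    threshold defines the linear range.  If no prefix qualifies the whole
    range is fitted and a warning is emitted.
    """
    c = np.asarray(concentrations, dtype=float)
    n = np.asarray(counts, dtype=float)
    if len(c) < 3:
        raise ValueError("need >= 3 points")
    order = np.argsort(c)
    c, n = c[order], n[order]

    def zero_intercept(cc, nn):
        slope = (cc * nn).sum() / (cc * cc).sum()
        resid = nn - slope * cc
        ss_tot = ((nn - nn.mean()) ** 2).sum()
        r2 = 1.0 - (resid ** 2).sum() / ss_tot if ss_tot > 0 else 1.0
        return slope, r2

    for k in range(len(c), 2, -1):
        slope, r2 = zero_intercept(c[:k], n[:k])
        if r2 >= r2_threshold:
            return LinearRange(slope=float(slope), r_squared=float(r2),
                               upper_concentration=float(c[k - 1]), n_points=k)
    slope, r2 = zero_intercept(c, n)
    warnings.warn("no prefix met the linearity threshold; "
                  "returning the whole-range fit", stacklevel=2)
    return LinearRange(slope=float(slope), r_squared=float(r2),
                       upper_concentration=float(c[-1]), n_points=len(c))


def spatial_gradient(table: pd.DataFrame,
                     extent_px: float,
                     pitch_um: float,
                     n_segments: int = 10,
                     flow_axis: str = "x",
                     cross_extent_px: float | None = None) -> pd.DataFrame:
    """Per-segment localisation densities along the flow direction.

    The scan is cut into ``n_segments`` equal-length segments along
    ``flow_axis`` ('x' or 'y', mosaic coordinates); segment 1 is the channel
    entrance (lowest coordinate).  Densities are counts per 100 um^2 using
    the segment area = segment length x cross extent.  Under mass-transport
    limitation the density decays from entrance to exit.
    """
    if n_segments < 2:
        raise ValueError("need >= 2 segments")
    if flow_axis not in ("x", "y"):
        raise ValueError("flow_axis must be 'x' or 'y'")
    coord = table[f"{flow_axis}_px"].to_numpy(dtype=float)
    other = "y_px" if flow_axis == "x" else "x_px"
    if cross_extent_px is None:
        cross_extent_px = float(table[other].max() - table[other].min()) \
            if len(table) else 0.0
    seg_len = extent_px / n_segments
    seg_area_units = seg_len * cross_extent_px * pitch_um ** 2 / 100.0
    idx = np.clip((coord / seg_len).astype(int), 0, n_segments - 1)
    counts = np.bincount(idx, minlength=n_segments)
    density = counts / seg_area_units if seg_area_units > 0 else \
        np.full(n_segments, np.nan)
    return pd.DataFrame({"segment": np.arange(1, n_segments + 1),
                         "n": counts, "density_per_100um2": density})


def langmuir_equilibrium(concentration, n_max: float, k_half: float) -> np.ndarray:
    """Equilibrium Langmuir occupancy N_eq = N_max C / (C + K)."""
    c = np.asarray(concentration, dtype=float)
    return n_max * c / (c + k_half)
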