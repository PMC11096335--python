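"""Contrast classification, defect densities and replicate statistics.

Localisations are split by a contrast cut-off (default 7.5e-3) into a
*background* class -- substrate roughness and minute inhomogeneities, which
occupy a narrow low-contrast band -- and a *signal* class above it.  Counts
are reported as densities per 100 um^2 (a 10 x 10 um^2 reference area), which
makes scans of different sizes and instruments with different fields of view
comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_CONTRAST_CUTOFF = 7.5e-3

BACKGROUND, SIGNAL = "background", "signal"


@dataclass(frozen=True)
class ContrastCutoff:
    value: float = DEFAULT_CONTRAST_CUTOFF

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("cut-off must be > 0")


@dataclass
class ChannelScanSummary:
    """Per-channel counts and densities split by contrast class."""

    channel_id: str | None
    scanned_area_mm2: float
    n_background: int
    n_signal: int
    density_background: float  # counts per 100 um^2
    density_signal: float
    median_contrast: float


def classify_contrast(table: pd.DataFrame,
                      cutoff: ContrastCutoff | float = DEFAULT_CONTRAST_CUTOFF
                      ) -> pd.DataFrame:
    """Label each localisation background/signal by its peak contrast.

    A contrast exactly at the cut-off is classified as background (the
    conservative tie rule: fewer false signal counts).
    """
    value = cutoff.value if isinstance(cutoff, ContrastCutoff) else float(cutoff)
    if value <= 0:
        raise ValueError("cut-off must be > 0")
    if (table["peak_contrast"] <= 0).any():
        raise ValueError("peak contrasts must be > 0")
    out = table.copy()
    out["label"] = np.where(out["peak_contrast"] > value, SIGNAL, BACKGROUND)
    return out


def defect_density(table: pd.DataFrame, area_mm2: float,
                   channel_id: str | None = None) -> ChannelScanSummary:
    """Per-class counts and densities (per 100 um^2) over a scanned area."""
    if area_mm2 <= 0:
        raise ValueError("scanned area must be > 0")
    if "label" not in table.columns:
        raise ValueError("table must be classified first (classify_contrast)")
    area_units = area_mm2 * 1e6 / 100.0  # number of 100-um^2 cells
    n_bg = int((table["label"] == BACKGROUND).sum())
    n_sig = int((table["label"] == SIGNAL).sum())
    median_c = float(table["peak_contrast"].median()) if len(table) else float("nan")
    return ChannelScanSummary(channel_id=channel_id, scanned_area_mm2=area_mm2,
                              n_background=n_bg, n_signal=n_sig,
                              density_background=n_bg / area_units,
                              density_signal=n_sig / area_units,
                              median_contrast=median_c)


@dataclass
class ContrastHistogram:
    counts: np.ndarray
    bin_edges: np.ndarray
    kde_x: np.ndarray | None
    kde_y: np.ndarray | None


def contrast_histogram(table: pd.DataFrame, bins: int = 40,
                       log_bins: bool = True,
                       kde: bool = True) -> ContrastHistogram:
    """Histogram (log-spaced bins by default) plus a kernel-density curve of
    per-particle peak contrasts."""
    values = table["peak_contrast"].to_numpy(dtype=float) if len(table) else \
        np.empty(0)
    if len(values) == 0:
        warnings.warn("empty localisation table: empty histogram", stacklevel=2)
        return ContrastHistogram(np.empty(0), np.empty(0), None, None)
    if log_bins:
        edges = np.logspace(np.log10(values.min()) - 1e-9,
                            np.log10(values.max()) + 1e-9, bins + 1)
    else:
        edges = np.linspace(values.min(), values.max() + 1e-12, bins + 1)
    counts, edges = np.histogram(values, bins=edges)
    kde_x = kde_y = None
    if kde and len(values) > 2 and np.ptp(np.log10(values)) > 0:
        logv = np.log10(values)
        density = stats.gaussian_kde(logv)
        kde_x = np.logspace(logv.min(), logv.max(), 200)
        kde_y = density(np.log10(kde_x))
    return ContrastHistogram(counts=counts, bin_edges=edges,
                             kde_x=kde_x, kde_y=kde_y)


@dataclass
class ReplicateStat:
    value: float
    sem: float | None
    n: int
    statistic: str


def aggregate_replicates(values, statistic: str = "mean") -> ReplicateStat:
    """Group statistic (mean or median) with SEM = sd/sqrt(N).

    With a single replicate the SEM is undefined and reported as None.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 1:
        raise ValueError("need at least one replicate")
    if statistic == "mean":
        centre = float(arr.mean())
    elif statistic == "median":
        centre = float(np.median(arr))
    else:
        raise ValueError("statistic must be 'mean' or 'median'")
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else None
    return ReplicateStat(value=centre, sem=sem, n=int(arr.size),
                         statistic=statistic)


def one_way_anova(groups) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value across groups.

    Degenerate input (all observations identical) returns (F=0, p=1) instead
    of the 0/0 indeterminate form.
    """
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    grand = np.concatenate(arrays)
    if np.ptp(grand) == 0:
        return 0.0, 1.0
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ss_between = sum(a.size * (a.mean() - grand.mean()) ** 2 for a in arrays)
    df_between = len(arrays) - 1
    df_within = grand.size - len(arrays)
    if ss_within == 0:
        return float("inf"), 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return float(f), p
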