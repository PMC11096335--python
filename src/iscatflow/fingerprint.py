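"""EV surface-marker fingerprints.

Each microfluidic channel of a chip captures particles through a different
antibody; the per-channel capture densities over a marker panel form the
chip's *fingerprint*.  Two corrections make fingerprints comparable across
chips and samples:

1. the isotype-control (IgG1) density -- non-specific binding -- is
   subtracted marker-by-marker on a chip-by-chip basis;
2. each fingerprint is normalised to the mean of the three pan-EV
   tetraspanin markers (CD9, CD63, CD81), making it invariant to the overall
   particle concentration and flow rate.

Normalised fingerprints are then compared by a 2-component PCA projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

ISOTYPE_CONTROL = "IgG1"
TETRASPANINS = ("CD9", "CD63", "CD81")
CANCER_MARKERS = ("CD326", "HE4", "CA125")

RAW, CONTROL_SUBTRACTED, NORMALISED = "raw", "control_subtracted", "normalised"


@dataclass
class FingerprintMatrix:
    """Chip-replicate x marker capture densities with a processing stage.

    ``frame`` holds one row per chip replicate, a ``cell_line`` column (or
    any sample label) and one column per marker; ``stage`` is one of
    raw / control_subtracted / normalised.
    """

    frame: pd.DataFrame
    stage: str = RAW

    def __post_init__(self) -> None:
        if ISOTYPE_CONTROL not in self.frame.columns:
            raise ValueError(f"{ISOTYPE_CONTROL} (isotype control) column required")
        if self.stage == RAW and (self.frame[self.markers] < 0).to_numpy().any():
            raise ValueError("raw densities must be >= 0")

    @property
    def markers(self) -> list[str]:
        return [c for c in self.frame.columns if c != "cell_line"]

    @property
    def specific_markers(self) -> list[str]:
        return [m for m in self.markers if m != ISOTYPE_CONTROL]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, stage: str = RAW) -> "FingerprintMatrix":
        return cls(frame=frame.copy(), stage=stage)


def subtract_control(matrix: FingerprintMatrix) -> FingerprintMatrix:
    """Subtract each chip's isotype-control density from every marker.

    Negative results are floored at zero (a marker cannot be captured less
    than not at all); the IgG1 column itself is retained for QC.
    """
    if matrix.stage != RAW:
        raise ValueError("control subtraction applies to the raw stage")
    out = matrix.frame.copy()
    igg = out[ISOTYPE_CONTROL].to_numpy(dtype=float)
    for m in matrix.specific_markers:
        out[m] = np.maximum(out[m].to_numpy(dtype=float) - igg, 0.0)
    return FingerprintMatrix(frame=out, stage=CONTROL_SUBTRACTED)


def normalise_tetraspanin(matrix: FingerprintMatrix) -> FingerprintMatrix:
    """Divide every marker by the row's mean tetraspanin density.

    After this step the mean of (CD9, CD63, CD81) is exactly 1 in every row,
    and the fingerprint is invariant to global density rescaling
    (concentration or flow-rate differences between chips).
    """
    if matrix.stage != CONTROL_SUBTRACTED:
        raise ValueError("normalisation applies to the control-subtracted stage")
    missing = [m for m in TETRASPANINS if m not in matrix.frame.columns]
    if missing:
        raise ValueError(f"tetraspanin columns missing: {missing}")
    out = matrix.frame.copy()
    tetra_mean = out[list(TETRASPANINS)].mean(axis=1).to_numpy(dtype=float)
    if (tetra_mean <= 0).any():
        bad = np.flatnonzero(tetra_mean <= 0)
        raise ValueError(f"zero tetraspanin mean in row(s) {bad.tolist()}: "
                         "normalisation undefined")
    for m in matrix.markers:
        out[m] = out[m].to_numpy(dtype=float) / tetra_mean
    return FingerprintMatrix(frame=out, stage=NORMALISED)


POSITIVE, NOT_DISTINGUISHABLE = "positive", "not-distinguishable"


def positivity_call(matrix_raw: FingerprintMatrix, marker: str,
                    k: float = 2.0) -> str:
    """Call a marker positive when it clears the non-specific level.

    Rule: mean raw marker density across chip replicates exceeds the IgG1
    mean + k x SD(IgG1) (default k = 2).  With a single replicate the SD is
    unavailable; the call compares the means and warns.
    """
    if matrix_raw.stage != RAW:
        raise ValueError("positivity is called on raw densities")
    if marker not in matrix_raw.frame.columns:
        raise ValueError(f"unknown marker {marker!r}")
    vals = matrix_raw.frame[marker].to_numpy(dtype=float)
    igg = matrix_raw.frame[ISOTYPE_CONTROL].to_numpy(dtype=float)
    if len(vals) < 2:
        warnings.warn("single replicate: positivity call without an SD",
                      stacklevel=2)
        threshold = igg.mean()
    else:
        threshold = igg.mean() + k * igg.std(ddof=1)
    return POSITIVE if vals.mean() > threshold else NOT_DISTINGUISHABLE


@dataclass
class PCAProjection:
    """2-component PCA of normalised fingerprints."""

    scores: pd.DataFrame       # replicates x (PC1, PC2) + cell_line if known
    loadings: pd.DataFrame     # markers x (PC1, PC2)
    explained_variance_ratio: np.ndarray


def pca_project(matrix: FingerprintMatrix,
                z_score: bool = False) -> PCAProjection:
    """Project fingerprints onto their two leading principal components.

    Columns are the specific markers (IgG1 excluded), centred (optionally
    z-scored); the sign of each component is fixed so that its
    largest-magnitude loading is positive.
    """
    if matrix.stage != NORMALISED:
        raise ValueError("PCA applies to normalised fingerprints")
    cols = matrix.specific_markers
    X = matrix.frame[cols].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need >= 3 replicate rows for PCA")
    if z_score:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    n_comp = min(2, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    comps = pca.components_
    for i in range(n_comp):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] *= -1.0
            scores[:, i] *= -1.0
    pc_names = [f"PC{i + 1}" for i in range(n_comp)]
    score_df = pd.DataFrame(scores, columns=pc_names)
    if "cell_line" in matrix.frame.columns:
        score_df["cell_line"] = matrix.frame["cell_line"].to_numpy()
    loadings = pd.DataFrame(comps.T, index=cols, columns=pc_names)
    return PCAProjection(scores=score_df, loadings=loadings,
                         explained_variance_ratio=pca.explained_variance_ratio_)


def contrast_density_correlation(tables: dict[str, pd.DataFrame],
                                 area_mm2: float,
                                 label: str = "signal"
                                 ) -> tuple[pd.DataFrame, float]:
    """Median signal contrast versus capture density across markers.

    For each marker channel, pairs the median ``label``-class peak contrast
    with the channel's count density; returns the per-marker table and the
    Spearman rank correlation across markers.  Channels without
    localisations are excluded with a warning.
    """
    if area_mm2 <= 0:
        raise ValueError("area must be > 0")
    rows = []
    for marker, table in tables.items():
        sel = table[table["label"] == label] if "label" in table.columns else table
        if len(sel) == 0:
            warnings.warn(f"marker {marker!r} has no localisations; excluded",
                          stacklevel=2)
            continue
        rows.append(dict(marker=marker,
                         median_contrast=float(sel["peak_contrast"].median()),
                         density_per_100um2=len(sel) / (area_mm2 * 1e4)))
    if len(rows) < 3:
        raise ValueError("need >= 3 markers with localisations")
    df = pd.DataFrame(rows)
    rho = stats.spearmanr(df["median_contrast"], df["density_per_100um2"]).statistic
    return df, float(rho)
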