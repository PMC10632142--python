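"""Cell-type classification from marker intensities, FISH dot counts, and
transcriptomic marker screens.

Immunofluorescence intensities are z-scored per imaging batch (so samples
processed on different days are comparable), then cells are assigned to
types either by a z-score threshold on one channel or by k-means clustering
on the z-scored channels — in the two-marker BNC2/FOXP2 case the cluster
with the higher BNC2-like z is the pRGC10-like type.

FISH transcripts are quantified per cell as

    dot_number = (integrated_intensity − background_per_px × area) / single_dot_intensity

floored at zero, with strict thresholds (>40 dots for BNC2, >80 for FSTL4)
for calling a cell probe-positive.

The transcriptomic marker screen compares expression of candidate genes
(e.g. GABRA2, GLRA2) between each peripheral cluster and its declared foveal
partner; a cluster is excluded as a candidate when any screened gene differs
by more than 2 natural-log fold with P < 0.05 by two-sided Wilcoxon
rank-sum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

DOT_THRESHOLDS = {"BNC2": 40.0, "FSTL4": 80.0}
SCREEN_LFC_THRESHOLD = 2.0
SCREEN_ALPHA = 0.05


# ---------------------------------------------------------------------------
# marker-intensity classification


def zscore_channels(
    table: pd.DataFrame,
    channels: Sequence[str],
    batch_col: str = "batch_id",
) -> pd.DataFrame:
    """Standardize intensity channels per batch (population denominator).

    Adds ``z_<channel>`` columns. Raises when a batch has fewer than 2 cells
    or a channel has zero variance within a batch (naming the offender).
    """
    out = table.copy()
    for ch in channels:
        out[f"z_{ch}"] = np.nan
    groups = out.groupby(batch_col) if batch_col in out.columns else [("all", out)]
    for batch, sub in groups:
        if len(sub) < 2:
            raise ValueError(f"batch {batch!r} has fewer than 2 cells")
        for ch in channels:
            vals = sub[ch].to_numpy(dtype=float)
            sd = vals.std(ddof=0)
            if sd == 0:
                raise ValueError(f"zero variance in channel {ch!r}, batch {batch!r}")
            out.loc[sub.index, f"z_{ch}"] = (vals - vals.mean()) / sd
    return out


@dataclass
class KmeansResult:
    table: pd.DataFrame  # with assigned_label column
    centroids_z: np.ndarray
    inertia: float
    degenerate: bool  # clusters not meaningfully separated


def kmeans_classify(
    table: pd.DataFrame,
    channels: Sequence[str],
    k: int = 2,
    seed: int | None = 0,
    labels: Sequence[str] = ("pRGC10-like", "pRGC16-like"),
) -> KmeansResult:
    """k-means clustering on z-scored channels with type-label assignment.

    For k = 2, the cluster whose mean first-channel z-score is higher gets
    ``labels[0]`` (the BNC2-high pRGC10-like type); assignment is therefore
    invariant to cluster-index permutation. Clustering is flagged degenerate
    when the centroid separation is small relative to within-cluster spread
    (one biological class, or inseparable classes).
    """
    zcols = [f"z_{ch}" for ch in channels]
    missing = [c for c in zcols if c not in table.columns]
    if missing:
        table = zscore_channels(table, channels)
    X = table[zcols].to_numpy(dtype=float)
    if len(np.unique(X, axis=0)) < k:
        raise ValueError(f"fewer than k={k} distinct points")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    order = np.argsort(-km.cluster_centers_[:, 0])  # descending first-channel z
    if k == 2:
        names = {order[0]: labels[0], order[1]: labels[1]}
    else:
        names = {c: f"cluster_{rank}" for rank, c in enumerate(order)}
    out = table.copy()
    out["assigned_label"] = [names[c] for c in km.labels_]
    out["method"] = "kmeans"
    within = math.sqrt(km.inertia_ / len(X)) if len(X) else 0.0
    sep = np.inf
    for i in range(k):
        for j in range(i + 1, k):
            sep = min(sep, float(np.linalg.norm(km.cluster_centers_[i] - km.cluster_centers_[j])))
    degenerate = bool(k > 1 and within > 0 and sep < 2.0 * within)
    return KmeansResult(
        table=out, centroids_z=km.cluster_centers_, inertia=float(km.inertia_), degenerate=degenerate
    )


def threshold_classify(
    table: pd.DataFrame,
    channel: str,
    z_threshold: float,
    positive_label: str = "positive",
    negative_label: str = "negative",
) -> pd.DataFrame:
    """Classify cells positive when the channel z-score strictly exceeds a threshold."""
    zcol = f"z_{channel}"
    if zcol not in table.columns:
        table = zscore_channels(table, [channel])
    out = table.copy()
    out["assigned_label"] = np.where(out[zcol] > z_threshold, positive_label, negative_label)
    out["method"] = "threshold"
    return out


def label_agreement(a: Sequence, b: Sequence) -> float:
    """Fraction of cells assigned the same label by two classifiers."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    return float(np.mean(a == b))


# ---------------------------------------------------------------------------
# FISH dot counting


def count_dots(
    integrated_intensity: float,
    area_px: float,
    background_per_px: float,
    single_dot_intensity: float,
) -> float:
    """Estimated transcript dots per cell from integrated FISH intensity.

    dot_number = (integrated − background_per_px × area) / single_dot_intensity,
    floored at 0 (a noisy cell can go negative). The value is left
    non-integer; probe thresholds compare the real value.
    """
    if single_dot_intensity <= 0:
        raise ValueError("single_dot_intensity must be positive")
    if area_px <= 0:
        raise ValueError("area_px must be positive")
    raw = (integrated_intensity - background_per_px * area_px) / single_dot_intensity
    return max(raw, 0.0)


def call_probe_positive(
    dot_number: float,
    probe: str,
    thresholds: dict[str, float] | None = None,
) -> bool:
    """Strictly-greater-than dot-count threshold per probe (BNC2: 40, FSTL4: 80)."""
    thresholds = thresholds or DOT_THRESHOLDS
    if probe not in thresholds:
        raise ValueError(f"unknown probe {probe!r}; known: {sorted(thresholds)}")
    return dot_number > thresholds[probe]


def dot_count_table(cells: pd.DataFrame, thresholds: dict[str, float] | None = None) -> pd.DataFrame:
    """Apply the dot-number formula and probe calls to a per-cell table.

    Expects columns integrated_intensity, area_px, background_per_px,
    single_dot_intensity and probe; cells flagged in an ``artifact`` column
    (blood vessels, high background) are excluded from positivity calls.
    """
    out = cells.copy()
    out["dot_number"] = [
        count_dots(r.integrated_intensity, r.area_px, r.background_per_px, r.single_dot_intensity)
        for r in cells.itertuples()
    ]
    out["positive"] = [
        call_probe_positive(dn, probe, thresholds)
        for dn, probe in zip(out["dot_number"], out["probe"])
    ]
    if "artifact" in out.columns:
        out.loc[out["artifact"].astype(bool), "positive"] = False
    return out


# ---------------------------------------------------------------------------
# transcriptomic marker screen


def _normalize_library(counts: pd.DataFrame) -> pd.DataFrame:
    """Library-size normalisation: scale each cell to the median total count."""
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        warnings.warn("cells with zero total counts; left unscaled")
    med = float(totals.median())
    scale = np.where(totals > 0, med / totals, 1.0)
    return counts * scale


@dataclass
class ScreenResult:
    table: pd.DataFrame  # per (pair, gene): lfc, p, flagged
    excluded_pairs: list[tuple[str, str]]


def marker_screen(
    counts: pd.DataFrame,
    cluster_labels: pd.Series,
    cluster_pairs: Sequence[tuple[str, str]],
    genes: Sequence[str],
    lfc_threshold: float = SCREEN_LFC_THRESHOLD,
    alpha: float = SCREEN_ALPHA,
    normalize: bool = True,
    eps: float = 1e-8,
) -> ScreenResult:
    """Screen foveal/peripheral cluster pairs for differential marker expression.

    For each (foveal, peripheral) pair and each gene, computes the
    natural-log fold change of cluster means of library-size-normalised
    counts and a two-sided Wilcoxon rank-sum p-value; a pair is excluded as
    an ON-DSGC candidate when any screened gene satisfies |lfc| > 2 and
    p < 0.05 (the conjunction).
    """
    missing = [g for g in genes if g not in counts.index]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing}")
    mat = _normalize_library(counts) if normalize else counts
    rows = []
    excluded_pairs = []
    for fov, per in cluster_pairs:
        fov_cells = cluster_labels.index[cluster_labels == fov]
        per_cells = cluster_labels.index[cluster_labels == per]
        if len(fov_cells) == 0 or len(per_cells) == 0:
            raise ValueError(f"empty cluster in pair ({fov}, {per})")
        pair_flagged = False
        for g in genes:
            a = mat.loc[g, fov_cells].to_numpy(dtype=float)
            b = mat.loc[g, per_cells].to_numpy(dtype=float)
            lfc = math.log((b.mean() + eps) / (a.mean() + eps))
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue)
            flagged = abs(lfc) > lfc_threshold and p < alpha
            pair_flagged |= flagged
            rows.append(
                {
                    "foveal": fov,
                    "peripheral": per,
                    "gene": g,
                    "log_fold_change": lfc,
                    "p_value": p,
                    "flagged": flagged,
                }
            )
        if pair_flagged:
            excluded_pairs.append((fov, per))
    table = pd.DataFrame(rows)
    table["excluded"] = [
        (r.foveal, r.peripheral) in excluded_pairs for r in table.itertuples()
    ]
    return ScreenResult(table=table, excluded_pairs=excluded_pairs)


def dotplot_stats(
    counts: pd.DataFrame,
    cluster_labels: pd.Series,
    genes: Sequence[str],
) -> pd.DataFrame:
    """Dot-plot statistics per (cluster, gene).

    ``pct_expressing`` is the percentage of cells with count > 0;
    ``mean_in_expressing`` averages only over expressing cells and is NaN
    (undefined) when no cell expresses the gene.
    """
    rows = []
    for cl in pd.unique(cluster_labels):
        cells = cluster_labels.index[cluster_labels == cl]
        for g in genes:
            vals = counts.loc[g, cells].to_numpy(dtype=float)
            expressing = vals > 0
            pct = 100.0 * expressing.mean() if len(vals) else 0.0
            mean_expr = float(vals[expressing].mean()) if expressing.any() else float("nan")
            rows.append(
                {
                    "cluster": cl,
                    "gene": g,
                    "pct_expressing": pct,
                    "mean_in_expressing": mean_expr,
                }
            )
    return pd.DataFrame(rows)
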