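"""Pixel-based vector-sum mapping of direction-selective somas.

The movie is converted per pixel to ΔF/F (same 23-s pre-stimulus baseline
rule as ROI processing), spatially Gaussian filtered (sigma = 2 px by
default), max-projected within each bar presentation window, averaged over
trials per direction, and summed as vectors per pixel. Clusters of pixels
with high vector-sum magnitude mark candidate direction-selective somas,
which are reported as connected components with centroid, area and mean
preferred angle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .imaging import DEFAULT_BASELINE_WINDOW_S, DEFAULT_RESPONSE_TAIL_S, CalciumMovie

if TYPE_CHECKING:
    from .synth import StimulusSchedule


@dataclass
class VectorSumMap:
    """Per-pixel vector-sum magnitude/angle maps and per-direction images."""

    magnitude: np.ndarray  # Y x X, >= 0
    angle_deg: np.ndarray  # Y x X, NaN where magnitude == 0 or pixel masked
    nvs: np.ndarray  # normalized magnitude (|V| / scalar sum), NaN where masked
    direction_images: dict[float, np.ndarray]
    valid: np.ndarray  # False where per-pixel F0 was unreliable


def pixel_vector_sum_map(
    movie: CalciumMovie,
    schedule: "StimulusSchedule",
    sigma_px: float = 2.0,
    baseline_window_s: float = DEFAULT_BASELINE_WINDOW_S,
    response_tail_s: float = DEFAULT_RESPONSE_TAIL_S,
    f0_floor_quantile: float = 0.01,
    f0_floor_frac: float = 0.05,
) -> VectorSumMap:
    """Compute the per-pixel vector-sum map of a drifting-bar movie.

    Per-pixel F₀ is the mean over the pre-stimulus baseline window. Dark
    pixels, where the ΔF/F division is unstable, are masked out: a pixel is
    kept only when its F₀ exceeds both the ``f0_floor_quantile`` quantile of
    the F₀ image and ``f0_floor_frac`` of its 99th percentile (the latter
    guards fields with large unlabelled areas, where the quantile floor is
    near zero). The reported magnitude is the raw |V| (heat-map convention);
    the normalised variant |V|/ΣR is returned alongside.
    """
    directions = schedule.directions
    if len(directions) < 2:
        raise ValueError("schedule must contain at least 2 bar directions")
    times = movie.times
    t_on = schedule.t_first_on
    sel = (times >= t_on - baseline_window_s - 1e-9) & (times < t_on - 1e-9)
    if not sel.any():
        raise ValueError("no pre-stimulus frames for per-pixel F0")
    stack = movie.stack.astype(np.float64)
    f0 = stack[sel].mean(axis=0)
    floor = max(
        np.quantile(f0, f0_floor_quantile),
        f0_floor_frac * np.percentile(f0, 99),
        0.0,
    )
    valid = f0 > floor
    f0_safe = np.where(valid, f0, np.inf)  # masked pixels contribute 0 response
    dff = (stack - f0) / f0_safe
    if sigma_px > 0:
        dff = ndimage.gaussian_filter(dff, sigma=(0, sigma_px, sigma_px), mode="reflect")

    per_dir: dict[float, list[np.ndarray]] = {d: [] for d in directions}
    for ep in schedule.epochs:
        if ep.kind != "bar":
            continue
        e_sel = (times >= ep.t_on_s - 1e-9) & (times <= ep.t_off_s + response_tail_s + 1e-9)
        if not e_sel.any():
            raise ValueError("epoch outside recording")
        per_dir[ep.direction_deg].append(dff[e_sel].max(axis=0))
    dir_images = {d: np.mean(imgs, axis=0) for d, imgs in per_dir.items() if imgs}

    vx = np.zeros_like(f0)
    vy = np.zeros_like(f0)
    scalar = np.zeros_like(f0)
    for d, img in dir_images.items():
        resp = np.clip(img, 0.0, None)
        th = np.radians(d)
        vx += resp * np.cos(th)
        vy += resp * np.sin(th)
        scalar += resp
    mag = np.hypot(vx, vy)
    with np.errstate(invalid="ignore", divide="ignore"):
        nvs = np.where(scalar > 0, mag / np.where(scalar > 0, scalar, 1.0), 0.0)
    angle = np.degrees(np.arctan2(vy, vx)) % 360.0
    angle[(mag == 0) | ~valid] = np.nan
    mag = np.where(valid, mag, 0.0)
    return VectorSumMap(
        magnitude=mag, angle_deg=angle, nvs=np.where(valid, nvs, np.nan),
        direction_images=dir_images, valid=valid,
    )


def detect_candidates(
    vsmap: VectorSumMap,
    threshold: float = 0.995,
    absolute: bool = False,
    min_area_px: int = 4,
) -> pd.DataFrame:
    """Segment candidate DS somas as suprathreshold connected components.

    ``threshold`` is a quantile of the magnitude map (default 0.995) unless
    ``absolute`` is set. Components are 8-connected; each is reported with
    centroid (pixel coordinates), area, circular-mean angle weighted by
    magnitude, and mean magnitude. An empty map yields an empty table.
    """
    mag = vsmap.magnitude
    if absolute:
        thr = threshold
    else:
        if not 0 < threshold <= 1:
            raise ValueError("quantile threshold must lie in (0, 1]")
        thr = np.quantile(mag, threshold)
    mask = mag > thr
    if not mask.any():
        return pd.DataFrame(
            columns=["candidate", "centroid_x", "centroid_y", "area_px", "angle_deg", "magnitude"]
        )
    labels = measure.label(mask, connectivity=2)
    rows = []
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        ys, xs = region.coords[:, 0], region.coords[:, 1]
        w = mag[ys, xs]
        ang = np.radians(vsmap.angle_deg[ys, xs])
        ok = np.isfinite(ang)
        mean_angle = float("nan")
        if ok.any():
            mean_angle = float(
                np.degrees(np.arctan2(np.sum(w[ok] * np.sin(ang[ok])), np.sum(w[ok] * np.cos(ang[ok]))))
                % 360.0
            )
        cy, cx = region.centroid
        rows.append(
            {
                "candidate": len(rows),
                "centroid_x": cx,
                "centroid_y": cy,
                "area_px": int(region.area),
                "angle_deg": mean_angle,
                "magnitude": float(w.mean()),
            }
        )
    return pd.DataFrame(rows, columns=["candidate", "centroid_x", "centroid_y", "area_px", "angle_deg", "magnitude"])
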