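"""ΔF/F processing of calcium movies and ROI traces.

Raw somatic fluorescence is background-subtracted, converted to fractional
change ΔF/F = (F − F₀)/F₀ with F₀ the mean over a pre-stimulus baseline
window (23 s by default), optionally high-pass filtered to remove slow
background oscillations, and segmented into per-epoch peak responses: the
maximum ΔF/F within each stimulus window is taken per trial, then trial
maxima are averaged per direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal

if TYPE_CHECKING:
    from .synth import StimulusSchedule

DEFAULT_BASELINE_WINDOW_S = 23.0
DEFAULT_RESPONSE_TAIL_S = 1.0


@dataclass
class CalciumMovie:
    """T x Y x X fluorescence stack with acquisition metadata."""

    stack: np.ndarray
    frame_rate_hz: float
    px_per_um: float = 1.0
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        if self.stack.ndim != 3 or min(self.stack.shape) < 1:
            raise ValueError("stack must be a non-empty T x Y x X array")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.stack.shape[0]) / self.frame_rate_hz


@dataclass
class RoiTraceSet:
    """Per-ROI fluorescence time series on a shared time base.

    ``raw_f`` is (n_roi, T); ``dff`` is populated by :func:`compute_dff`.
    """

    roi_ids: list[str]
    raw_f: np.ndarray
    frame_rate_hz: float
    t0_s: float = 0.0
    masks: list[np.ndarray] | None = None
    background_f: np.ndarray | None = None
    dff: np.ndarray | None = None
    baseline_window_s: float | None = None

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.raw_f.shape[1]) / self.frame_rate_hz

    def to_frame(self, which: str = "dff") -> pd.DataFrame:
        """Traces as a tidy DataFrame with a ``time_s`` column."""
        data = getattr(self, which)
        if data is None:
            raise ValueError(f"{which} has not been computed")
        df = pd.DataFrame(data.T, columns=self.roi_ids)
        df.insert(0, "time_s", self.times)
        return df


def extract_traces(movie: CalciumMovie, rois: Sequence[np.ndarray]) -> RoiTraceSet:
    """Average movie pixels within each ROI mask over time.

    ``rois`` are boolean Y x X masks; every mask must be non-empty and match
    the movie's spatial shape.
    """
    _, ny, nx = movie.stack.shape
    flat = movie.stack.reshape(movie.stack.shape[0], -1)
    traces = []
    for i, mask in enumerate(rois):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (ny, nx):
            raise ValueError(f"ROI {i} shape {mask.shape} != movie frame {(ny, nx)}")
        idx = np.flatnonzero(mask.ravel())
        if idx.size == 0:
            raise ValueError(f"ROI {i} is empty")
        traces.append(flat[:, idx].mean(axis=1))
    return RoiTraceSet(
        roi_ids=[f"roi_{i}" for i in range(len(rois))],
        raw_f=np.asarray(traces, dtype=np.float64),
        frame_rate_hz=movie.frame_rate_hz,
        t0_s=movie.t0_s,
        masks=[np.asarray(m, dtype=bool) for m in rois],
    )


def subtract_background(traces: RoiTraceSet, background: np.ndarray) -> RoiTraceSet:
    """Subtract a background trace (no-laser control or background ROI).

    The background trace must share the ROI time base; it is subtracted
    elementwise from every ROI trace.
    """
    background = np.asarray(background, dtype=np.float64).ravel()
    if background.shape[0] != traces.raw_f.shape[1]:
        raise ValueError(
            f"background length {background.shape[0]} != trace length {traces.raw_f.shape[1]}"
        )
    return replace(traces, raw_f=traces.raw_f - background[None, :], background_f=background)


def _baseline_slice(
    times: np.ndarray, t_first_on: float, baseline_window_s: float
) -> np.ndarray:
    start = t_first_on - baseline_window_s
    if start < times[0] - 1e-9:
        warnings.warn(
            f"only {t_first_on - times[0]:.1f} s of pre-stimulus recording available "
            f"(requested {baseline_window_s:.1f} s); using all available frames",
            stacklevel=3,
        )
        start = times[0]
    sel = (times >= start - 1e-9) & (times < t_first_on - 1e-9)
    if not sel.any():
        raise ValueError("no pre-stimulus frames available for baseline estimation")
    return sel


def compute_dff(
    traces: RoiTraceSet,
    schedule: "StimulusSchedule",
    baseline_window_s: float = DEFAULT_BASELINE_WINDOW_S,
) -> RoiTraceSet:
    """ΔF/F = (F − F₀)/F₀ with F₀ the mean over the pre-stimulus window.

    The window is the last ``baseline_window_s`` seconds before the first
    stimulus onset; if less pre-stimulus recording exists, all available
    frames are used with a warning. A non-positive F₀ is rejected as
    non-physical.
    """
    sel = _baseline_slice(traces.times, schedule.t_first_on, baseline_window_s)
    f0 = traces.raw_f[:, sel].mean(axis=1)
    if np.any(f0 <= 0):
        bad = [traces.roi_ids[i] for i in np.flatnonzero(f0 <= 0)]
        raise ValueError(f"non-positive baseline F0 for ROIs {bad}")
    dff = (traces.raw_f - f0[:, None]) / f0[:, None]
    return replace(traces, dff=dff, baseline_window_s=baseline_window_s)


def highpass_restore_baseline(
    traces: RoiTraceSet,
    cutoff_hz: float,
    method: str = "butter",
    order: int = 2,
    percentile: float = 10.0,
) -> RoiTraceSet:
    """Remove slow background oscillations while keeping stimulus transients.

    Default is a zero-phase Butterworth high-pass (``sosfiltfilt``), which
    attenuates a sinusoid an octave or more below the cutoff to a few percent
    while transients much shorter than 1/cutoff pass nearly unchanged.
    ``method="percentile"`` instead subtracts a running low-percentile
    baseline over a window of 3/cutoff seconds. Operates on ΔF/F if computed,
    otherwise on the raw traces.
    """
    nyq = traces.frame_rate_hz / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")
    data = traces.dff if traces.dff is not None else traces.raw_f
    if method == "butter":
        sos = signal.butter(order, cutoff_hz, btype="highpass", fs=traces.frame_rate_hz, output="sos")
        out = signal.sosfiltfilt(sos, data, axis=1)
    elif method == "percentile":
        win = max(int(round(3.0 / cutoff_hz * traces.frame_rate_hz)), 3)
        base = ndimage.percentile_filter(data, percentile, size=(1, win), mode="nearest")
        out = data - base
    else:
        raise ValueError(f"unknown method {method!r}")
    if traces.dff is not None:
        return replace(traces, dff=out)
    return replace(traces, raw_f=out)


def epoch_responses(
    traces: RoiTraceSet,
    schedule: "StimulusSchedule",
    response_tail_s: float = DEFAULT_RESPONSE_TAIL_S,
) -> pd.DataFrame:
    """Peak ΔF/F per ROI per stimulus epoch.

    The peak is the maximum ΔF/F within [t_on, t_off + tail]; the tail
    captures indicator decay after stimulus offset. Returns a tidy table with
    one row per (roi, epoch): columns roi_id, epoch, trial, direction_deg,
    speed_um_s, kind, diameter_um, peak_dff. Trial averaging is done
    downstream (maxima per trial, then averaged).
    """
    if traces.dff is None:
        raise ValueError("compute_dff must be called before epoch_responses")
    times = traces.times
    rows = []
    for e_idx, ep in enumerate(schedule.epochs):
        sel = (times >= ep.t_on_s - 1e-9) & (times <= ep.t_off_s + response_tail_s + 1e-9)
        if not sel.any():
            raise ValueError(f"epoch {e_idx} lies outside the recording")
        peaks = traces.dff[:, sel].max(axis=1)
        for r_idx, roi in enumerate(traces.roi_ids):
            rows.append(
                {
                    "roi_id": roi,
                    "epoch": e_idx,
                    "trial": ep.trial,
                    "direction_deg": ep.direction_deg,
                    "speed_um_s": ep.speed_um_s,
                    "kind": ep.kind,
                    "diameter_um": ep.diameter_um,
                    "peak_dff": peaks[r_idx],
                }
            )
    return pd.DataFrame(rows)


def direction_means(responses: pd.DataFrame) -> pd.DataFrame:
    """Trial-mean peak ΔF/F per ROI per direction (bar epochs only)."""
    bars = responses[responses["kind"] == "bar"]
    return (
        bars.groupby(["roi_id", "direction_deg"])["peak_dff"]
        .mean()
        .reset_index()
        .rename(columns={"peak_dff": "mean_peak_dff"})
    )


def baseline_sd(
    traces: RoiTraceSet,
    schedule: "StimulusSchedule",
    baseline_window_s: float = DEFAULT_BASELINE_WINDOW_S,
) -> np.ndarray:
    """Per-ROI ΔF/F standard deviation over the pre-stimulus baseline window."""
    if traces.dff is None:
        raise ValueError("compute_dff must be called first")
    sel = _baseline_slice(traces.times, schedule.t_first_on, baseline_window_s)
    if sel.sum() < 2:
        raise ValueError("baseline window contains fewer than 2 frames")
    return traces.dff[:, sel].std(axis=1)
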