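"""Direction-selectivity statistics and tuning-curve fits.

The two headline statistics are the normalized vector sum (NVS) — the
magnitude of the per-direction response vector sum divided by the scalar sum
of responses, 0 for an untuned cell and 1 for a perfectly directional one —
and the direction selectivity index DSI = (pref − null)/(pref + null), which
ranges from −1 to 1 and goes negative when, e.g. after GABA_A blockade, the
residual response lies opposite the original preferred direction. Tuning
curves are fit with the von Mises function

    R(x) = R_max * exp(kappa * cos((x − mu) * pi/180)) / exp(kappa),

the circular analogue of the Gaussian, which equals R_max at the preferred
direction mu and degenerates to a constant as kappa -> 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

if TYPE_CHECKING:
    from .imaging import RoiTraceSet
    from .synth import StimulusSchedule

RESPONSIVENESS_FACTOR = 1.5  # mean amplitude must exceed 1.5 x baseline sd


# ---------------------------------------------------------------------------
# vector statistics


@dataclass(frozen=True)
class VectorSum:
    magnitude: float
    angle_deg: float  # NaN when magnitude is 0 (undefined)
    nvs: float

    @property
    def angle_defined(self) -> bool:
        return not math.isnan(self.angle_deg)


def vector_sum(
    directions_deg: Sequence[float], amplitudes: Sequence[float]
) -> VectorSum:
    """Vector sum of per-direction response amplitudes.

    Negative amplitudes are clipped to 0 before summation (the scalar-sum
    normalisation presumes non-negative responses), which guarantees
    NVS ∈ [0, 1]. With all-zero responses the magnitude and NVS are 0 and the
    angle is flagged undefined (NaN).
    """
    d = np.asarray(directions_deg, dtype=float)
    r = np.clip(np.asarray(amplitudes, dtype=float), 0.0, None)
    if len(np.unique(d % 360.0)) < 2:
        raise ValueError("need at least 2 distinct directions")
    th = np.radians(d)
    vx, vy = float(np.sum(r * np.cos(th))), float(np.sum(r * np.sin(th)))
    mag = math.hypot(vx, vy)
    total = float(r.sum())
    if total == 0.0 or mag == 0.0:
        return VectorSum(magnitude=mag, angle_deg=float("nan"), nvs=0.0 if total == 0 else mag / total)
    return VectorSum(magnitude=mag, angle_deg=math.degrees(math.atan2(vy, vx)) % 360.0, nvs=mag / total)


def dsi(pref: float, null: float) -> float:
    """Direction selectivity index (pref − null)/(pref + null).

    Undefined (NaN) when pref + null = 0. Values near 1 indicate strong
    selectivity; negative values a residual response opposite the original
    preferred direction.
    """
    s = pref + null
    if s == 0:
        return float("nan")
    return (pref - null) / s


def preferred_null(
    directions_deg: Sequence[float], amplitudes: Sequence[float]
) -> tuple[float, float]:
    """Preferred and null directions from trial-mean responses.

    Preferred = argmax response direction (ties broken toward the vector-sum
    angle); null = preferred + 180°.
    """
    d = np.asarray(directions_deg, dtype=float) % 360.0
    r = np.asarray(amplitudes, dtype=float)
    peak = r.max()
    tied = np.flatnonzero(r >= peak - 1e-12)
    if len(tied) > 1:
        vs = vector_sum(d, r)
        if vs.angle_defined:
            diffs = np.abs((d[tied] - vs.angle_deg + 180.0) % 360.0 - 180.0)
            pref = float(d[tied[np.argmin(diffs)]])
        else:
            pref = float(d[tied[0]])
    else:
        pref = float(d[tied[0]])
    return pref, (pref + 180.0) % 360.0


def dsi_from_profile(
    directions_deg: Sequence[float],
    amplitudes: Sequence[float],
    pref_deg: float | None = None,
) -> float:
    """DSI from a tuning profile; pass ``pref_deg`` to reuse a fixed axis.

    For drug comparisons the pre-drug preferred axis is retained, so the
    post-drug DSI can be negative when the residual response flips.
    """
    d = np.asarray(directions_deg, dtype=float) % 360.0
    r = np.asarray(amplitudes, dtype=float)
    if pref_deg is None:
        pref_deg, _ = preferred_null(d, r)
    null_deg = (pref_deg + 180.0) % 360.0

    def _amp(angle: float) -> float:
        i = np.argmin(np.abs((d - angle + 180.0) % 360.0 - 180.0))
        return float(r[i])

    return dsi(_amp(pref_deg), _amp(null_deg))


# ---------------------------------------------------------------------------
# von Mises fit


@dataclass(frozen=True)
class VonMisesFit:
    r_max: float
    mu_deg: float
    kappa: float
    fit_ok: bool
    rmse: float = float("nan")
    message: str = ""


def von_mises(x_deg, r_max: float, mu_deg: float, kappa: float):
    """The tuning-curve model R_max * exp(kappa*cos((x−mu)·π/180)) / exp(kappa)."""
    x = np.asarray(x_deg, dtype=float)
    return r_max * np.exp(kappa * (np.cos(np.radians(x - mu_deg)) - 1.0))


def fit_von_mises(
    directions_deg: Sequence[float],
    amplitudes: Sequence[float],
    kappa_max: float = 50.0,
) -> VonMisesFit:
    """Least-squares von Mises fit of a direction tuning curve.

    Initialisation: mu at the vector-sum angle, R_max at the peak response,
    kappa = 1; kappa is bounded to [0, kappa_max]. Non-convergence returns
    ``fit_ok=False`` with the solver message; the raw statistics remain
    available to the caller.
    """
    d = np.asarray(directions_deg, dtype=float)
    r = np.asarray(amplitudes, dtype=float)
    if len(d) < 4:
        raise ValueError("need at least 4 directions for a von Mises fit")
    if np.any(r < 0):
        raise ValueError("amplitudes must be non-negative")
    vs = vector_sum(d, r)
    mu0 = vs.angle_deg if vs.angle_defined else float(d[np.argmax(r)])
    p0 = [max(r.max(), 1e-12), mu0, 1.0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                von_mises,
                d,
                r,
                p0=p0,
                bounds=([0.0, mu0 - 360.0, 0.0], [np.inf, mu0 + 360.0, kappa_max]),
                maxfev=10_000,
            )
    except RuntimeError as exc:
        return VonMisesFit(float("nan"), float("nan"), float("nan"), False, message=str(exc))
    resid = r - von_mises(d, *popt)
    return VonMisesFit(
        r_max=float(popt[0]),
        mu_deg=float(popt[1]) % 360.0,
        kappa=float(popt[2]),
        fit_ok=True,
        rmse=float(np.sqrt(np.mean(resid**2))),
    )


# ---------------------------------------------------------------------------
# responsiveness


def is_responsive(
    mean_amplitude: float | Sequence[float], baseline_sd: float
) -> bool:
    """True iff the average response amplitude strictly exceeds 1.5 × baseline sd.

    ``mean_amplitude`` may be the per-epoch peak amplitudes (averaged here)
    or a precomputed mean; the threshold comparison is strict, so an
    amplitude of exactly 1.5 sd is not responsive.
    """
    if baseline_sd <= 0:
        raise ValueError("baseline_sd must be positive")
    amp = float(np.mean(mean_amplitude))
    return amp > RESPONSIVENESS_FACTOR * baseline_sd


# ---------------------------------------------------------------------------
# orientation conventions


@dataclass(frozen=True)
class OrientationConvention:
    """Mapping of retinal axes to angles (superior=90, temporal=0, inferior=270,
    nasal=180), with an optional chirality flip for flat-mounted retina.

    Implemented as angle -> (rotation ± angle) mod 360, which is a bijection
    on the circle; ``flip`` reflects about the horizontal axis (90° ↔ 270°).
    """

    rotation_deg: float = 0.0
    flip: bool = False

    def apply(self, angles_deg):
        a = np.asarray(angles_deg, dtype=float)
        out = (self.rotation_deg - a) if self.flip else (self.rotation_deg + a)
        return out % 360.0

    def invert(self, angles_deg):
        a = np.asarray(angles_deg, dtype=float)
        out = (self.rotation_deg - a) if self.flip else (a - self.rotation_deg)
        return out % 360.0


def apply_orientation(angles_stimulus_deg, convention: OrientationConvention):
    """Remap stimulus-space angles into retinal coordinates."""
    return convention.apply(angles_stimulus_deg)


# ---------------------------------------------------------------------------
# per-ROI profiles


@dataclass
class TuningProfile:
    """Per-ROI direction tuning summary."""

    roi_id: str
    directions_deg: np.ndarray
    mean_peak_dff: np.ndarray
    vector: VectorSum
    dsi: float
    pref_deg: float
    vm_fit: VonMisesFit
    responsive: bool | None = None


def profile_from_responses(
    responses: pd.DataFrame,
    roi_id: str,
    baseline_sd: float | None = None,
    pref_deg: float | None = None,
) -> TuningProfile:
    """Assemble a TuningProfile from an epoch-response table (one ROI).

    ``responses`` is the tidy table from :func:`retinads.imaging.epoch_responses`;
    trial maxima are averaged per direction before statistics are computed.
    """
    sub = responses[(responses["roi_id"] == roi_id) & (responses["kind"] == "bar")]
    if sub.empty:
        raise ValueError(f"no bar responses for ROI {roi_id!r}")
    means = sub.groupby("direction_deg")["peak_dff"].mean()
    d = means.index.to_numpy(dtype=float)
    r = means.to_numpy(dtype=float)
    vs = vector_sum(d, np.clip(r, 0, None))
    prof_pref = pref_deg
    if prof_pref is None:
        prof_pref, _ = preferred_null(d, np.clip(r, 0, None))
    responsive = None
    if baseline_sd is not None:
        responsive = is_responsive(sub["peak_dff"].to_numpy(), baseline_sd)
    return TuningProfile(
        roi_id=roi_id,
        directions_deg=d,
        mean_peak_dff=r,
        vector=vs,
        dsi=dsi_from_profile(d, r, pref_deg=prof_pref),
        pref_deg=prof_pref,
        vm_fit=fit_von_mises(d, np.clip(r, 0, None)),
        responsive=responsive,
    )


def profiles_table(profiles: Sequence[TuningProfile]) -> pd.DataFrame:
    """Flatten TuningProfiles to one row per ROI (nvs, dsi, fit parameters)."""
    return pd.DataFrame(
        {
            "roi_id": p.roi_id,
            "nvs": p.vector.nvs,
            "vector_angle_deg": p.vector.angle_deg,
            "dsi": p.dsi,
            "pref_deg": p.pref_deg,
            "vm_r_max": p.vm_fit.r_max,
            "vm_mu_deg": p.vm_fit.mu_deg,
            "vm_kappa": p.vm_fit.kappa,
            "fit_ok": p.vm_fit.fit_ok,
            "responsive": p.responsive,
        }
        for p in profiles
    )


# ---------------------------------------------------------------------------
# velocity and spot metrics


def velocity_tuning(
    traces: "RoiTraceSet",
    schedule: "StimulusSchedule",
    roi_index: int = 0,
    window_s: float = 0.5,
) -> pd.DataFrame:
    """Peak response per bar speed: max of a sliding 0.5-s-window mean.

    Returns one row per (speed, direction) with the windowed maximum ΔF/F;
    used on preferred/null protocols spanning 125–2000 µm/s.
    """
    if traces.dff is None:
        raise ValueError("compute_dff must be called first")
    times = traces.times
    trace = traces.dff[roi_index]
    win = max(int(round(window_s * traces.frame_rate_hz)), 1)
    kernel = np.ones(win) / win
    smoothed = np.convolve(trace, kernel, mode="same")
    rows = []
    for ep in schedule.epochs:
        if ep.kind != "bar":
            continue
        sel = (times >= ep.t_on_s - 1e-9) & (times <= ep.t_off_s + 1.0 + 1e-9)
        if not sel.any():
            warnings.warn(f"speed condition {ep.speed_um_s} µm/s outside recording; omitted")
            continue
        rows.append(
            {
                "speed_um_s": ep.speed_um_s,
                "direction_deg": ep.direction_deg,
                "trial": ep.trial,
                "peak_windowed_dff": float(smoothed[sel].max()),
            }
        )
    df = pd.DataFrame(rows)
    return (
        df.groupby(["speed_um_s", "direction_deg"])["peak_windowed_dff"].mean().reset_index()
    )


def spot_response_integral(
    traces: "RoiTraceSet",
    schedule: "StimulusSchedule",
    roi_index: int = 0,
) -> pd.DataFrame:
    """Time-integral (trapezoidal) of ΔF/F over each spot presentation window.

    Returns one row per spot diameter with the trial-mean integral over the
    stimulus duration (2 s in the standard protocol).
    """
    if traces.dff is None:
        raise ValueError("compute_dff must be called first")
    times = traces.times
    trace = traces.dff[roi_index]
    rows = []
    for ep in schedule.epochs:
        if ep.kind != "spot":
            continue
        sel = (times >= ep.t_on_s - 1e-9) & (times <= ep.t_off_s + 1e-9)
        rows.append(
            {
                "diameter_um": ep.diameter_um,
                "trial": ep.trial,
                "integral_dff_s": float(np.trapezoid(trace[sel], times[sel])),
            }
        )
    df = pd.DataFrame(rows)
    return df.groupby("diameter_um")["integral_dff_s"].mean().reset_index()


# ---------------------------------------------------------------------------
# group statistics


def compare_groups(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) between independent groups.

    Uses the exact null distribution when there are no ties, matching hand
    enumeration at small n. Returns (statistic, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("each group needs at least one observation")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def compare_paired(before: Sequence[float], after: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test for paired before/after data.

    Identical pairs (all zero differences) are a degenerate case and return
    p = 1 with a warning rather than an error.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired samples must have equal length")
    diffs = after - before
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; signed-rank test degenerate")
        return 0.0, 1.0
    res = stats.wilcoxon(before, after, zero_method="wilcox", alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
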