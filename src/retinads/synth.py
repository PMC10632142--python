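"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here: drifting-bar
calcium movies containing von Mises-tuned and untuned cells, random /
exclusion-zone / superposed soma mosaics, bimodal two-marker intensity tables,
FISH-style integrated-intensity tables, and two-condition expression count
matrices with controllable fold changes. All generators are deterministic
given a seed.

The movie generator emulates a two-photon recording of the ganglion cell
layer during a drifting-bar protocol: each model cell responds to a bar epoch
with amplitude ``r_max * exp(kappa * (cos(theta - mu) - 1))`` (the von Mises
tuning curve, equal to ``r_max`` at the preferred direction ``mu`` and flat
when ``kappa = 0``), with onset at the time the bar's leading edge crosses the
soma centre and an exponential indicator-decay kernel. Somas are rendered as
isotropic 2D Gaussians (sigma = radius/2, truncated at 3 sigma). Optics,
motion artefacts and vascular shadowing are not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .imaging import CalciumMovie

STANDARD_DIRECTIONS = tuple(float(d) for d in range(0, 360, 45))


# ---------------------------------------------------------------------------
# stimulus schedule


@dataclass(frozen=True)
class Epoch:
    """One stimulus presentation.

    ``direction_deg`` is the direction of stimulus motion on the retina;
    geometry is the bar width/length (µm) for bars or the diameter for spots.
    """

    direction_deg: float
    speed_um_s: float
    t_on_s: float
    t_off_s: float
    kind: Literal["bar", "spot"] = "bar"
    width_um: float = 500.0
    length_um: float = 750.0
    diameter_um: float = 0.0
    trial: int = 0

    @property
    def duration_s(self) -> float:
        return self.t_off_s - self.t_on_s


@dataclass(frozen=True)
class StimulusSchedule:
    """Time-ordered, non-overlapping stimulus epochs with block structure."""

    epochs: tuple[Epoch, ...]
    n_trials: int = 3
    inter_stimulus_s: float = 5.0

    def __post_init__(self) -> None:
        t_prev = -math.inf
        for ep in self.epochs:
            if ep.t_off_s <= ep.t_on_s:
                raise ValueError("epoch with non-positive duration")
            if ep.t_on_s < t_prev:
                raise ValueError("epochs overlap or are out of order")
            t_prev = ep.t_off_s

    @property
    def directions(self) -> tuple[float, ...]:
        return tuple(sorted({ep.direction_deg for ep in self.epochs if ep.kind == "bar"}))

    @property
    def t_first_on(self) -> float:
        return self.epochs[0].t_on_s

    @property
    def t_end(self) -> float:
        return self.epochs[-1].t_off_s


def make_bar_schedule(
    directions: Sequence[float] = STANDARD_DIRECTIONS,
    n_trials: int = 3,
    speed_um_s: float = 500.0,
    bar_width_um: float = 500.0,
    bar_length_um: float = 750.0,
    inter_stimulus_s: float = 5.0,
    pre_stimulus_s: float = 35.0,
    travel_um: float = 750.0,
    seed: int | None = None,
) -> StimulusSchedule:
    """Build a pseudorandomized drifting-bar schedule.

    Directions are shuffled within each block so that every direction is
    presented once before any repeats; defaults follow the standard
    8-direction protocol (500 µm/s, 5 s inter-stimulus interval, 35 s of
    pre-stimulus recording for baseline estimation). ``travel_um`` is the
    distance the leading edge travels within an epoch and must cover the scan
    field so every soma is crossed.
    """
    rng = np.random.default_rng(seed)
    dur = (travel_um + bar_width_um) / speed_um_s
    epochs: list[Epoch] = []
    t = pre_stimulus_s
    for trial in range(n_trials):
        block = list(directions)
        if seed is not None:
            rng.shuffle(block)
        for d in block:
            epochs.append(
                Epoch(
                    direction_deg=float(d) % 360.0,
                    speed_um_s=speed_um_s,
                    t_on_s=t,
                    t_off_s=t + dur,
                    kind="bar",
                    width_um=bar_width_um,
                    length_um=bar_length_um,
                    trial=trial,
                )
            )
            t += dur + inter_stimulus_s
    return StimulusSchedule(tuple(epochs), n_trials=n_trials, inter_stimulus_s=inter_stimulus_s)


def make_spot_schedule(
    diameters_um: Sequence[float],
    n_trials: int = 1,
    duration_s: float = 2.0,
    inter_stimulus_s: float = 5.0,
    pre_stimulus_s: float = 35.0,
) -> StimulusSchedule:
    """Build a schedule of stationary spot presentations of increasing diameter."""
    epochs = []
    t = pre_stimulus_s
    for trial in range(n_trials):
        for d in diameters_um:
            epochs.append(
                Epoch(
                    direction_deg=0.0,
                    speed_um_s=0.0,
                    t_on_s=t,
                    t_off_s=t + duration_s,
                    kind="spot",
                    diameter_um=float(d),
                    trial=trial,
                )
            )
            t += duration_s + inter_stimulus_s
    return StimulusSchedule(tuple(epochs), n_trials=n_trials, inter_stimulus_s=inter_stimulus_s)


# ---------------------------------------------------------------------------
# ground-truth cells and movie generation


@dataclass(frozen=True)
class GroundTruthCell:
    """Model cell with known tuning.

    ``kappa = 0`` gives an untuned (but responsive) cell; ``r_max`` is the
    peak ΔF/F at the preferred direction ``mu_deg``.
    """

    center_xy_um: tuple[float, float]
    radius_um: float = 5.0
    baseline_f0: float = 100.0
    r_max: float = 1.0
    mu_deg: float = 0.0
    kappa: float = 0.0
    indicator_tau_s: float = 0.5
    class_label: str = "other"

    def __post_init__(self) -> None:
        if self.kappa < 0 or self.r_max < 0 or self.baseline_f0 <= 0:
            raise ValueError("require kappa >= 0, r_max >= 0, baseline_f0 > 0")

    def tuning_amplitude(self, direction_deg: float) -> float:
        """von Mises response amplitude for a bar moving in ``direction_deg``."""
        delta = math.radians(direction_deg - self.mu_deg)
        return self.r_max * math.exp(self.kappa * (math.cos(delta) - 1.0))


@dataclass
class SynthMovieBundle:
    """A generated movie plus the schedule and ground truth that produced it."""

    movie: CalciumMovie
    schedule: StimulusSchedule
    truth: list[GroundTruthCell]
    seed: int | None

    def soma_masks(self) -> list[np.ndarray]:
        """Boolean disk masks (radius = soma radius) for each ground-truth cell."""
        _, ny, nx = self.movie.stack.shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        masks = []
        for c in self.truth:
            cx = c.center_xy_um[0] * self.movie.px_per_um
            cy = c.center_xy_um[1] * self.movie.px_per_um
            r = max(c.radius_um * self.movie.px_per_um, 1.0)
            masks.append((xx - cx) ** 2 + (yy - cy) ** 2 <= r**2)
        return masks


def _epoch_waveform(
    t: np.ndarray, t0: float, dur: float, tau: float
) -> np.ndarray:
    """Boxcar response convolved with an exponential indicator kernel.

    Normalised so the continuous-time peak equals 1 (reached at the end of
    the crossing); decays with time constant ``tau`` afterwards.
    """
    w = np.zeros_like(t)
    rise = (t >= t0) & (t < t0 + dur)
    w[rise] = 1.0 - np.exp(-(t[rise] - t0) / tau)
    decay = t >= t0 + dur
    peak = 1.0 - math.exp(-dur / tau)
    w[decay] = peak * np.exp(-(t[decay] - t0 - dur) / tau)
    return w / peak


def cell_dff_trace(
    cell: GroundTruthCell,
    schedule: StimulusSchedule,
    times: np.ndarray,
    field_um: tuple[float, float],
) -> np.ndarray:
    """Noise-free ΔF/F time course of one model cell under a schedule.

    Bar epochs: the response begins when the bar's leading edge reaches the
    soma centre and lasts ``width/speed``. Spot epochs: the cell responds with
    ``r_max`` for the spot duration when its centre lies inside the spot
    (spots are centred on the field).
    """
    dff = np.zeros_like(times)
    half_diag = 0.5 * math.hypot(*field_um)
    cx = cell.center_xy_um[0] - field_um[0] / 2.0
    cy = cell.center_xy_um[1] - field_um[1] / 2.0
    for ep in schedule.epochs:
        if ep.kind == "bar":
            amp = cell.tuning_amplitude(ep.direction_deg)
            if amp <= 0:
                continue
            th = math.radians(ep.direction_deg)
            proj = cx * math.cos(th) + cy * math.sin(th)
            t0 = ep.t_on_s + (proj + half_diag) / ep.speed_um_s
            dur = ep.width_um / ep.speed_um_s
        else:
            if math.hypot(cx, cy) > ep.diameter_um / 2.0:
                continue
            amp = cell.r_max
            t0 = ep.t_on_s
            dur = ep.duration_s
        dff += amp * _epoch_waveform(times, t0, dur, cell.indicator_tau_s)
    return dff


def generate_movie(
    field_um: tuple[float, float],
    px_per_um: float,
    frame_rate_hz: float,
    cells: Sequence[GroundTruthCell],
    schedule: StimulusSchedule,
    noise_sd: float = 0.0,
    seed: int | None = None,
    noise_model: Literal["gaussian", "poisson"] = "gaussian",
    post_stimulus_s: float = 3.0,
    duration_s: float | None = None,
) -> SynthMovieBundle:
    """Render a synthetic calcium movie of model cells under a stimulus schedule.

    Parameters
    ----------
    field_um : (width, height) of the scan field in µm.
    noise_sd : per-pixel, per-frame additive Gaussian noise (raw fluorescence
        units). With ``noise_model="poisson"`` pixel values are Poisson draws
        around the noiseless value instead.
    duration_s : recording length; defaults to schedule end + ``post_stimulus_s``.

    Raises
    ------
    ValueError
        If a cell lies outside the field or the schedule does not fit inside
        the requested duration.
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be positive")
    for c in cells:
        x, y = c.center_xy_um
        if not (0 <= x <= field_um[0] and 0 <= y <= field_um[1]):
            raise ValueError(f"cell at {c.center_xy_um} lies outside the field {field_um}")
    if duration_s is None:
        duration_s = schedule.t_end + post_stimulus_s
    if schedule.t_end > duration_s:
        raise ValueError("schedule extends beyond the movie duration")

    n_frames = int(round(duration_s * frame_rate_hz))
    ny = int(round(field_um[1] * px_per_um))
    nx = int(round(field_um[0] * px_per_um))
    times = np.arange(n_frames) / frame_rate_hz
    stack = np.zeros((n_frames, ny, nx), dtype=np.float64)

    yy, xx = np.mgrid[0:ny, 0:nx]
    for c in cells:
        f_t = c.baseline_f0 * (1.0 + cell_dff_trace(c, schedule, times, field_um))
        cx = c.center_xy_um[0] * px_per_um
        cy = c.center_xy_um[1] * px_per_um
        sigma = max(c.radius_um * px_per_um / 2.0, 0.5)
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        blob = np.exp(-r2 / (2 * sigma**2))
        blob[r2 > (3 * sigma) ** 2] = 0.0  # truncate at 3 sigma
        ys, xs = np.nonzero(blob)
        stack[:, ys, xs] += f_t[:, None] * blob[ys, xs][None, :]

    rng = np.random.default_rng(seed)
    if noise_model == "poisson":
        stack = rng.poisson(np.clip(stack, 0, None)).astype(np.float64)
    elif noise_sd > 0:
        stack += rng.normal(0.0, noise_sd, size=stack.shape)
    movie = CalciumMovie(
        stack=stack.astype(np.float32),
        frame_rate_hz=frame_rate_hz,
        px_per_um=px_per_um,
    )
    return SynthMovieBundle(movie=movie, schedule=schedule, truth=list(cells), seed=seed)


def place_cells(
    n_cells: int,
    field_um: tuple[float, float],
    radius_um: float = 5.0,
    min_separation_um: float | None = None,
    margin_um: float | None = None,
    seed: int | None = None,
    **cell_kwargs,
) -> list[GroundTruthCell]:
    """Scatter non-overlapping model somas uniformly inside the scan field."""
    rng = np.random.default_rng(seed)
    if margin_um is None:
        margin_um = 3 * radius_um
    if min_separation_um is None:
        min_separation_um = 2.5 * radius_um
    pts: list[tuple[float, float]] = []
    budget = 10_000 * n_cells
    while len(pts) < n_cells and budget > 0:
        budget -= 1
        x = rng.uniform(margin_um, field_um[0] - margin_um)
        y = rng.uniform(margin_um, field_um[1] - margin_um)
        if all(math.hypot(x - px, y - py) >= min_separation_um for px, py in pts):
            pts.append((x, y))
    if len(pts) < n_cells:
        raise RuntimeError(f"could not place {n_cells} cells; placed {len(pts)}")
    return [GroundTruthCell(center_xy_um=p, radius_um=radius_um, **cell_kwargs) for p in pts]


def make_ds_field(
    n_ds: int = 5,
    n_other: int = 15,
    field_um: tuple[float, float] = (160.0, 160.0),
    kappa_ds: float = 4.0,
    r_max: float = 1.0,
    baseline_f0: float = 100.0,
    snr: float = 5.0,
    n_trials: int = 3,
    frame_rate_hz: float = 4.0,
    px_per_um: float = 1.0,
    seed: int | None = 0,
) -> SynthMovieBundle:
    """Standard test field: a few DS cells among untuned-but-responsive cells.

    Emulates a GCL scan field in which a minority of somas are
    direction-selective (von Mises ``kappa_ds``, random preferred
    directions) and the rest respond equally to all directions. ``snr`` is
    the peak somatic signal (baseline_f0 * r_max) over the per-pixel noise
    sd. Uses the standard 8-direction, 3-trial drifting-bar protocol.
    """
    rng = np.random.default_rng(seed)
    base = place_cells(
        n_ds + n_other, field_um, radius_um=5.0, min_separation_um=18.0, seed=seed
    )
    cells = [
        GroundTruthCell(
            center_xy_um=c.center_xy_um,
            radius_um=c.radius_um,
            baseline_f0=baseline_f0,
            r_max=r_max,
            mu_deg=float(rng.uniform(0, 360)),
            kappa=kappa_ds if i < n_ds else 0.0,
            class_label="pRGC10-like" if i < n_ds else "other",
        )
        for i, c in enumerate(base)
    ]
    schedule = make_bar_schedule(
        n_trials=n_trials,
        pre_stimulus_s=25.0,
        travel_um=float(np.hypot(*field_um)),
        seed=seed,
    )
    return generate_movie(
        field_um,
        px_per_um,
        frame_rate_hz,
        cells,
        schedule,
        noise_sd=baseline_f0 * r_max / snr if snr > 0 else 0.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# mosaics


def generate_mosaic(
    kind: Literal["random", "exclusion", "superposition"],
    density_per_mm2: float,
    region_um: tuple[float, float],
    d_min_um: float | None = None,
    n_mosaics: int = 3,
    seed: int | None = None,
):
    """Generate a 2D soma mosaic within a rectangular region.

    ``random``: uniform i.i.d. points. ``exclusion``: hard-core (dart-throwing
    with rejection; no pair closer than ``d_min_um``). ``superposition``: the
    union of ``n_mosaics`` independent exclusion mosaics, each at
    ``density/n_mosaics`` — the generative model for several independently
    tiling subtypes whose pooled somas look random.

    Returns a :class:`retinads.mosaic.PointMosaic`; for superposition the
    labels record the component mosaic of each point.
    """
    from .mosaic import PointMosaic

    w, h = region_um
    area_mm2 = w * h * 1e-6
    n = int(round(density_per_mm2 * area_mm2))
    if n < 10:
        raise ValueError("density * area must give at least 10 points")
    rng = np.random.default_rng(seed)

    if kind == "random":
        pts = np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])
        return PointMosaic(points_um=pts, region_um=region_um)
    if kind == "exclusion":
        if d_min_um is None:
            raise ValueError("exclusion mosaics require d_min_um")
        pts = _hardcore(n, w, h, d_min_um, rng)
        return PointMosaic(points_um=pts, region_um=region_um)
    if kind == "superposition":
        if d_min_um is None:
            raise ValueError("superposition mosaics require d_min_um for each component")
        all_pts, labels = [], []
        per = density_per_mm2 / n_mosaics
        for i in range(n_mosaics):
            ni = int(round(per * area_mm2))
            pts = _hardcore(ni, w, h, d_min_um, rng)
            all_pts.append(pts)
            labels.extend([f"mosaic_{i}"] * len(pts))
        return PointMosaic(
            points_um=np.vstack(all_pts), region_um=region_um, labels=np.array(labels)
        )
    raise ValueError(f"unknown mosaic kind {kind!r}")


def _hardcore(n: int, w: float, h: float, d_min: float, rng: np.random.Generator) -> np.ndarray:
    """Sequential-rejection hard-core sampling; budget 10^4 darts per point."""
    pts: list[np.ndarray] = []
    budget = 10_000 * n
    d2 = d_min * d_min
    while len(pts) < n and budget > 0:
        budget -= 1
        p = np.array([rng.uniform(0, w), rng.uniform(0, h)])
        if not pts:
            pts.append(p)
            continue
        arr = np.asarray(pts)
        if np.min(np.sum((arr - p) ** 2, axis=1)) >= d2:
            pts.append(p)
    if len(pts) < n:
        raise RuntimeError(
            f"hard-core packing infeasible: placed {len(pts)} of {n} points "
            f"at d_min={d_min} µm"
        )
    return np.asarray(pts)


# ---------------------------------------------------------------------------
# marker-intensity tables


def generate_marker_table(
    n_cells: int,
    class_fractions: dict[str, float],
    channel_means: dict[str, dict[str, float]],
    channel_sds: dict[str, dict[str, float]],
    seed: int | None = None,
    batch_id: str = "batch0",
) -> pd.DataFrame:
    """Per-cell marker intensities from class-conditional Gaussians.

    ``channel_means[class][channel]`` gives the mean intensity of ``channel``
    in cells of ``class``; true labels are retained in ``true_label``.
    """
    total = sum(class_fractions.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError("class fractions must sum to 1")
    for cls, sds in channel_sds.items():
        for ch, sd in sds.items():
            if sd <= 0:
                raise ValueError(f"non-positive sd for class {cls!r} channel {ch!r}")
    rng = np.random.default_rng(seed)
    classes = list(class_fractions)
    labels = rng.choice(classes, size=n_cells, p=[class_fractions[c] for c in classes])
    channels = list(next(iter(channel_means.values())))
    rows = {
        ch: np.array(
            [rng.normal(channel_means[lab][ch], channel_sds[lab][ch]) for lab in labels]
        )
        for ch in channels
    }
    df = pd.DataFrame(rows)
    df.insert(0, "cell_id", [f"cell_{i:05d}" for i in range(n_cells)])
    df["true_label"] = labels
    df["batch_id"] = batch_id
    return df


# ---------------------------------------------------------------------------
# expression matrices


def generate_expression_matrix(
    n_genes: int,
    cluster_sizes: dict[str, int],
    cluster_pairs: Sequence[tuple[str, str]],
    fold_changes: dict[tuple[str, str], float] | None = None,
    mean_expression: float = 5.0,
    dispersion: float = 0.5,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial count matrix for paired foveal/peripheral clusters.

    ``cluster_pairs`` lists (foveal_id, peripheral_id) partners; every cluster
    in ``cluster_sizes`` must appear in a pair. ``fold_changes`` maps
    ``(gene_name, cluster_id)`` to a natural-log fold applied to that
    cluster's mean for that gene (e.g. -3.0 for a 3-log drop). Gene names are
    ``g0000``, ``g0001``, ...

    Returns (counts DataFrame genes x cells, per-cell cluster labels).
    """
    paired = {c for pair in cluster_pairs for c in pair}
    unpaired = set(cluster_sizes) - paired
    if unpaired:
        raise ValueError(f"clusters without a declared partner: {sorted(unpaired)}")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    base_mu = rng.lognormal(mean=math.log(mean_expression), sigma=0.5, size=n_genes)
    fold_changes = fold_changes or {}

    cols, labels = [], []
    blocks = []
    for cl, size in cluster_sizes.items():
        mu = base_mu.copy()
        for (gene, target), lfc in fold_changes.items():
            if target == cl:
                mu[genes.index(gene)] *= math.exp(lfc)
        # NB with mean mu and dispersion r: p = r/(r+mu)
        r = 1.0 / dispersion
        p = r / (r + mu)
        blocks.append(rng.negative_binomial(r, p[:, None], size=(n_genes, size)))
        cols.extend(f"{cl}_c{i:04d}" for i in range(size))
        labels.extend([cl] * size)
    counts = pd.DataFrame(np.hstack(blocks), index=genes, columns=cols)
    return counts, pd.Series(labels, index=cols, name="cluster")


# ---------------------------------------------------------------------------
# synthetic volumes for contact analysis


def generate_wrapped_volumes(
    shape: tuple[int, int, int] = (20, 64, 64),
    n_segments: int = 6,
    wrap: bool = True,
    clutter_fraction: float = 0.01,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary reference/partner volumes where partner processes wrap the reference.

    The reference mask is a set of random straight 'dendrite' segments; the
    partner (when ``wrap``) is a one-voxel dilated sheath with random voxel
    dropout — it follows and overlaps the reference the way wrap-around
    processes imaged at finite resolution do — plus sparse random clutter.
    Used to exercise the rotation-control contact statistic.
    """
    from scipy.ndimage import binary_dilation

    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    ref = np.zeros(shape, dtype=bool)
    for _ in range(n_segments):
        z = rng.integers(2, nz - 2)
        x0, y0 = rng.uniform(5, nx - 5), rng.uniform(5, ny - 5)
        ang = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(15, min(nx, ny) * 0.6)
        for s in np.linspace(0, length, int(length * 2)):
            x = int(round(x0 + s * np.cos(ang)))
            y = int(round(y0 + s * np.sin(ang)))
            if 0 <= x < nx and 0 <= y < ny:
                ref[z, y, x] = True
    partner = np.zeros(shape, dtype=bool)
    if wrap:
        sheath = binary_dilation(ref, iterations=1)
        partner = sheath & (rng.random(shape) < 0.6)
    partner |= rng.random(shape) < clutter_fraction
    return ref, partner
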