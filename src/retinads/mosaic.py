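"""Spatial statistics of retinal cell mosaics.

A cell type that tiles the retina places its somas in a quasi-regular
mosaic. Two classic statistics quantify this:

* the Voronoi domain regularity index (VDRI) — mean Voronoi domain area
  divided by its standard deviation, with domains intersecting the sampling
  boundary excluded. Uniform random points give VDRI ≈ 1.9; regular mosaics
  give higher values. Observed VDRIs are compared against random simulations
  at matched density.
* the density recovery profile (DRP) — neighbour density as a function of
  distance in 20-µm annuli out to 1 mm, edge-corrected by the analytic
  annulus ∩ region area per reference point. A central "well" of low density
  reveals an exclusion zone; its depth relative to the 390–1000 µm plateau
  (the convergence percentage) quantifies how complete the exclusion is.
  The union of several independent regular mosaics shows neither a raised
  VDRI nor a well, which is how superposed subtype mosaics are detected.

All coordinates are in µm; densities are reported per mm².
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import Point, Polygon

from .units import UM2_PER_MM2

RegionLike = Union[tuple[float, float], Polygon]

DRP_BIN_UM = 20.0
DRP_MAX_UM = 1000.0
DRP_PLATEAU_MIN_UM = 390.0  # bin centres >= this form the plateau
DRP_WELL_BINS = 3


def _region_polygon(region: RegionLike) -> Polygon:
    if isinstance(region, Polygon):
        return region
    w, h = region
    return Polygon([(0, 0), (w, 0), (w, h), (0, h)])


@dataclass
class PointMosaic:
    """2D soma coordinates (µm) within a bounded sampling region."""

    points_um: np.ndarray
    region_um: RegionLike
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points_um = np.asarray(self.points_um, dtype=float)
        if self.points_um.ndim != 2 or self.points_um.shape[1] != 2:
            raise ValueError("points_um must be an (n, 2) array")
        poly = _region_polygon(self.region_um)
        eps = 1e-9
        for p in self.points_um:
            if not poly.buffer(eps).contains(Point(p)):
                raise ValueError(f"point {p} lies outside the sampling region")

    @property
    def n(self) -> int:
        return len(self.points_um)

    @property
    def area_mm2(self) -> float:
        return _region_polygon(self.region_um).area / UM2_PER_MM2

    @property
    def density_per_mm2(self) -> float:
        return self.n / self.area_mm2

    def subset(self, label: str) -> "PointMosaic":
        if self.labels is None:
            raise ValueError("mosaic has no labels")
        sel = self.labels == label
        return PointMosaic(self.points_um[sel], self.region_um)


# ---------------------------------------------------------------------------
# Voronoi regularity


@dataclass
class VoronoiResult:
    areas_um2: np.ndarray  # retained (border-excluded) domain areas
    excluded: np.ndarray  # per-point flag: True if the domain was excluded
    vdri: float  # inf (flagged) when retained areas have zero spread

    @property
    def n_retained(self) -> int:
        return len(self.areas_um2)


def _polygon_area(verts: np.ndarray) -> float:
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def voronoi_regularity(mosaic: PointMosaic) -> VoronoiResult:
    """Voronoi tessellation with border exclusion and the regularity index.

    A domain is excluded when it is unbounded or any of its vertices lies
    outside or on the region boundary. VDRI = mean(area) / sd(area)
    (population sd) over the retained domains; a zero-spread set of areas
    (perfect lattice) is flagged as infinite.
    """
    if mosaic.n < 4:
        raise ValueError("need at least 4 points for a Voronoi tessellation")
    vor = Voronoi(mosaic.points_um)
    poly = _region_polygon(mosaic.region_um)
    is_rect = not isinstance(mosaic.region_um, Polygon)
    if is_rect:
        w, h = mosaic.region_um

    areas = []
    excluded = np.ones(mosaic.n, dtype=bool)
    for i, reg_i in enumerate(vor.point_region):
        reg = vor.regions[reg_i]
        if len(reg) == 0 or -1 in reg:
            continue
        verts = vor.vertices[reg]
        if is_rect:
            inside = (
                (verts[:, 0] > 0).all()
                and (verts[:, 0] < w).all()
                and (verts[:, 1] > 0).all()
                and (verts[:, 1] < h).all()
            )
        else:
            inside = all(poly.contains(Point(v)) for v in verts)
        if not inside:
            continue
        excluded[i] = False
        areas.append(_polygon_area(verts))
    areas = np.asarray(areas)
    if len(areas) == 0:
        raise ValueError("all Voronoi domains intersect the region boundary")
    sd = areas.std() if len(areas) > 1 else 0.0
    vdri = float("inf") if sd == 0 else float(areas.mean() / sd)
    return VoronoiResult(areas_um2=areas, excluded=excluded, vdri=vdri)


@dataclass
class NullVdri:
    vdris: np.ndarray
    mean: float
    sd: float
    observed: float | None = None
    observed_quantile: float | None = None  # empirical quantile of observed in null

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.vdris, q))


def random_null_vdri(
    n: int,
    region: RegionLike,
    n_sims: int = 99,
    seed: int | None = None,
    observed: float | None = None,
) -> NullVdri:
    """VDRI null distribution from uniform random mosaics at matched n/region.

    Exact-n matching in the same region; the observed VDRI's empirical
    quantile within the null is reported when given.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if n_sims == 1:
        warnings.warn("n_sims=1 gives a degenerate null summary")
    rng = np.random.default_rng(seed)
    poly = _region_polygon(region)
    minx, miny, maxx, maxy = poly.bounds
    is_rect = not isinstance(region, Polygon)
    vals = np.empty(n_sims)
    for s in range(n_sims):
        pts = []
        while len(pts) < n:
            cand = np.column_stack(
                [rng.uniform(minx, maxx, n), rng.uniform(miny, maxy, n)]
            )
            if is_rect:
                pts.extend(cand.tolist())
            else:
                pts.extend(c for c in cand.tolist() if poly.contains(Point(c)))
        pts = np.asarray(pts[:n])
        vals[s] = voronoi_regularity(PointMosaic(pts, region)).vdri
    quant = None
    if observed is not None:
        quant = float(np.mean(vals < observed))
    return NullVdri(
        vdris=vals,
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=0)),
        observed=observed,
        observed_quantile=quant,
    )


# ---------------------------------------------------------------------------
# density recovery profile


def _quadrant_area(a: np.ndarray, b: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Area of {0<=x<=a, 0<=y<=b} ∩ disc of radius r at the origin (a, b > 0)."""

    def G(x: np.ndarray, r: np.ndarray) -> np.ndarray:
        x = np.minimum(x, r)
        return 0.5 * (x * np.sqrt(np.maximum(r**2 - x**2, 0.0)) + r**2 * np.arcsin(np.clip(x / np.where(r > 0, r, 1.0), -1, 1)))

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    r = np.asarray(r, dtype=float)
    a_c = np.minimum(a, r)
    out = np.where(b >= r, G(a_c, r), 0.0)
    lo = b < r
    if np.any(lo):
        x_b = np.sqrt(np.maximum(r**2 - b**2, 0.0))
        inside = a_c <= x_b
        out = np.where(
            lo & inside,
            b * a_c,
            np.where(lo, b * x_b + G(a_c, r) - G(x_b, r), out),
        )
    return np.where(r <= 0, 0.0, out)


def disc_region_area(points: np.ndarray, radii: np.ndarray, region: RegionLike) -> np.ndarray:
    """Area of disc(point, r) ∩ region for each point and radius: (n, m) array.

    Closed form for rectangular regions; shapely buffers for polygons.
    """
    points = np.asarray(points, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if not isinstance(region, Polygon):
        w, h = region
        px, py = points[:, 0][:, None], points[:, 1][:, None]
        r = radii[None, :]
        return (
            _quadrant_area(px, py, r)
            + _quadrant_area(w - px, py, r)
            + _quadrant_area(px, h - py, r)
            + _quadrant_area(w - px, h - py, r)
        )
    out = np.zeros((len(points), len(radii)))
    for i, p in enumerate(points):
        for j, r in enumerate(radii):
            if r <= 0:
                continue
            out[i, j] = Point(p).buffer(r, quad_segs=64).intersection(region).area
    return out


@dataclass
class DrpProfile:
    bin_edges_um: np.ndarray  # 0..1000 in 20-µm steps
    density_per_mm2: np.ndarray  # one per annulus
    n_reference: int
    well_density: float  # mean of the 3 lowest bins (first bin excluded)
    plateau_density: float  # mean density over 390-1000 µm
    convergence_pct: float  # well / plateau x 100

    @property
    def bin_centers_um(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_um[:-1] + self.bin_edges_um[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_inner_um": self.bin_edges_um[:-1],
                "r_outer_um": self.bin_edges_um[1:],
                "density_per_mm2": self.density_per_mm2,
            }
        )


def density_recovery_profile(
    mosaic: PointMosaic,
    bin_um: float = DRP_BIN_UM,
    max_r_um: float = DRP_MAX_UM,
) -> DrpProfile:
    """Edge-corrected density recovery profile of a point mosaic.

    For every reference point, neighbours are counted per 20-µm annulus out
    to 1 mm; each annulus area is corrected by its intersection with the
    sampling region, and density(r) = Σ counts / Σ corrected areas. The well
    density is the mean of the 3 lowest-density bins (the first bin is
    excluded for its elevated variability); the plateau is the mean density
    from 390–1000 µm; convergence is their ratio in percent.
    """
    if mosaic.n < 10:
        raise ValueError("need at least 10 points for a DRP")
    poly = _region_polygon(mosaic.region_um)
    minx, miny, maxx, maxy = poly.bounds
    if max_r_um > min(maxx - minx, maxy - miny):
        warnings.warn(
            "region smaller than the maximum DRP radius; outer annuli are clipped"
        )
    edges = np.arange(0.0, max_r_um + bin_um / 2, bin_um)
    pts = mosaic.points_um
    diff = pts[:, None, :] - pts[None, :, :]
    dists = np.sqrt((diff**2).sum(axis=-1))
    iu = ~np.eye(len(pts), dtype=bool)
    counts, _ = np.histogram(dists[iu], bins=edges)

    disc_areas = disc_region_area(pts, edges, mosaic.region_um)  # (n, n_edges)
    annulus_areas = (disc_areas[:, 1:] - disc_areas[:, :-1]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(annulus_areas > 0, counts / annulus_areas, np.nan) * UM2_PER_MM2

    centers = 0.5 * (edges[:-1] + edges[1:])
    interior = density[1:]  # first bin excluded from the well search
    finite = interior[np.isfinite(interior)]
    well = float(np.mean(np.sort(finite)[:DRP_WELL_BINS]))
    plateau_sel = centers >= DRP_PLATEAU_MIN_UM
    plateau = float(np.nanmean(density[plateau_sel]))
    conv = float("nan") if plateau == 0 else well / plateau * 100.0
    return DrpProfile(
        bin_edges_um=edges,
        density_per_mm2=density,
        n_reference=mosaic.n,
        well_density=well,
        plateau_density=plateau,
        convergence_pct=conv,
    )


# ---------------------------------------------------------------------------
# density and coverage


def coverage_factor(density_per_mm2: float, dendritic_area_mm2: float) -> float:
    """Cell density × dendritic field area; 1.0 means exact tiling, higher
    values indicate overlapping arbours."""
    if density_per_mm2 < 0 or dendritic_area_mm2 < 0:
        raise ValueError("density and dendritic area must be non-negative")
    return density_per_mm2 * dendritic_area_mm2


def density_grid(
    points: np.ndarray,
    region_um: tuple[float, float],
    cell_um: float = 500.0,
    bad_cells: np.ndarray | None = None,
) -> np.ndarray:
    """Cell densities (per mm²) on a grid of ``cell_um`` squares.

    Cells flagged in ``bad_cells`` (poor focus, damaged tissue) are replaced
    by the mean of their valid 8-neighbours; a flagged cell with no valid
    neighbour is left NaN with a warning. Only full grid squares are used.
    """
    points = np.asarray(points, dtype=float)
    w, h = region_um
    nx, ny = int(w // cell_um), int(h // cell_um)
    if nx < 1 or ny < 1:
        raise ValueError("region must cover at least one full grid cell")
    grid = np.zeros((ny, nx))
    cell_area_mm2 = (cell_um**2) / UM2_PER_MM2
    for x, y in points:
        ix, iy = int(x // cell_um), int(y // cell_um)
        if 0 <= ix < nx and 0 <= iy < ny:
            grid[iy, ix] += 1
    grid /= cell_area_mm2
    if bad_cells is None:
        return grid
    bad = np.asarray(bad_cells, dtype=bool)
    if bad.shape != grid.shape:
        raise ValueError("bad_cells must match the grid shape")
    out = grid.copy()
    for iy, ix in zip(*np.nonzero(bad)):
        neigh = []
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == dx == 0:
                    continue
                jy, jx = iy + dy, ix + dx
                if 0 <= jy < ny and 0 <= jx < nx and not bad[jy, jx]:
                    neigh.append(grid[jy, jx])
        if neigh:
            out[iy, ix] = float(np.mean(neigh))
        else:
            warnings.warn(f"flagged grid cell ({iy},{ix}) has no valid neighbour")
            out[iy, ix] = np.nan
    return out


def equivalent_eccentricity(x_mm_nasal: float, y_mm_vertical: float) -> float:
    """Equivalent eccentricity √((0.61·x)² + y²) for nasal-retina coordinates.

    ``x`` is mm nasal to the foveal centre (weighted 0.61), ``y`` mm superior
    or inferior.
    """
    return math.hypot(0.61 * x_mm_nasal, y_mm_vertical)
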