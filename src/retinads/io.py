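"""Reading and writing the pipeline's file formats.

Movies are multi-page TIFF with a JSON sidecar (schedule, ground truth,
seed, pixel size, frame rate); point mosaics, marker tables and response
tables are CSV; expression matrices are MatrixMarket plus a label CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import io as spio

from .imaging import CalciumMovie
from .mosaic import PointMosaic
from .synth import Epoch, GroundTruthCell, StimulusSchedule, SynthMovieBundle


def save_movie_bundle(bundle: SynthMovieBundle, tiff_path: str | Path) -> Path:
    """Write a movie as TIFF plus a ``.json`` sidecar; returns the sidecar path."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, bundle.movie.stack)
    sidecar = tiff_path.with_suffix(".json")
    meta = {
        "frame_rate_hz": bundle.movie.frame_rate_hz,
        "px_per_um": bundle.movie.px_per_um,
        "t0_s": bundle.movie.t0_s,
        "seed": bundle.seed,
        "schedule": {
            "n_trials": bundle.schedule.n_trials,
            "inter_stimulus_s": bundle.schedule.inter_stimulus_s,
            "epochs": [dataclasses.asdict(e) for e in bundle.schedule.epochs],
        },
        "truth": [dataclasses.asdict(c) for c in bundle.truth],
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def load_movie_bundle(tiff_path: str | Path) -> SynthMovieBundle:
    tiff_path = Path(tiff_path)
    meta = json.loads(tiff_path.with_suffix(".json").read_text())
    movie = CalciumMovie(
        stack=tifffile.imread(tiff_path),
        frame_rate_hz=meta["frame_rate_hz"],
        px_per_um=meta["px_per_um"],
        t0_s=meta.get("t0_s", 0.0),
    )
    schedule = StimulusSchedule(
        epochs=tuple(Epoch(**e) for e in meta["schedule"]["epochs"]),
        n_trials=meta["schedule"]["n_trials"],
        inter_stimulus_s=meta["schedule"]["inter_stimulus_s"],
    )
    truth = [
        GroundTruthCell(**{**c, "center_xy_um": tuple(c["center_xy_um"])})
        for c in meta["truth"]
    ]
    return SynthMovieBundle(movie=movie, schedule=schedule, truth=truth, seed=meta.get("seed"))


def save_mosaic(mosaic: PointMosaic, csv_path: str | Path) -> Path:
    """Points as CSV (x_um, y_um, label) plus a JSON region sidecar."""
    csv_path = Path(csv_path)
    df = pd.DataFrame(mosaic.points_um, columns=["x_um", "y_um"])
    if mosaic.labels is not None:
        df["label"] = mosaic.labels
    df.to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".region.json")
    if isinstance(mosaic.region_um, tuple):
        region = {"type": "rect", "size_um": list(mosaic.region_um)}
    else:
        region = {"type": "polygon", "coords_um": list(map(list, mosaic.region_um.exterior.coords))}
    sidecar.write_text(json.dumps(region))
    return sidecar


def load_mosaic(csv_path: str | Path) -> PointMosaic:
    from shapely.geometry import Polygon

    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    region = json.loads(csv_path.with_suffix(".region.json").read_text())
    region_um = (
        tuple(region["size_um"]) if region["type"] == "rect" else Polygon(region["coords_um"])
    )
    labels = df["label"].to_numpy() if "label" in df.columns else None
    return PointMosaic(df[["x_um", "y_um"]].to_numpy(), region_um, labels=labels)


def save_expression(counts: pd.DataFrame, labels: pd.Series, prefix: str | Path) -> None:
    """Counts as MatrixMarket (genes x cells) plus gene/cell/label CSVs."""
    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), np.asarray(counts, dtype=float))
    pd.Series(counts.index, name="gene").to_csv(prefix.parent / f"{prefix.name}_genes.csv", index=False)
    labels.rename_axis("cell_id").reset_index().to_csv(
        prefix.parent / f"{prefix.name}_labels.csv", index=False
    )


def load_expression(prefix: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    prefix = Path(prefix)
    mat = spio.mmread(str(prefix.with_suffix(".mtx")))
    mat = np.asarray(mat.todense()) if hasattr(mat, "todense") else np.asarray(mat)
    genes = pd.read_csv(prefix.parent / f"{prefix.name}_genes.csv")["gene"]
    lab = pd.read_csv(prefix.parent / f"{prefix.name}_labels.csv")
    counts = pd.DataFrame(mat, index=genes, columns=lab["cell_id"])
    return counts, pd.Series(lab["cluster"].to_numpy(), index=lab["cell_id"], name="cluster")
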