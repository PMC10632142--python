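"""End-to-end orchestration from a single configuration.

``run_pipeline`` runs selected stages (synthetic movie -> ΔF/F -> tuning ->
vector-sum mapping; mosaic statistics; marker classification; contact
morphometry) on synthetic inputs, writing every output plus a manifest with
versions, seeds and a parameter hash. Deterministic stages are bit-identical
across reruns of the same config. All units are explicit in key names
(_um, _s, _hz) to avoid µm/degree ambiguity; the macaque magnification
constant (223 µm/degree) is exposed for speed conversion.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, classify, dsmap, imaging, io, morpho, mosaic, synth, tuning
from .units import MACAQUE_UM_PER_DEG, um_s_to_deg_s

KNOWN_STAGES = ("imaging", "mosaic", "classify", "morpho")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": ["imaging", "mosaic", "classify"],
    "imaging": {
        "field_um": [96.0, 96.0],
        "px_per_um": 1.0,
        "frame_rate_hz": 4.0,
        "n_ds_cells": 3,
        "n_other_cells": 6,
        "ds_kappa": 4.0,
        "r_max": 1.0,
        "baseline_f0": 100.0,
        "noise_sd": 10.0,
        "n_trials": 3,
        "speed_um_s": 500.0,
        "bar_width_um": 500.0,
        "baseline_window_s": 23.0,
        "detect_quantile": 0.995,
    },
    "mosaic": {
        "kind": "exclusion",
        "density_per_mm2": 50.0,
        "region_um": [2000.0, 2000.0],
        "d_min_um": 80.0,
        "n_null_sims": 99,
    },
    "classify": {
        "n_cells": 400,
        "fraction_prgc10": 0.745,
        "separation_sd": 6.0,
    },
    "morpho": {
        "shape": [16, 64, 64],
        "n_segments": 6,
    },
}


def validate_config(config: dict) -> dict:
    """Merge with defaults and reject unknown keys (listing offenders)."""
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    unknown = [k for k in config if k not in merged]
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for k, v in config.items():
        if isinstance(v, dict):
            bad = [kk for kk in v if kk not in merged[k]]
            if bad:
                raise ValueError(f"unknown config keys in {k!r}: {sorted(bad)}")
            merged[k].update(v)
        else:
            merged[k] = v
    bad_stages = [s for s in merged["stages"] if s not in KNOWN_STAGES]
    if bad_stages:
        raise ValueError(f"unknown stages: {bad_stages}")
    return merged


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run the configured stages, writing outputs and a manifest.

    Returns the manifest dict; every written file is listed under
    ``outputs``. Stage seeds are derived deterministically from the top-level
    seed and recorded.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_seed = int(cfg["seed"])
    seeds = {s: (root_seed * 1000 + i) % (2**31) for i, s in enumerate(KNOWN_STAGES)}
    manifest: dict = {
        "retinads_version": __version__,
        "config_hash": _config_hash(cfg),
        "config": cfg,
        "seeds": seeds,
        "um_per_deg": MACAQUE_UM_PER_DEG,
        "outputs": [],
        "summary": {},
    }

    def _write(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, index=False)
        manifest["outputs"].append(name)

    if "imaging" in cfg["stages"]:
        ic = cfg["imaging"]
        field = tuple(ic["field_um"])
        rng = np.random.default_rng(seeds["imaging"])
        cells = synth.place_cells(
            ic["n_ds_cells"] + ic["n_other_cells"], field, seed=seeds["imaging"]
        )
        cells = [
            synth.GroundTruthCell(
                center_xy_um=c.center_xy_um,
                radius_um=c.radius_um,
                baseline_f0=ic["baseline_f0"],
                r_max=ic["r_max"],
                mu_deg=float(rng.uniform(0, 360)) if i < ic["n_ds_cells"] else 0.0,
                kappa=ic["ds_kappa"] if i < ic["n_ds_cells"] else 0.0,
                class_label="pRGC10-like" if i < ic["n_ds_cells"] else "other",
            )
            for i, c in enumerate(cells)
        ]
        schedule = synth.make_bar_schedule(
            n_trials=ic["n_trials"],
            speed_um_s=ic["speed_um_s"],
            bar_width_um=ic["bar_width_um"],
            travel_um=float(np.hypot(*field)),
            seed=seeds["imaging"],
        )
        bundle = synth.generate_movie(
            field, ic["px_per_um"], ic["frame_rate_hz"], cells, schedule,
            noise_sd=ic["noise_sd"], seed=seeds["imaging"],
        )
        io.save_movie_bundle(bundle, out / "movie.tiff")
        manifest["outputs"] += ["movie.tiff", "movie.json"]
        traces = imaging.extract_traces(bundle.movie, bundle.soma_masks())
        traces = imaging.compute_dff(traces, schedule, ic["baseline_window_s"])
        responses = imaging.epoch_responses(traces, schedule)
        _write(responses, "epoch_responses.csv")
        sds = imaging.baseline_sd(traces, schedule, ic["baseline_window_s"])
        profiles = [
            tuning.profile_from_responses(responses, roi, baseline_sd=float(sd))
            for roi, sd in zip(traces.roi_ids, sds)
        ]
        prof_table = tuning.profiles_table(profiles)
        prof_table["true_label"] = [c.class_label for c in cells]
        _write(prof_table, "tuning.csv")
        vsmap = dsmap.pixel_vector_sum_map(bundle.movie, schedule)
        cand = dsmap.detect_candidates(vsmap, threshold=ic["detect_quantile"])
        _write(cand, "ds_candidates.csv")
        manifest["summary"]["imaging"] = {
            "n_candidates": int(len(cand)),
            "mean_nvs_ds": float(prof_table[prof_table.true_label != "other"].nvs.mean()),
            "mean_nvs_other": float(prof_table[prof_table.true_label == "other"].nvs.mean()),
            "speed_deg_s": um_s_to_deg_s(ic["speed_um_s"]),
        }

    if "mosaic" in cfg["stages"]:
        mc = cfg["mosaic"]
        mos = synth.generate_mosaic(
            mc["kind"], mc["density_per_mm2"], tuple(mc["region_um"]),
            d_min_um=mc.get("d_min_um"), seed=seeds["mosaic"],
        )
        io.save_mosaic(mos, out / "mosaic.csv")
        manifest["outputs"] += ["mosaic.csv", "mosaic.region.json"]
        vr = mosaic.voronoi_regularity(mos)
        null = mosaic.random_null_vdri(
            mos.n, mos.region_um, n_sims=mc["n_null_sims"], seed=seeds["mosaic"],
            observed=vr.vdri,
        )
        drp = mosaic.density_recovery_profile(mos)
        _write(drp.to_frame(), "drp.csv")
        manifest["summary"]["mosaic"] = {
            "n_points": mos.n,
            "vdri": vr.vdri,
            "null_vdri_mean": null.mean,
            "null_vdri_p95": null.percentile(95),
            "observed_quantile": null.observed_quantile,
            "drp_convergence_pct": drp.convergence_pct,
        }

    if "classify" in cfg["stages"]:
        cc = cfg["classify"]
        sep = cc["separation_sd"]
        table = synth.generate_marker_table(
            cc["n_cells"],
            {"pRGC10-like": cc["fraction_prgc10"], "pRGC16-like": 1 - cc["fraction_prgc10"]},
            {
                "pRGC10-like": {"bnc2": 100 + 10 * sep, "foxp2": 100},
                "pRGC16-like": {"bnc2": 100, "foxp2": 100 + 10 * sep},
            },
            {
                "pRGC10-like": {"bnc2": 10, "foxp2": 10},
                "pRGC16-like": {"bnc2": 10, "foxp2": 10},
            },
            seed=seeds["classify"],
        )
        res = classify.kmeans_classify(table, ["bnc2", "foxp2"], seed=seeds["classify"] % 2**31)
        _write(res.table, "marker_classification.csv")
        agreement = classify.label_agreement(res.table["assigned_label"], res.table["true_label"])
        manifest["summary"]["classify"] = {
            "n_cells": cc["n_cells"],
            "kmeans_truth_agreement": agreement,
            "degenerate": res.degenerate,
        }

    if "morpho" in cfg["stages"]:
        mo = cfg["morpho"]
        ref, par = synth.generate_wrapped_volumes(
            tuple(mo["shape"]), n_segments=mo["n_segments"], seed=seeds["morpho"]
        )
        res = morpho.contact_fraction(ref, par)
        manifest["summary"]["morpho"] = {
            "overlap_pct": res.total_overlap_pct,
            "rotated_overlap_pct": res.rotated_overlap_pct,
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
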