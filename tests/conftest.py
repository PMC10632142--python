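import numpy as np
import pytest

from retinads import imaging, synth, tuning


@pytest.fixture(scope="session")
def ds_field_bundle():
    """One standard DS field (5 tuned + 15 untuned cells, SNR 5, 3 trials)."""
    return synth.make_ds_field(seed=0)


@pytest.fixture(scope="session")
def noiseless_single_cell():
    """A noiseless movie of one tuned cell (mu=90, kappa=4) with slow wide bars.

    The slow speed makes the bar crossing long relative to the indicator
    decay, so sampled peak amplitudes match the programmed tuning curve
    closely.
    """
    field = (64.0, 64.0)
    cell = synth.GroundTruthCell(
        center_xy_um=(32.0, 32.0), r_max=0.5, kappa=4.0, mu_deg=90.0
    )
    schedule = synth.make_bar_schedule(
        n_trials=1,
        speed_um_s=125.0,
        bar_width_um=500.0,
        pre_stimulus_s=25.0,
        travel_um=float(np.hypot(*field)),
        seed=0,
    )
    return synth.generate_movie(
        field, 1.0, 10.0, [cell], schedule, noise_sd=0.0, seed=0
    )


def extract_direction_means(bundle):
    """Trial-mean peak ΔF/F per ROI per direction from a movie bundle."""
    traces = imaging.extract_traces(bundle.movie, bundle.soma_masks())
    traces = imaging.compute_dff(traces, bundle.schedule)
    responses = imaging.epoch_responses(traces, bundle.schedule)
    return traces, responses


@pytest.fixture(scope="session")
def population_dsi_runner():
    """Callable computing per-cell DSIs of a movie population, with an
    optional fixed preferred axis per cell (the pre-drug convention)."""

    def run(kappa, seed, pref_axes=None, n_cells=10):
        field = (160.0, 160.0)
        rng = np.random.default_rng(3)  # fixed geometry/tuning across conditions
        base = synth.place_cells(
            n_cells, field, radius_um=5.0, min_separation_um=18.0, seed=3
        )
        mus = [float(rng.uniform(0, 360)) for _ in base]
        cells = [
            synth.GroundTruthCell(
                center_xy_um=c.center_xy_um, baseline_f0=100.0, r_max=1.0,
                mu_deg=mu, kappa=kappa,
            )
            for c, mu in zip(base, mus)
        ]
        schedule = synth.make_bar_schedule(
            n_trials=3, pre_stimulus_s=25.0, travel_um=float(np.hypot(*field)), seed=seed
        )
        bundle = synth.generate_movie(
            field, 1.0, 4.0, cells, schedule, noise_sd=20.0, seed=seed
        )
        traces, responses = (
            imaging.compute_dff(
                imaging.extract_traces(bundle.movie, bundle.soma_masks()), schedule
            ),
            None,
        )
        responses = imaging.epoch_responses(traces, schedule)
        dsis, axes = [], []
        for i, roi in enumerate(traces.roi_ids):
            sub = responses[(responses.roi_id == roi) & (responses.kind == "bar")]
            means = sub.groupby("direction_deg")["peak_dff"].mean()
            d, r = means.index.to_numpy(), means.to_numpy()
            pref = pref_axes[i] if pref_axes is not None else None
            dsis.append(tuning.dsi_from_profile(d, r, pref_deg=pref))
            if pref is None:
                pref, _ = tuning.preferred_null(d, r)
            axes.append(pref)
        return np.array(dsis), axes

    return run
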