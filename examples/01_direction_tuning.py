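"""Direction tuning of a single simulated ON-DSGC.

Generates a noiseless calcium movie of one tuned cell (preferred direction
90°, von Mises kappa = 4) under the standard 8-direction drifting-bar
protocol, extracts its ΔF/F responses, and prints the tuning statistics.
The normalized vector sum (NVS) is 0 for untuned and 1 for perfectly
directional cells; the fitted von Mises parameters should recover the
programmed ground truth.
"""

import numpy as np

from retinads import imaging, synth, tuning

field = (64.0, 64.0)
cell = synth.GroundTruthCell(center_xy_um=(32.0, 32.0), r_max=0.5, mu_deg=90.0, kappa=4.0)
schedule = synth.make_bar_schedule(
    n_trials=3, speed_um_s=125.0, pre_stimulus_s=25.0,
    travel_um=float(np.hypot(*field)), seed=1,
)
bundle = synth.generate_movie(field, 1.0, 10.0, [cell], schedule, noise_sd=0.0, seed=1)

traces = imaging.extract_traces(bundle.movie, bundle.soma_masks())
traces = imaging.compute_dff(traces, schedule)
responses = imaging.epoch_responses(traces, schedule)
profile = tuning.profile_from_responses(responses, "roi_0")

print("per-direction trial-mean peak ΔF/F:")
for d, r in zip(profile.directions_deg, profile.mean_peak_dff):
    print(f"  {d:5.0f}°  {r:.3f}")
print(f"NVS                = {profile.vector.nvs:.3f}  (angle {profile.vector.angle_deg:.1f}°)")
print(f"DSI                = {profile.dsi:.3f}  (pref {profile.pref_deg:.0f}°)")
print(
    f"von Mises fit      : r_max={profile.vm_fit.r_max:.3f}, "
    f"mu={profile.vm_fit.mu_deg:.1f}°, kappa={profile.vm_fit.kappa:.2f}"
)
print("ground truth       : r_max=0.500, mu=90.0°, kappa=4.00")
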