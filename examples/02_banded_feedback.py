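"""Calibrated feedback: from block responses to bands and sphere positions.

Runs a few main-experiment blocks at different programmed efforts, applies
the sliding-window estimate (5 baseline scans, 3 response scans right after
tapping), expresses each response as % of the individual maximum, and maps
it to the weak/strong bands that drive the virtual sphere.
"""

import numpy as np

import duoscan as ds
from duoscan.analysis import block_responses, calibrate, extract_roi, incremental_localizer
from duoscan.classification import estimate_block, position_object

site = ds.SiteConfig("A", matrix_size=(20, 20), n_slices=10)
subject = ds.SubjectProfile("subj01", max_amplitude_percent=2.69,
                            activation_center=(10, 10, 5), activation_radius=3.0,
                            noise_sd_percent=0.2)

# part 1: localizer -> calibration profile
loc = ds.localizer_design()
loc_run = ds.simulate_run(loc, subject, site, np.ones(5), seed=2)
roi = extract_roi(incremental_localizer(loc_run, loc))
profile = calibrate(loc_run, roi, loc)

# part 2: six main blocks at programmed efforts
config = ds.default_config(matrix_size=(20, 20), n_slices=10)
main = ds.main_design(config, seed=5)
efforts = np.zeros(main.n_blocks)
efforts[:6] = [0.80, 0.45, 0.10, 0.62, 0.31, 0.95]
run = ds.simulate_run(main, subject, site, efforts, seed=3)
trace = run.data[roi.mask, :].mean(axis=0)
raws = block_responses(trace, main)

print(f"calibration maximum: {profile.max_bold_percent:.3f}%  (= 100%)")
print("block  effort  raw%    relative%  band          sphere")
for b in range(6):
    est = estimate_block(b + 1, raws[b], profile)
    pos = position_object(est.band, est.relative_percent)
    print(f"{b + 1:>4}   {efforts[b]:.2f}   {est.raw_response_percent:5.2f}"
          f"   {est.relative_percent:7.1f}    {est.band.value:<12}"
          f"  y={pos.vertical_position:.2f} ({pos.region})")
print("-> <30% of maximum is insufficient, 30-60% is weak ('L'),")
print("   >60% is strong ('U'); the sphere sits at relative/100.")
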