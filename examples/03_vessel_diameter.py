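"""Estimate a vessel constriction from line-profile FWHM around locomotion onsets.

Simulates a single-band movie of a vessel whose width shrinks by 12% for 2 s
after each onset, then recovers the change with the diameter pipeline:
post-onset mean image → perpendicular profile → FWHM → percent change.
"""

import hemoloco as hl

movie, onsets = hl.synthetic.simulate_vessel_movie(
    baseline_fwhm_px=10.0, constriction_pct=12.0, noise_sd=0.0
)
rate = 32.0
mid, width = movie.shape[1] // 2, movie.shape[2]

baseline_img = movie[: onsets[0] - int(2 * rate)].mean(axis=0)
post_img = hl.post_onset_mean_image(movie, onsets, rate, window_s=2.0)

w_base = hl.fwhm_width(hl.extract_profile(baseline_img, (mid, 0), (mid, width - 1)))
w_post = hl.fwhm_width(hl.extract_profile(post_img, (mid, 0), (mid, width - 1)))
change = hl.percent_change(w_post, w_base)

print(f"baseline width: {w_base:.2f} px")
print(f"post-onset width: {w_post:.2f} px")
print(f"width change: {change:+.1f} % (simulated: -12.0 %)")
# A negative percent change means the vessel constricted after locomotion onset.
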