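"""Forward-model a short multi-wavelength recording and unmix it back to hemoglobin.

Builds a 40-s, 24×24-pixel synthetic session, renders the four-band
reflectance stack through the modified Beer-Lambert forward optics, converts
it back to ΔHbO/ΔHbR/ΔHbT maps, and compares the recovered draining-vein
trace with the injected ground truth.
"""

import numpy as np

import hemoloco as hl

cfg = hl.SimConfig(seed=1, duration_s=40.0, n_events=1, image_size=(24, 24),
                   noise_sd=0.0, amplitude_jitter_sd=0.0)
spectra = hl.ChromophoreSpectra.default()

loco, onsets = hl.simulate_locomotion(cfg)
gt = hl.simulate_compartment_traces(cfg, loco, onsets)
raster = hl.compartment_raster(cfg.image_size)
stack = hl.render_stack(gt, spectra, cfg, raster=raster)
stack.baseline_frames = slice(0, 64)  # quiet pre-event frames define I0

hemo = hl.unmix_stack(hl.attenuation(stack), spectra, frame_rate=cfg.frame_rate_hz)
trace = hl.percent_change_trace(hemo, raster == "draining_vein", hl.BaselineSpec())
truth = gt.traces["draining_vein"]

print(f"event onset at t = {onsets[0] / cfg.frame_rate_hz:.1f} s")
print(f"recovered draining-vein minimum: {trace.min():+.3f} % HbT")
print(f"injected   draining-vein minimum: {truth.min():+.3f} % HbT")
print(f"max |recovered - truth| = {np.abs(trace - truth).max():.2e} % HbT")
# The recovered ROI trace matches the injected kernel to numerical precision:
# the spectral inversion is the exact inverse of the forward optics at zero noise.
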