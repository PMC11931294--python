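# Methods

## The measurement model

Widefield optical imaging spectroscopy records remitted light at four
illumination bands (494±20, 560±5, 575±14, 595±5 nm) at 32 Hz over a
184×184-pixel thinned-skull window (~75 μm/px). Under the modified
Beer–Lambert law, the attenuation change of band λ at a pixel relative to a
baseline intensity I₀ is

    ΔA(λ) = −log₁₀(I(λ)/I₀(λ)) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR] · X(λ)

with ε the band-averaged molar extinction coefficients (cm⁻¹·M⁻¹),
concentration changes in mol/L (reported in μM), and X(λ) the differential
path length (cm). With four bands and two chromophores the system is
over-determined; `spectral.unmix_stack` solves it per pixel-frame by ordinary
least squares through a single precomputed pseudoinverse. ΔHbT = ΔHbO + ΔHbR
holds exactly by construction.

Numerical conventions: base-10 logarithm; ε in cm⁻¹·M⁻¹ and X in cm (stated
to avoid silent unit drift); I₀ is the per-pixel mean over a configurable
baseline frame range, defaulting to the full recording. The bundled ε table
is band-averaged from a standard hemoglobin compilation and the default X(λ)
values are plausible green-light path lengths for cortical reflectance; both
are package defaults and overridable. The pipeline's correctness contract is
forward/inverse self-consistency (the round trip recovers injected
concentrations to < 1e−6 μM at zero noise), not agreement with any particular
Monte-Carlo path-length table. Saturation-dependent path-length rescaling is
approximated: per-compartment baseline saturation (100 μM total Hb; SO₂ 0.90
artery, 0.80 whisker region/parenchyma, 0.70 veins) enters only
absolute-concentration reporting, while the differential inversion uses fixed
X(λ). Percent-change HbT reporting is insensitive to this refinement.

## Event analysis

The locomotion trace is zero when the animal is stationary and positive (in
arbitrary units) while it runs. An onset is the first supra-zero sample of a
movement run lasting ≥ 0.5 s, preceded by ≥ 1 s of quiescence — an automated
stand-in for manual marking; on the synthetic generator it recovers the
ground-truth onsets exactly. Epochs span [−5, +20) s around onset (half-open,
onset exactly on a sample: 800 samples at 32 Hz, onset at column 160).
Overlapping epochs are permitted (minimum separation 0 by default).

Each epoch is normalized to its own baseline, ΔTrace = (Trace − Trace₀)/|Trace₀|,
where Trace₀ is the arithmetic mean of the 5-s pre-onset window (the
aggregator is a package choice), ×100 for hemodynamic traces so values read
in % HbT. When |Trace₀| falls below an epsilon (the common case for
locomotion epochs, whose baseline is all zeros) the division is undefined, so
the row falls back to plain subtraction and is flagged. Event size is the
trapezoidal area under the raw locomotion trace over the 5 s after onset —
computed on the raw trace deliberately: a preceding bout inside the baseline
window would otherwise leak into the divisor.

Metrics are computed on the closed 0–5 s post-onset window: trapezoidal AUC;
maximum peak and minimum as the mean over ±0.25 s (17 samples) around the raw
extremum, clipping the averaging window at the 0 and 5 s boundaries rather
than extending past them; times-to-peak as the raw argmax/argmin times; and a
normalized speed |peak|/time-to-peak with the time floored at one sample
period to avoid division by zero. The minimum is the global minimum of the
window regardless of whether it precedes or follows the maximum. Locomotion-
size stratification sorts events ascending by a chosen field (stable sort, so
boundary ties resolve by original event order) and takes the first and last
⌊q·N⌋ events (234 of 2343 at q = 0.10).

## Vessel diameter

A vessel appears darker than tissue at green illumination. From the mean
image over [0, 2) s after each onset, an intensity profile is sampled along a
perpendicular line; the background is the median of the outer 25% of profile
samples (a package choice), the dip height is background − intensity, and the
width is the distance between the two half-maximum crossings flanking the dip
minimum, each located by linear interpolation (no smoothing by default; an
optional Gaussian pre-smooth is available). A dark-pixel count below a
threshold tracks the same quantity more crudely. Changes are percent of
baseline width; negative means constriction. At widefield resolution this is
an index of caliber change, not a micrometer-accurate diameter.

## Regions of interest

The activated whisker region is the set of pixels exceeding mean + k·SD
(k = 1.5 default) of the stimulus-evoked spatial map — read as mean + k·SD
because a bare "k·SD" cut is ill-defined for maps with nonzero mean — reduced
to its largest connected component (the region is implicitly contiguous).
The rule is invariant under affine transforms of the map. Vessel masks come
from an SVD of the mean-centered pixel×time matrix: the chosen component's
loading map is thresholded at a quantile of |loading| (ties kept, so exact
low-rank movies recover their support); the component's sign is flipped so
its peak temporal score is positive. Component choice is manual by index, or
automated as the component whose temporal score best correlates with a
concurrent locomotion trace. The chromophore the map is built from is a
caller choice.

## Group statistics

Summaries report mean, sample SD (n−1) and n per group. Correlations are
Pearson with two-sided p per vessel group. Slope comparison between two
vessel groups fits y ~ x·group: the interaction term tests slope equality and
the group term of the common-slope model tests the intercept difference.
Multi-group comparisons use a linear mixed model with a random intercept per
animal (random slopes are not modeled); per-factor Wald chi-square tests are
reported, and pairwise contrasts of estimated marginal means (predictions
averaged over the reference grid of observed factor levels) are adjusted with
the studentized-range (Tukey) distribution using a residual-df approximation,
with the df method recorded in the result metadata. When the random-effect
variance is forced to zero the model reduces to ordinary fixed-effects ANOVA
and per-term F tests match it exactly; the same path serves as a flagged
fallback on non-convergence. Two-group tests are Wilcoxon signed-rank
(paired) and Mann–Whitney U (unpaired), two-sided; all-tied degenerate inputs
are flagged. Normality screening (Shapiro–Wilk, Kolmogorov–Smirnov, variance
F test) is reported, never branched on automatically.

## The synthetic-data generator

The generator defines the study conditions every test runs under. One
session is 750 s at 32 Hz. Locomotion bouts have a trapezoidal speed profile
(25% rise, 50% plateau, 25% fall) with uniform-random amplitude (1–10 a.u.)
and duration (1–8 s), ≥ 2 s of quiescence between bouts, and onsets placed so
every event admits a full −5/+20 s epoch; the resulting event sizes average
≈ 16 a.u.·s of 0–5 s AUC, and ~20 events fit a session, matching the scale of
the real dataset (2343 events / 118 sessions). Speeds are continuous positive
units rather than integer counts: quantization adds nothing and can zero-out
small bouts that the detector must see.

Compartment responses are differences of gamma-variate lobes normalized to
unit peak, superposed per event:

    h(t) = dip_amplitude · lobe(t; t_dip, k_dip) + gain · AUC · lobe(t; t_peak, k_peak)

The artery family carries only the positive lobe, scaled by each event's
locomotion AUC (artery gain 0.45 %/(a.u.·s), peak 3.1 s; whisker vein 0.22 at
3.3 s; parenchyma 0.30 at 3.2 s). The draining vein has a fixed −2.9% dip at
1.2 s plus a late locomotion-scaled positive lobe (gain 0.080, peak 4.8 s)
whose size was solved in closed form so the 0–5 s kernel AUC is ≈ 0 at the
mean locomotion AUC. The meningeal vein has a fixed −4.0% dip at 1.7 s and no
positive lobe (no overshoot). A fractional per-event amplitude jitter
(sd 0.3, independent of locomotion size) emulates trial-to-trial biological
scatter; at the default conditions the group means land near the reported
compartment responses (artery max ≈ +7.3% at ≈3.1 s, whisker vein ≈ +3.6%,
draining-vein minimum ≈ −2.7% at ≈1.2 s with near-zero AUC, meningeal
minimum ≈ −3.8% with AUC ≈ −7 %·s).

A % ΔHbT excursion is apportioned to ΔHbO/ΔHbR before rendering: dilations
are all ΔHbO (fresh arterial blood), dips proportional to the compartment's
resting saturation; a fully proportional rule is available. The vessel raster
is straight vertical vessels on a uniform background (no tortuosity), and
camera noise is additive Gaussian on reflectance (no shot-noise refinement).
Everything is a pure function of (config, seed).

What the generator does **not** emulate — brain motion, respiration/whisking
covariates, startle, photon transport, genotype effects (disease labels are
assigned round-robin and carry no effect) — bounds what passing tests show:
they demonstrate that the pipeline recovers known compartment structure from
data obeying the stated forward model, not that it is robust to every
artifact of real recordings.

## Problem sizes

Trace-level study simulation runs at full session length (750 s, 32 Hz);
the default study is 6 animals × 2 sessions × 20 events = 240 events, enough
to pin the compartment signatures (correlations, timings, AUC signs) without
long runtimes. Imaging round-trip checks render spatially reduced stacks
(~24×24 px, tens of seconds), since the spectral inversion is per-pixel and
gains nothing from more pixels. The acceptance script and the full test suite
each complete in well under a minute on one CPU.

## Known limitations

- The mixed-model pairwise df uses a residual-df approximation rather than a
  Satterthwaite correction; for the balanced, event-rich tables produced here
  the difference is negligible, and the df method is recorded in the output.
- The draining-vein kernel's late positive lobe makes its maximum occur near
  the 5-s window edge, slightly later than in real traces; the acceptance
  signatures (dip timing, AUC signs, correlation structure) do not depend on
  it.
- FWHM profiling assumes a single dominant dip; crossing vessels or strong
  vignetting violate the background estimate.
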