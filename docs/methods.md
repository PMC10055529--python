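# Methods

This note documents the models, parameters and estimators in `flodm`: what
the synthetic generator emulates, how the reconstruction and quantification
layers are defined, which numerical choices were open and how they were
settled, and what the package's passing tests do and do not demonstrate
about real data.

## Response templates

A `ResponseTemplate` is the noiseless percent-change time course of one
signal (astrocytic Ca²⁺ ΔF/F, neuronal Ca²⁺ ΔF/F, ΔCBFv/CBFv, or vessel
diameter Δφ) under one condition, parameterized directly by the group
kinetics an experiment reports: signed peak amplitude `A`, onset `t_onset`,
peak time `t_p`, return-to-baseline time `t_r`, and an optional undershoot
(depth ≥ 0, end time).  The curve is

* 0 for `t ≤ t_onset`;
* raised-cosine rise `A·(1 − cos πu)/2` on `[t_onset, t_p]` — smooth
  takeoff and smooth peak;
* quarter-cosine decay `A·cos(π/2·u)` on `[t_p, t_r]`;
* sine undershoot lobe `−sign(A)·depth·sin(πw)` on `[t_r, end]`;
* 0 afterwards.

The decay lobe is deliberately a *quarter* cosine rather than a full
raised cosine: a raised-cosine decay approaches zero tangentially (zero
slope at `t_r`), which makes the return time unidentifiable under noise —
any threshold- or band-based estimator fires minutes early, and no
estimator can do better because the curve carries no information about
where it "ends".  The quarter cosine crosses zero transversally, so `t_r`
is a genuine feature of the curve; the slope discontinuity at `t_r` is
harmless (the template is piecewise smooth by construction).

When a per-minute **rate** is the primary printed estimand
(`rate_override`), the rising phase is instead a linear ramp from
`t_onset = 0`, so that the ordinary-least-squares slope of the noiseless
template over `[0, min(t_p, 30)]` equals the prescribed rate exactly, and
the amplitude is the implied `rate × t_p`.

## Condition presets

Presets bind templates to cohort structure: number of animals `n`, ROIs per
signal `m = 5`, between-animal gain spread, trace noise, time axis
(−10…70 min at 0.5 min, injection at t = 0).  The built-in presets encode
the published kinetics listed in the README.  Two choices deserve note:

* **DREADD+cocaine preset scales.**  The printed post-activation rates
  (0.35, −2.03, 0.11 %/min over 0–30 min) are not arithmetically
  reconcilable with peak amplitudes of a few percent under any reading of
  "averaged per-minute increase", so the rate-true templates carry their
  own amplitude scales (amplitude = rate × t_p, with t_p = 6, 6 and
  3.5 min).  The neuronal template's `t_r = 4.235 min` is chosen so its
  analytic FWHM is exactly the printed 2.24 min given the linear rise.
  Consequently the *rates and FWHM* are the estimands of record for this
  preset, not the amplitudes.
* **Capillary heterogeneity.**  Per-vessel gains within a compartment are a
  fixed pattern with mean 1; the capillary set {−0.55, 0.55, 1.4, 2.6}
  spreads individual capillary responses from >+7% (flow increase) to
  <−35% while keeping the compartment-mean trough at the template value —
  reproducing the qualitative observation that single capillaries respond
  heterogeneously and only the multi-capillary mean is informative.

**Between-animal variability** is a multiplicative gain
`g ~ Normal(1, animal_sd/100)` per (animal, signal), default
`animal_sd = 15` (percent of the template amplitude).  A relative spread is
used because the published per-signal s.e.m. values imply absolute spreads
ranging from ~0.4 to ~5 percentage points — no single absolute number can
represent them, and a gain on the template is the natural reading of
"template × animal gain".  Simulated cohort s.e.m. therefore brackets the
smaller printed s.e.m.s (Ca²⁺ signals) but understates the largest (CBFv);
recovery criteria use the simulation's own spread, never the printed one.

**Trace noise** is i.i.d. Gaussian with SD 0.3 percentage points per
sample, a conventional magnitude for widefield ΔF/F; movie rendering adds
Poisson photon noise instead.  No source states these levels; they are
declared, not inferred.

## Fluorescence arm

Movies are interleaved green/red frame pairs at the camera rate (default
80 fps ⇒ consecutive same-channel frames 25 ms apart), one pair per
minute-grid time point.  Pixel intensity is `baseline map × (1 + ΔF/F/100)
× exp(−bleach·t)`, mixed by a row-stochastic 2×2 crosstalk matrix (default
10% off-diagonal) and Poisson-sampled.  The analysis side demultiplexes by
the manifest schedule, computes ΔF/F against the per-ROI baseline-window
mean (default −10…0 min; ≥3 baseline frames required; non-positive
baselines masked with a warning), optionally divides out a mono-exponential
bleach fitted on the baseline, and extracts per-ROI spatial means.  ΔF/F is
computed on ROI-mean raw intensities rather than per pixel — more
noise-robust, and on phantoms the difference is far below the trace noise.
Crosstalk unmixing (inversion of the declared matrix) exists but is off by
default; with it off, a red-only event of amplitude a induces a green
artifact of at most 0.1·a in co-expressing regions — measured and reported,
never silently removed.

## Doppler arm

Forward model: every voxel inside a vessel carries
`φ = wrap(4π n v_z T / λ0)` with `v_z = v_axial·cos(80°)·(1 + ΔCBFv/100)`
(plug flow, no diffraction/PSF or speckle modelling), plus Gaussian phase
noise.  The default Doppler angle of 80° is typical for cortical imaging
and keeps all phantom velocities sub-Nyquist; the default phase noise
σ_φ = 0.0026 rad is *derived* from the instrument-class sensitivity claim
of 20 µm/s at T = 10 µs via `v_sens = λ0·σ_φ/(4π n T)`.

Reconstruction inverts the same relation voxelwise.  No phase unwrapping is
performed: super-Nyquist flow reconstructs wrapped (e.g. 1.5×v_Nyq appears
as −0.5×v_Nyq) and the validity mask — `|φ| > k·σ_φ`, k = 3 — never hides
it; aliasing is a documented failure mode.  Kasai-style complex averaging
over N repeat A-scans is available (default N = 1).  The ratio series is
`100·(v − v̄_base)/v̄_base` with the *signed* baseline in the denominator,
so it is the relative change of flow **speed** for arteries (v > 0) and
veins (v < 0) alike; voxels whose baseline sits below `k·v_sens` are
excluded (NaN) from all downstream means rather than zero-filled, because
zero-filling biases ΔCBFv toward −100%.

## Vessel quantification

The baseline-mean velocity volume is thresholded at the validity floor,
cleaned of components under 5 voxels, thinned with a 3D skeleton, and split
into branch-free segments by removing skeleton voxels with more than two
skeleton neighbours.  Diameter is `2 × mean EDT along the centerline ×
voxel size` (bias ≤ 1 voxel on analytic cylinders over radii 2–10 voxels;
phantom vessels are tilted off-grid so centerline averaging dithers the
quantization).  Compartments: capillary if diameter < 10 µm, else artery
for positive axial velocity, vein for negative — the velocity-sign rule is
a phantom convention standing in for the anatomical identification a human
would make.  Per-segment flow traces average ratio voxels within 50% of the
radius of the centerline (partial-volume edges excluded); compartment
traces are exact means of member segments.  Automated segment selection
replaces the manual vessel-ROI selection of a real experiment.

## Kinetics estimators

All estimators operate per trace; cohort metrics are computed on each
animal's ROI-mean curve and rolled up as mean ± s.e.m. with n = animals
(never ROIs).  Smoothing is a 3-sample running median only — no low-pass,
to avoid biasing peak times.

* **Peak** — extremum of the median-smoothed trace in the search window;
  the amplitude is read from the raw trace within ±1 sample of that
  location (the median filter clips narrow peaks; reading raw restores
  noiseless exactness while the smoothed argmax keeps noise robustness).
  All-flat traces report amplitude 0 with undefined peak time.
* **Return time** — first time after the peak at which the smoothed trace
  re-enters the baseline band ±k·SD (k = 2) and stays for ≥2 samples; the
  reported value is then refined to the zero crossing of a least-squares
  line over the preceding 5 min of decay, which is unbiased for a
  transversal crossing.  Never-returning traces are right-censored at the
  window end, explicitly, never imputed.
* **Rate** — OLS slope over `[0, min(t_p, 30 min)]`, operationalizing
  "averaged per-minute increase" (exactly recoverable, noise-robust, and
  the definition `rate_override` is built against).  The window end is the
  *first attainment* of the peak level within the baseline noise band: for
  plateau-shaped responses the plain argmax smears uniformly over the
  plateau under noise and drags the fit into the decay.  On pooled
  low-noise curves the attainment trigger itself correlates with residual
  noise, so `rise_end="peak"` ends the window at the located peak instead;
  the acceptance script uses it for the sharp DREADD neuronal transient.
* **FWHM** — half-maximum crossings found scanning outward from the peak
  (immune to distant noise excursions), linearly interpolated; uncrossed
  half-levels are right-censored.
* **Undershoot** — opposite-polarity extremum after the return time.

Known limitation: for responses whose amplitude is within ~3× the trace
noise (the DREADD neuronal template: 0.385% vs ~0.13% on ROI-mean curves),
per-animal FWHM estimates are unreliable; rates and peaks remain usable,
and pooled-curve estimation is preferred.

## Statistics

Correlations are zero-lag Pearson coefficients on per-animal mean traces
over [0, 60] min (no lag search — a single r per pair is the reported
quantity; window and smoothing are config values surfaced in the report).
Under the default `flow_negated` convention the flow/diameter trace is
negated first, so Ca-increase/flow-decrease coupling is positive; both
conventions are always computed and stored.  The simulated correlation
*magnitudes* follow from the template shapes and are not calibrated to any
published value — only the ordering (astrocytic coupling exceeds neuronal)
is a designed property, because the neuronal template is over long before
the flow recovers.  Paired and one-sample two-sided t-tests report the
effect (mean difference ± s.e.m.) alongside p, with an explicit degenerate
flag for zero-variance inputs.  Holm–Šidák step-down is implemented
directly — ascending p-values tested at `1 − (1−α)^(1/(k−i+1))`, stopping
at the first failure — and cross-checked in the tests against an
independent implementation; it rejects a superset of Bonferroni at equal α.
One-way and repeated-measures ANOVA are thin wrappers over scipy/statsmodels,
clearly labelled as standard calls.

## Reports, provenance, determinism

Every report embeds the seed, a SHA-256 hash of the canonical preset JSON,
the software version, the full run config (minus the output directory,
which is location not configuration), all metric/correlation tables as
records, and a content hash over the canonical serialization; a report
without provenance is refused.  All randomness flows from a single seed
through `numpy.random.default_rng`; identical config + seed reproduces
every CSV/TIFF/JSON byte for byte.

## Problem sizes

Defaults were chosen as the smallest sizes that exercise every code path
with stable statistics: cohorts of n = 7 (cocaine), 5 (clozapine), 4
(DREADD) animals × 5 ROIs on a 161-point grid; the flow phantom is a
48×96×96 grid at 3 µm voxels with 4 vessels per compartment (arteries
r = 21 µm, veins 24 µm, capillaries 4.5 µm) and one volume per 0.75 min;
pipeline demo runs use a coarser 32×64×64 grid at 4.5 µm.  Cohort-level
recovery averages 20 seeded cohorts (40 for the pooled DREADD rates).

## What passing tests do and do not show

The generator produces exactly the structure the estimators assume:
time-locked, motion-free, registration-free responses with Gaussian trace
noise, multiplicative animal gains and stationary baselines.  Recovery of
the encoded kinetics therefore validates the *estimators and the pipeline
plumbing*, not the biology: real data add motion, pulsatility, baseline
drift beyond mono-exponential bleaching, neuropil contamination, vessel
tortuosity and anatomical compartment identification, none of which are
modelled.  In-scope fidelity is checked the opposite way too — forward
Doppler rendering followed by reconstruction recovers phantom velocities to
1e-9 mm/s noiselessly, and every estimator reproduces the analytic template
estimands exactly (time quantities within one 0.5-min sample).
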