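# Methods

This note records the models, numerical choices and known limits of the
`arraypulse` pipeline, in the order the data flow through it.

## Signal model and preprocessing

A recording is a time × 12 matrix sampled at 100 Hz for ~30 s, one column
per element of a 3 × 4 pressure grid (rows: radial / intermediate / ulnar
passages; columns: axial positions).  Units are arbitrary sensor pressure.

Denoising uses a Chebyshev type-I band-pass, 1–4 Hz, passband ripple
0.5 dB.  "6th order" is read as the order of the final band-pass transfer
function, i.e. a 3rd-order low-pass prototype (`scipy.signal.cheby1(3, …)`),
the common convention of the design routine; both the order and the ripple
are configurable.  The filter is applied forward–backward
(`sosfiltfilt`) with reflect padding of one impulse-settling length
(estimated as the time for the impulse-response envelope to fall below
10⁻⁴ of its peak), so the output is zero-phase and edge transients are
suppressed.  Consequences worth knowing:

- the effective magnitude response is |H|², so the passband droop doubles
  in dB and the stop bands deepen;
- DC is removed, so **all downstream amplitudes are relative**, never
  absolute contact pressures;
- at 72 bpm only the first ~3 harmonics survive, which *reshapes* beat
  morphology: post-filter fiducial ratios are systematically higher than
  raw-morphology ratios.  All cohort comparisons therefore happen strictly
  within the same processing chain.

## Beat segmentation, APW, MRPW

Beat feet are local minima immediately preceding steep upstrokes: the first
difference is thresholded at half its 98th percentile, candidate events are
separated by at least one beat period at the maximum heart rate (180 bpm
default), and each event is walked back to the preceding minimum or plateau
edge.  Only inter-onset gaps consistent with the configured heart-rate
bounds (40–180 bpm) become beat slices.  Constant or upstroke-free signals
yield an empty segmentation with a status string rather than an error.

The average pulse wave (APW) resamples every beat linearly to the *median*
beat length and averages pointwise — the median (not a fixed length)
preserves the subject's own period.  The most representative pulse wave
(MRPW) is the beat with the highest Pearson correlation against the APW
(computed on beats resampled to the APW length; the returned beat is the
original, un-resampled one; ties go to the earliest beat; zero-variance
beats are excluded with a warning).

## Fiducial detection

Given one beat with its onset at index 0:

- **h₁** — the percussion peak: the earliest local maximum within 15% of
  the global maximum.  For a clean beat this *is* the global maximum; the
  tolerance matters after heavy filtering, which can merge the tidal and
  dicrotic waves into a hump marginally higher than the percussion wave,
  and a near-equal peak that comes earlier is always the percussion wave.
- **h₄** — the dicrotic notch: the lowest local minimum within 0.6·t after
  the peak (a physiological systole bound; configurable), constrained to
  lie above the onset level.  When filtering flattens the notch into a
  plateau with no local minimum, the notch falls back to the strongest
  convex bend (maximum of the second difference) of the descending limb,
  accepted only if a concave bend follows — this separates a true
  diastolic plateau from plain monotone decay, which yields "no notch".
- **h₃** — the tidal wave: the largest local maximum between peak and
  notch; when the tidal wave is merged into the descending limb, the
  strongest concave-to-convex inflection is used instead, and the
  `h3_method` field records which rule fired.  A beat with no notch has no
  tidal wave (and no dicrotic wave) by convention.
- **h₅** — the dicrotic wave: the largest local maximum after the notch,
  reported **relative to the notch level**, so values near zero or
  negative are meaningful (reported group means of this feature hover
  around zero).  Absent → h₅ = 0 by convention.
- **w** — width of the main-wave lobe at (2/3)·h₁ above onset ("one third
  below the peak"), with sub-sample linear interpolation at the crossings.
  The complementary reading (1/3·h₁) is available via the level argument.

Noise handling: a robust noise estimate (1.4826 × median |residual| of a
quadratic Savitzky–Golay fit, window ≈ 0.07 s) decides whether the beat is
noisy (σ > 0.003 × range).  Noisy beats are smoothed for extremum
localization, candidate extrema must clear a prominence gate of 3× the
post-smoothing residual noise, notch candidates must be followed by a rise
the noise cannot produce (max(3σ, 0.05·h₁) — the dicrotic wave), and
extremum times are refined to sub-sample precision by a quadratic vertex
fit over ±3 samples.  None of this machinery is active on clean beats, so
noiseless results are bit-identical to the plain rules above.

All amplitudes are measured relative to the onset amplitude except h₅
(relative to the notch).

## Array pulse volume

At each sample time the 12 amplitudes form a 3 × 4 frame.  Bilinear
interpolation onto a uniform N × N grid spanning the footprint (nodes at
the corners, rows across the width, columns along the length) is computed
as the tensor product R F Cᵀ of two 1-D linear interpolation operators —
exact bilinear interpolation, with the bilinear bounds (surface between
node min and max, nodes reproduced exactly) holding by construction.

The volume statistic is V = S·ΣΣ M with **S the per-cell area
A_total/N²**, i.e. a Riemann sum.  Taking S as the total footprint area —
the literal reading of the defining formula — makes V grow with N²; that
reading is available behind the `literal_total_area_s` flag for
comparison, but the per-cell interpretation is the default because it is
the only one for which V is N-invariant (verified to <1% between N = 200
and N = 1000; exact for constant frames).

Per-passage volumes restrict the surface to the transverse third of rows
nearest that passage's sensor row (with N not divisible by 3, RP takes
rows [0, ⌊N/3⌋), IP the next third, UP the remainder) and are normalized
as (regional mean height) × A_total, so RP/IP/UP/mean share one scale and
the mean-region series is the average of the three passage series up to
band rounding.  Because interpolation and band averaging are both linear
in the 12 channel values, each regional volume is an exact fixed linear
functional of the channel vector; the implementation precomputes these
12-weight functionals by pushing basis frames through the full surface
computation once (a test asserts exact agreement with explicit surface
integration).

APV features of a beat: fiducials are detected independently on each
group's mean waveform (passage morphology differs, and reported
per-passage values are not the arithmetic average of one another), then
APV_h1 = V(t_h1) − V(t_onset), APV_h3 = V(t_h3) − V(t_onset), APV_h4 =
V(t_h4) − V(t_onset), APV_h5 = V(t_h5) − V(t_h4), with ratios as
quotients by APV_h1.  All volumes are relative to the beat-onset volume
(the band-pass destroyed absolute offsets).  A missing tidal wave yields a
missing APV_h3 (NaN); a missing dicrotic wave yields APV_h5 = 0.  The
reference channel — whose MRPW window delimits the analysis beat — is the
channel with the largest median per-beat peak-to-peak amplitude (ties to
the lowest index).  Manual fiducial overrides (group → time) are accepted
to reproduce manual identification workflows.

N defaults to 1000; tests and the acceptance script run N = 200, justified
by the measured grid convergence (<1% between 200 and 1000).

## Statistics

Per parameter: Shapiro–Wilk at α = 0.05 on both samples gates a
pooled-variance two-sample t-test (df = nₓ + n_y − 2); otherwise the
Mann–Whitney U-test — exact when nₓ + n_y ≤ 12 without ties, else the
normal approximation with tie and continuity corrections, with U exactly
at its null mean reported as p = 1.  Zero-variance pairs: equal means give
t = 0, p = 1; unequal means are a degeneracy error.  p values are
two-sided; significance tiers at 0.05 / 0.01 / 0.001.  No
multiple-testing correction is applied by default (parameters are reported
individually, matching standard practice for this kind of table);
Benjamini–Hochberg is available behind a flag.

## Synthetic data

A beat is a sum of three Gaussian bumps (percussion, tidal, dicrotic) on a
period-normalized axis, detrended by the line through its endpoint values
(onset = end = 0, so beats concatenate continuously) and scaled to unit
percussion peak.  A Gaussian-bump model was chosen over physiological
transmission-line models because its ground-truth fiducials are analytic
and the pipeline needs morphology, not physiology.

Preset calibration: the two presets share bump geometry (centers/widths);
the tidal and dicrotic amplitudes were solved numerically — detector in
the loop on a dense 2 kHz rendering — so the clean-beat fiducial ratios
equal the reported cohort means exactly: healthy h₃/h₁ = 0.823,
h₄/h₁ = 0.727; hypertensive 0.874, 0.789.  The resulting morphology is a
"shoulder" tidal wave high on the descending limb with a shallow notch —
the waveform shape these ratio values imply.  Two consequences are
documented rather than hidden: (i) at 100 Hz sampling the shallow tidal
ripple is not always resolved and the detector reads the merged wave via
its inflection; (ii) the notch plateau makes single-beat ±20 ms notch
localization unattainable under heavy noise, which is why detector
accuracy is tested on a sharp-component model and the pipeline reaches
preset beats only after ensemble averaging.

A recording is gains ⊗ beat-train + drift + powerline + noise:

- per-beat periods from a jittered heart rate (default mean 72 bpm,
  beat-to-beat SD 2 bpm — seated-rest variability), evaluated analytically
  at every sample time so there are no resampling artifacts;
- spatial gains from a 2-D Gaussian over the grid (artery running axially
  under the RP row, slightly off-center) — all positive, peak 1.0;
- baseline drift: 0.3 amplitude sinusoid at 0.25 Hz, random phase per
  channel (body/wrist movement);
- powerline: 5% amplitude at 50 Hz (at Nyquist of the 100 Hz clock, and
  inside neither the signal band nor the filter passband);
- white noise SD 0.04 per channel, ≈ SNR 20 dB against the beat train.

Cohorts (default 26 per group, the study-size convention): per-subject
heart rate ~ Normal(preset mean, 5 bpm) truncated to [40, 180], log-normal
multiplicative jitter (σ = 0.10) on the tidal and dicrotic amplitudes and
on the overall contact gain.  Per-subject seeds derive deterministically
from the master seed via `numpy.random.SeedSequence.spawn`.

**What the generator does not emulate:** contact-pressure dependence (the
light/medium/heavy hold-down protocol), arrhythmias, respiratory
modulation, sensor cross-talk, motion artifacts beyond sinusoidal drift,
and any true hemodynamics.  Passing tests therefore demonstrate that the
pipeline recovers what this generator encodes — morphology ratios, spatial
gain structure, group shifts — not that it is validated on clinical
recordings.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` use N = 200 interpolation
grids, 30 s recordings, 26-subject groups, 50-replicate power checks and
500-replicate type-I checks; these sizes give stable statistics while
keeping a full run in the order of a minute.

## Known limitations

- Absolute APV units are arbitrary: the sensor pitch and contact area are
  unpublished, so the footprint defaults to the unit square and all
  volumes scale linearly with it.
- The 1–4 Hz band-pass is faithful to the published processing but is
  aggressive at resting heart rates; measured ratios are
  filter-conditioned quantities, comparable only within the same chain.
- The exact per-passage volume rule used for the original tables is not
  recoverable from their description (their mean row is not the average of
  the passage rows); the restricted-surface rule implemented here is one
  defensible choice and is stated explicitly.
- Printed clinical table values are not reproduction targets: the raw
  subject data are unavailable, and the printed test statistics cannot be
  recomputed from the printed summaries.
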