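# Methods

This note documents the models, estimators, defaults and numerical choices
behind `rgcestim`, and what the synthetic validation studies do and do not
establish about real recordings.

## Recording and stimulus model

A recording session is one retinal patch on a 60-channel perforated MEA
(8 × 8 grid without corners, 30 µm electrodes, 200 µm pitch, channel 15 a
reference that carries no units), sampled at 25 kHz. All times are seconds
from session start, float64. Stimulation protocols are either a full-field
light alternation (2 s ON / 2 s OFF, 20 repeats) or trains of identical
symmetric cathodic-first biphasic current pulses, one train per
(amplitude, duration) combination of the tested grid
{10, 15, 20, 25, 30} µA × {0.5, 1, 2} ms, pulses 1 s apart. The generator
emits 50 pulses per train by default; the analysis uses every onset
present (a `max_trials` override exists because published descriptions of
comparable experiments are ambiguous between 50 applied and 20 analysed
trials).

## Electrical response quantification

* **Baseline**: spikes in the 20 × 100 ms bins immediately before a
  train's first pulse, divided by 2 s. It is computed once per train
  block — 1 s inter-pulse spacing leaves no room for a 2 s window between
  pulses — and each block's 4 s pre-gap guarantees the window is free of
  evoked activity.
* **Evoked rate**: mean spike count per pulse in the indirect-response
  window 10–100 ms after onset, divided by 90 ms. The first 10 ms are
  blanked (stimulus artifact + direct somatic responses). Windows are
  half-open `[onset+10 ms, onset+100 ms)`.
* **Relative response** = evoked rate / baseline rate. Both are rates, not
  raw counts, because the windows differ in width (100 ms bins vs 90 ms).
  Conventions: 0/0 → 0; positive evoked over a silent baseline → +∞
  (unambiguously responsive; capped at 10⁶ before interpolation).
* **ES-responsive**: relative response ≥ 1.5 at the strongest stimulus
  (30 µA / 2 ms). The 1.5 factor is the package-wide threshold level and
  is configurable.
* **PSTH**: 20 ms bins over ±0.5 s around onset, counts averaged over
  trials. The 99% bound is the mean of the 25 pre-onset bins plus the
  two-sided normal quantile (z ≈ 2.576) times their sample SD. Because the
  SD comes from only 25 bins, flat Poisson cells exceed the bound in
  ~1.2% of bins rather than the nominal 0.5% — measured by
  `validation.psth_bound_exceedance` and reported by the acceptance
  script.
* **Modulation label**: per cell, 3 PAM curves (relative response vs
  amplitude at fixed duration) and 5 PDM curves (vs duration at fixed
  amplitude) are built from the same 15 measurements. A curve is
  "proportional" when its Spearman ρ ≥ 0.8 (configurable). *Well*
  requires every curve proportional **and** ES-responsiveness; *unmodulated*
  means no proportional curve or no ES response; anything between is
  *poor*. Rank-based, hence invariant to uniform scaling. Note that a
  single noise-induced rank flip on a 3-point PDM curve drops ρ to 0.5, so
  even strongly modulated cells are frequently labelled *poor* — the
  strictness is intentional and mirrors the small well-modulated fractions
  reported for real retinas (~6–18%).

## Light classification and severity

Onset (offset) scores are the pooled firing rate in the 0.5 s windows
after light onset (offset), divided by the whole-block mean rate. A phase
is responsive when its pooled count exceeds the 99% quantile of a Poisson
null at the block mean; labels follow from the two flags (ON, OFF, ON_OFF,
none). Two tests at 1% give ≤ 2% family false-positive rate on
unresponsive cells (measured ~1%). A patch's light-responsive fraction is
the percentage of cells labelled anything but `none`. Severity: untreated
patches are *normal*; treated patches are *severe* exactly when no cell is
light-responsive, else *non-severe*.

## Thresholds and the strength–duration law

`threshold_from_curve` finds the first upward crossing of the 1.5× level
and interpolates linearly between the bracketing tested stimuli. If the
curve starts above the level, the line through the first two points is
extrapolated downward, floored at 0.1× the smallest tested value
(reference group-mean threshold currents at 0.5 ms sit below the smallest
tested amplitude, so an extrapolation convention is unavoidable); if the
level is never reached the estimate is *censored*.

`fit_sd` fits *I*(*D*) = *R*(1 + *C*/*D*) by nonlinear least squares on
**relative** residuals (*I*‑predicted − *I*)/*I*, initialised from the
Weiss linearization (OLS of *Q* = *I·D* on *D*: slope *R*, intercept
*R·C*), with *R*, *C* > 0. Relative residuals match the dominant noise
mechanism — the block baseline multiplies a whole response curve, so
threshold errors are multiplicative — and keep short-duration/high-current
points from dominating. Non-convergence falls back to the linearized
estimate (flagged).

The pipeline pools threshold points from both modulation axes — (fixed
*D*, threshold *I*) from PAM and (threshold *D*, fixed *I*) from PDM; both
lie on the same strength–duration curve. Only **interpolated** points feed
the fit: censored points carry no value, and extrapolated points lie
outside the measured stimulus range and act as high-leverage outliers on a
hyperbola. Extrapolated thresholds are still reported per cell and enter
the group threshold tables.

**Identifiability.** On the tested duration grid (0.5–2 ms), a chronaxie
far above 2 ms makes *I*(*D*) ≈ *R·C*/*D*: the product *R·C* is well
determined but *R* and *C* separately are not, and fits can run away
(hence the pipeline summary reports medians). This is a property of the
experimental design, not of the estimator; resolving a 4–7 ms chronaxie
would require longer tested durations.

## Charge metrics

Charge per phase *Q* = amplitude × duration; µA × ms = nC exactly.
Charge density divides by the geometric disc area of the 30 µm electrode,
π(15 µm)² = 7.0686 × 10⁻⁶ cm², giving mC·cm⁻²·phase⁻¹. Rounding to 2
decimals happens only at report time. Group tables report the density two
ways — mean of per-cell densities, and density of the mean threshold;
with full-precision inputs the two coincide (density is linear in the
threshold), and they differ only through the rounding of printed means.

## Synthetic patches

Each simulated RGC is a homogeneous Poisson process (spontaneous rate,
lognormal across cells, median 8 Hz by default) plus:

* **light transients** — 0.5 s of added Poisson rate (default 25 Hz) after
  light onset and/or offset according to the cell's ON/OFF/ON–OFF type;
* **electrically evoked spikes** — per pulse, Poisson(*m*) spikes with
  truncated-normal latencies (mode 40 ms, SD 15 ms) inside 10–100 ms;
  never inside the artifact blank. The expected count *m* is a logistic
  function of per-phase charge *Q* = *I·D*, anchored to the cell's
  strength–duration law: the logistic is shifted so that at
  *I* = *R*(1 + *C*/*D*) the cell adds exactly the spikes that put the
  measured relative response at 1.5 (the evoked window also contains
  spontaneous spikes, so *m*_threshold = 0.5 × 0.09 s × spontaneous rate).
  That makes (*R*, *C*) the exact ground truth for the threshold and
  fitting stages.

The logistic steepness (`recruit_slope`, scale as a fraction of the
threshold charge) defaults to 0.12: single-cell electrical recruitment is
steep, and graded population curves arise from threshold heterogeneity
across cells. Broad-recruitment cells (slope ~0.8) rise across the whole
tested grid and are the ones that attain *well-modulated* labels; with the
steep default most cells plateau right above threshold and are honestly
labelled *poor*. Degeneration phenotypes: *non-severe* patches saturate
(response clamps at `evoked_max` beyond a saturation charge of ~1.2–1.8×
the 1 ms threshold charge) with lower evoked counts and a 48.4%
light-responsive fraction; *severe* patches have no light-responsive cells
and a 27.8% ES-responsive fraction; the healthy defaults are 66.1% and
56.1%. One master seed drives a patch; each cell uses a substream derived
from (seed, cell index).

Raw traces are rendered by stamping a canonical biphasic waveform
(negative trough, smaller positive lobe, ~1.6 ms) at each spike's sample
index over Gaussian noise; ground-truth sample indices are kept.

What the generator does **not** emulate: refractory structure and bursting
in spontaneous firing, rate drift, correlated noise across electrodes,
electrical artifact waveforms, overlapping spikes from neighbouring cells,
and direct (< 10 ms) responses. Passing validation therefore shows the
estimators are correct under the stated statistical assumptions, not that
they are robust to every pathology of real recordings.

## Validation studies and problem sizes

`rgcestim.validation` (all driven by one seed; the acceptance script and
tests use them):

* **Strength–duration recovery** — 60 cells, full 15-train design, 100
  pulses/train, evoked_max ≈ 10 spikes/pulse, spontaneous median 40 Hz,
  rheobase lognormal median 7 µA (σ = 0.1), chronaxie median 1.2 ms
  (σ = 0.2). These conditions put every threshold inside the tested grid
  and make the chronaxie resolvable by the tested durations (see
  Identifiability above); the high spontaneous rate gives the 2 s baseline
  enough spikes for precise relative responses. Median relative errors are
  typically ~10% (rheobase) and ~15–20% (chronaxie).
* **Detection** — 500 spikes at ~20 Hz over 25 s, SNR 8 (trough = 8× noise
  SD), 4× SD threshold after the 100 Hz high-pass; recall 1.00, precision
  ~0.97. On noise-only traces the false-positive rate matches the Gaussian
  crossing rate fs·P(x < −4σ) ≈ 0.8 events/s — an irreducible property of
  a 4σ threshold at 25 kHz, which is why the detection study fixes the
  trace length rather than letting noise-only stretches dilute precision.
* **Calibration** — 500 flat-Poisson PSTH simulations (bound exceedance
  ~1%) and 500 unresponsive cells through the light classifier
  (false-positive rate ~1–2%).
* **Monotonicity** — on noise-free expected curves of SD-law cells,
  estimated threshold amplitude is non-increasing in fixed duration and
  threshold duration non-increasing in fixed amplitude, with censored
  estimates treated as above-range.

These sizes keep the whole validation run at a few seconds on one CPU
while leaving comfortable statistical margins.

## Known limitations

* Thresholds below the smallest tested stimulus depend on the linear
  extrapolation convention.
* Rheobase/chronaxie estimates on the 0.5–2 ms grid are reliable only for
  chronaxies comparable to the tested durations (see Identifiability).
* The well-modulated criterion's all-curves rule makes the label noisy for
  borderline cells; the ρ threshold is configurable but no smoothing is
  applied to curves before ranking.
* The PSTH bound is a normal approximation on 25 baseline bins; its
  realised exceedance (~1.2%) is slightly above the nominal 0.5%.
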