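# Methods

## Measurement model

All geometry lives in pixel units with pixel centers at integer
coordinates, 0-based, origin top-left, `(y, x)` order. A ROI boundary is a
circle, a simple polygon, or (for ribbon-shaped structures) an open
segmented line. From a boundary the pipeline derives three pixel sets:

* **rim** — pixels whose signed boundary distance `d` satisfies
  `|d| < 1` px (a band of total width 2 px straddling the curve);
* **background annulus** — `|d - 3| < 1` px (the boundary dilated outward
  by 3 px, same 2-px width); disjoint from the rim by construction;
* **lumen** — `d < -1` px (the interior eroded by 1 px).

"Two-pixel wide" is interpreted as a band symmetric about the boundary
curve, matching the line-width semantics of interactive ROI tools; whether
such tools subsample at sub-pixel resolution is tool-dependent, so the
integer-pixel band above is this package's fixed definition and every set
is verified against a brute-force per-pixel distance enumeration in the
test suite. Polygon distances are taken to the polygon outline
(segment-wise, via shapely), not to a fitted ellipse, so free-hand ROIs
behave predictably.

The rim MFI minus the annulus MFI is the per-frame marker signal. Luminal
readouts record both the mean and the total over the lumen set; because the
YFP/CFP *ratio* over one pixel set is identical for means and totals, the
pH branch is insensitive to that choice (it uses means).

## Trace processing and alignment

Background-subtracted traces are min-max normalized over the entire
recorded kinetic, so 0 and 1 are attained and normalization is idempotent.
No smoothing is applied before normalization; event detection can enable an
optional 3-point median filter (off by default) as a robustness guard that
never alters stored traces.

Reference events:

* **Rab5 peak** — time of the global maximum of the normalized trace
  (earliest sample on ties). Maxima at the first or last frame are flagged
  as possibly truncated. Multi-peak traces anchor on the tallest peak and
  carry a peak-count flag.
* **Rab7 half-max** — the earliest upward crossing of 0.5 of the final
  maximum after which the trace never falls below it again, linearly
  interpolated between frames; requires a plateau (last-quartile mean of
  the normalized trace at or above 0.8). "Final maximum" is the global
  maximum of the recorded trace, consistent with min-max normalization.

Alignment subtracts the per-endosome event time and assigns samples to the
nearest multiple of the bin width (default: the frame interval; an explicit
rule is needed when experiments at 1- and 2-min intervals are mixed). Per
bin and channel the ensemble mean, SD (ddof = 1, exactly 0 for constant
bins), SEM = SD/sqrt(n) and n are reported; bins carried by fewer than
`n_min` endosomes (default 2) are dropped. Which error bar a figure shows
(SD vs SEM) is a config choice; both are always computed.

**Conversion duration** is operationalized as the time from Rab7 first
exceeding 10% of its plateau (normalized trace) to Rab5 last falling below
10% of its peak and staying below, both linearly interpolated. The 10%
"initiation" threshold is this package's definition of conversion onset.

**Accessory patterns** (single peak / double peak / persistent) are binned
by a deterministic rule replacing by-eye classification: peaks count at
prominence ≥ 0.2 (normalized units) with ≥ 3 min separation; a trace is
"persistent" when it stays ≥ 0.3 for ≥ 80% of the frames later than 5 min
after the conversion reference. These thresholds are package choices, fixed
in `PatternParams`.

**Doubling time** uses the standard exponential-growth form
`(t2 - t1) · log 2 / log(c2 / c1)` (hours).

## pH calibration

Calibration fits the sigmoidal four-parameter dose-response model with
variable slope, with pH in the role of log(dose) and the background-
corrected luminal YFP/CFP ratio as response. The fit (scipy
`curve_fit`) is initialized from the data (asymptotes from the extreme
ratios, inflection at the median pH, hill 1) and is deterministic given the
points; it requires ≥ 5 distinct pH levels spanning ≥ 1.5 units. Inversion
is analytic: `pH = pH50 - log10((top - bottom)/(R - bottom) - 1)/hill`.
Ratios at or outside `(bottom, top)` are clipped just inside the domain and
flagged rather than extrapolated or rejected — ratios near the bottom
asymptote are expected for endolysosomes. Round-trip accuracy is < 1e-9 pH
across the domain.

## Synthetic scene generator

The generator emulates time-lapse imaging of enlarged (ionophore-washout
style) endosomes, the package's stand-in for microscope data. Per endosome:

* **Rab5**: piecewise-linear rise (default onset 10 min, rise 5 min) to
  `rab5_peak_amp` (default 150 counts), optional hold, then linear decline
  to baseline. Simple and analytically checkable.
* **Rab7**: logistic rise to `rab7_plateau_amp` (default 150 counts) with
  time constant `rab7_tau_min`.
* **Coupling**: the Rab5 decline starts at the instant Rab7 first reaches
  `conversion_coupling` (default 0.5) of its plateau — implemented by
  solving the logistic for that crossing — and Rab5 returns to baseline
  `conversion_duration_min` (default 4 min) after Rab7's 10%-of-plateau
  crossing.
* **Luminal pH**: a falling sigmoid from `ph_pre_rab5` 6.6 to
  `ph_post_conversion` 5.7 (10–90% width 4 min), centered by default on the
  Rab7 half-max time. A conversion-incompetent mode (`rab7_plateau_amp =
  0`, as in fusion-machinery knockouts) leaves Rab5 on the membrane and
  pushes the pH drop far beyond the recording.

Two numerical choices keep the encoded event times exactly recoverable at
the default 1-min sampling, rather than biased by discretization:

* `rab7_tau_min` defaults to `1/ln 9` ≈ 0.455 min, which places the
  10%-of-plateau crossing exactly one frame before the half-max time (the
  10–90% rise takes 2 min, comfortably inside the conversion window). With
  landmarks off the grid, linear interpolation across the convex logistic
  rise and across the Rab5 baseline kink systematically lengthens measured
  durations by ~0.2 min.
* Scenario generators draw recruitment onsets on the frame grid (integer
  minutes). With sub-frame phases, discrete peak detection on the
  asymmetric Rab5 pulse (slow rise, fast fall) is biased ~0.3 frames early,
  which would shift the ensemble Rab7-at-t0 reading below the coupling
  value actually encoded. Amplitudes (log-normal, CV ≈ 20%), radii
  (uniform 8–13 px) and noise do vary per endosome.

The **sensor model** is a tandem YFP/CFP probe: YFP brightness follows a
pKa-type sigmoid in pH (pKa 6.3, hill 1), CFP increases mildly with
acidification (5%/pH unit, floored), so the YFP/CFP ratio rises
monotonically with pH. The per-channel forms are a modelling convention:
only self-consistency between generator and calibration module is claimed,
not literature photophysics.

The **forward render** draws marker channels as a ring (Gaussian radial
profile, σ = 1 px, at the endosome radius) scaled by the marker amplitude
over a uniform background (20 counts), and sensor channels as a filled disk
with expectation `brightness × f(pH)`. Optional angular Gaussian spots
modulate ring channels to emulate rim subdomains. Noise is Poisson on the
expected counts plus additive Gaussian read noise (σ = 3), clipped at zero;
at the defaults the per-pixel SNR at the rim is ≈ 10. Imaging noise levels
and exposure are free parameters of the generator (chosen once as
plausible), not literature values.

What the generator does **not** model: point-spread-function optics,
z-stacks, cell context or segmentation, endosome drift or deformation,
photobleaching, channel bleed-through, or sub-frame event phases (see
above). Passing tests therefore demonstrate that the *analysis* recovers
what the *forward model* encodes — correctness of the measurement and
inference chain — not robustness to every artifact of real microscopy.
Manual ROI placement is likewise out of scope: the generator supplies the
true geometry as the ROI series.

## Benchmark scenarios and problem sizes

`fig4_conversion` (27 endosomes, 40 frames at 1 min), `fig11_ph`
(19 sensor endosomes, 30 frames, plus an 8-level pH 4.0–7.5 calibration
set), `golgi_ribbon` (one ribbon at pH 6.2 measured through a 2-px
segmented-line band), `fig7_patterns`, `fig6_subdomains` and `ccz1_ko`
(conversion-incompetent). Images are 64×64 px; these sizes keep a full
benchmark run in the tens of seconds on one core while leaving every
statistic well-determined. All randomness flows from explicit seeds;
identical config and seed give byte-identical outputs.

## Known limitations

* The background annulus sees a small, exact fraction of the Gaussian ring
  tail (~2% at σ = 1 px); background subtraction therefore scales, never
  distorts, normalized kinetics.
* The calibration curve is fitted to the generator's ratio law, which is a
  4PL only approximately (the CFP factor is linear in pH); residual
  inversion error at the defaults is < 0.02 pH.
* Pooled subdomain correlations treat every sampled position as one
  observation; positions along a smooth profile are autocorrelated, so the
  effective sample size is smaller than the pooled count (the independence
  null |r| shrinks only with the number of endosomes).
* No statistical testing between experimental conditions is provided; the
  kinetics readouts are descriptive (ensemble means with SD/SEM), and no
  curve models are fitted to individual traces.
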