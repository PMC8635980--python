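# endokin

Single-endosome maturation kinetics from multi-channel time-lapse imaging.

Endosome maturation converts early, Rab5-positive endosomes into late,
Rab7-positive endosomes that acidify and fuse with lysosomes. Because each
endosome matures on its own schedule, population-level imaging blurs the
choreography; the tractable readout is per-organelle: follow one enlarged
endosome over time, quantify each marker at its limiting membrane, and
anchor all traces to the Rab5-to-Rab7 conversion event before averaging.
`endokin` implements that analysis as a reusable, tested pipeline for
anyone quantifying per-organelle recruitment kinetics or luminal pH from
ring-shaped organelles:

* **Rim quantification** — mean fluorescence intensity (MFI) over a
  2-pixel-wide band straddling the endosome boundary, background-corrected
  with a second 2-pixel band offset 3 px outward, plus luminal statistics
  from the boundary eroded by 1 px.
* **Event-anchored averaging** — traces are min-max normalized over the
  full kinetic, `x_norm = (x - min x) / (max x - min x)`, anchored at the
  Rab5 peak or at the time Rab7 durably crosses 50% of its final maximum
  (the point of Rab conversion), and averaged per relative-time bin with
  SD/SEM/n.
* **Ratiometric pH** — a tandem YFP/CFP sensor's background-corrected
  luminal ratio R is calibrated against buffers of known pH with the
  four-parameter dose-response model
  `R(pH) = bottom + (top - bottom) / (1 + 10^((pH50 - pH) * hill))`
  and inverted analytically to convert per-frame ratios to pH.
* **Subdomain profiles** — intensity sampled along a 2-px-thick spline band
  around the full perimeter (top start, clockwise), pooled across endosomes
  into a Pearson correlation and regression between two markers.
* **Synthetic scene generator** — ground-truth marker kinetics
  (piecewise-linear Rab5 pulse, logistic Rab7, coupled at 50% of the Rab7
  plateau), sigmoidal luminal pH trajectories, and a forward imaging model
  (Gaussian ring / filled disk, Poisson + Gaussian noise) so every stage is
  testable against exact truth without microscope data.

## Worked example

Simulate a 27-endosome conversion experiment, measure and align it:

```python
from endokin.pipeline import PipelineConfig, simulate_scenario, analyze_scenario
import numpy as np

scn = simulate_scenario(PipelineConfig(scenario="fig4_conversion", seed=1))
summary = analyze_scenario(scn)
durations = list(summary["conversion_durations_min"].values())
print(f"endosomes aligned:        {summary['n_aligned']}")
print(f"Rab7 at t=0 (norm.):      {summary['rab7_at_t0']:.3f}")
print(f"median conversion (min):  {np.median(durations):.2f}")
```

prints

```
endosomes aligned:        27
Rab7 at t=0 (norm.):      0.496
median conversion (min):  3.81
```

Each endosome's rim traces were background-subtracted, normalized to
[0, 1], and aligned at its Rab5 peak. The ensemble-mean normalized Rab7 at
relative time t = 0 is ~0.5: Rab5 starts to leave the membrane when Rab7
has reached about half of its final level. The median conversion duration
(from Rab7 first exceeding 10% of its plateau to Rab5 falling durably below
10% of its peak) is under 4 minutes.

The pH branch works the same way:

```python
scn = simulate_scenario(PipelineConfig(scenario="fig11_ph", seed=2))
summary = analyze_scenario(scn)
print(f"pH before Rab5 recruitment: {summary['ph_pre_mean']:.2f}")
print(f"pH after conversion:        {summary['ph_post_mean']:.2f}")
```

```
pH before Rab5 recruitment: 6.60
pH after conversion:        5.70
```

A calibration image set (pH 4.0–7.5) is rendered, the four-parameter curve
fitted, and per-endosome luminal YFP/CFP ratios converted to pH: early
endosomes sit near pH 6.6 and drop to ~5.7 across Rab conversion.

A CLI mirrors the library (`endokin simulate / measure / kinetics / ph /
subdomains / acceptance`); see `endokin --help`.

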