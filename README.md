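# synaptodyn

Quantitative analysis of pre- and postsynaptic protein-cluster dynamics in
two-channel live imaging.

Inhibitory synapse assembly can be watched in real time: presynaptic
boutons (e.g. GAD65-GFP) and postsynaptic scaffold/receptor clusters
(gephyrin, GABA_A_R γ2) appear as fluorescent puncta that move, appear,
disappear, and pair up across the synaptic cleft over an hour of imaging.
`synaptodyn` turns the per-frame track tables exported by a particle
tracker into the analyses this kind of experiment needs:

- **registration** — chained thin-plate-spline (TPS) unwarping of the
  time-lapse with linearly time-interpolated landmarks (30-frame chunks),
  after integer-pixel translation pre-alignment, so tissue deformation is
  not mistaken for puncta mobility;
- **stability** — for a track spanning frames f₀…f_n with |f_i| direct
  detections, `stability = |f_i| / (f_n − f₀ + 1)`; bridged gap frames
  count toward the span but not the numerator, so the statistic is
  independent of track duration (a gapless track scores exactly 1);
- **mobility** — displacement from origin over the 10–60 min analysis
  window, mean velocity, net Euclidean displacement;
- **photobleach correction** — `F(t) = A·e^(−kt) + C` fitted to the
  control-arm mean intensity (t in minutes), applied as
  `F_corr(t) = F_meas(t) · F(t₀)/F(t)`, then baseline normalization to the
  first 3 min (12 frames at 15 s);
- **colocalization events** — two puncta are colocalized when their
  disk-equivalent surfaces touch (gap = 0); a *new* event requires a
  non-colocalized 10-min history, then ≥95% contact over the following
  10 min (events starting in the final 10 min are not scored); the partner
  is the opposite-channel track whose centre lies within 1 µm of the site
  and is classed *existing*/*new* by whether it was present ≥10 min before
  the event;
- **statistics** — bin width chosen as the smallest round-number candidate
  whose binned lag-1 autocorrelation of the control mean series falls
  below 0.3; linear mixed-effects models (`response ~ treatment × time`,
  random intercepts for image and track-within-image) with the
  time × treatment interaction as headline; quintile follow-ups,
  ≥1.5-fold-increase flagging, ANCOVA slope comparison, and KS / χ² /
  Fisher / Mann–Whitney stages.

Because raw live-imaging datasets of this kind are rarely deposited, the
package ships a first-class synthetic session generator
(`synaptodyn.synthetic_data`) with known ground truth — confined random
walks with a mobile tail, treatment-onset mobility shifts, detection
dropout, monoexponential bleaching, planted colocalization events and
receptor-recruitment ramps — so every stage is validated by parameter
recovery.

## Worked example

```python
from synaptodyn.cli_report import RunConfig, run_pipeline

out = run_pipeline(RunConfig(out_dir="demo", seed=7, scenario_preset="default"))
print((out / "report.md").read_text())
```

runs the full pipeline on the paper-scale synthetic study (10 images per
arm, ~35 presynaptic tracks per image, 60 min at 15 s frames) and prints,
among other panels:

```
## Panel 1 — Displacement over time by treatment
Binned LME (bin = 40 frames): time x treatment coef = 0.002251, p = 0.0405 (n = 780 tracks)

## Panel 3 — Colocalized-fluorescence quintile curves
- control: final-window normalized means, bottom→top quintile: 1.115, 1.028, 1.002, 0.999, 0.999
- sema4d: final-window normalized means, bottom→top quintile: 1.361, 1.058, 1.015, 1.001, 1.002

## Panel 4 — New colocalization events
events detected: 83; class counts: {'control:existing': 10, 'control:new': 31,
'sema4d:existing': 11, 'sema4d:new': 31}

## Panel 6 — Fold-increase fractions
fraction of scaffolds with >= 1.5x colocalized signal: control: 0.029, sema4d: 0.088
```

Reading the numbers: the positive time × treatment coefficient (µm/min) is
the treatment-dependent mobility increase the mixed model is designed to
detect; the quintile curves show receptor recruitment concentrated at
receptor-poor (bottom-quintile) scaffolds under treatment while
receptor-rich scaffolds stay flat; roughly three quarters of new
colocalization events involve a newly formed partner; and the flagged
fractions recover the planted share of scaffolds with ≥1.5× receptor
accumulation. The same stages are available individually
(`synaptodyn.compute_stability`, `fit_bleach_model`,
`detect_new_colocalization_events`, `fit_treatment_time_lme`, …) and from
the command line (`synaptodyn simulate|ingest|unwarp|run`).

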