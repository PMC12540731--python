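# spindlekin

Quantification pipeline for chromosome-congression studies: kinetochore
and spindle-pole trajectory analytics, immunofluorescence intensity
ratios, the accompanying statistics, and a synthetic spindle generator
with known ground truth.

## The problem

During early mitosis most chromosomes congress quickly to the metaphase
plate, but some linger near the spindle poles ("polar chromosomes"). Their
congression normally requires the kinesin-7 motor CENP-E — and, crucially,
centrosomes themselves inhibit congression initiation when CENP-E is
inactive: Aurora A kinase concentrates at centriolar poles in a spatial
activity gradient (negligible beyond ~3 µm), locally boosting Aurora B and
the phosphorylation of outer-kinetochore microtubule-binding proteins,
which prevents the stable end-on attachments needed to start moving.
Acentriolar poles carry ~4-fold less Aurora A activity, so chromosomes
near them initiate congression even without CENP-E.

This package implements the measurements used to establish and quantify
that picture, for anyone analysing 2D kinetochore/pole track tables or
kinetochore/pole ROI intensity tables:

- **geometry** — per-frame spindle coordinate frame: the equatorial plane
  is the perpendicular bisector of the pole–pole segment; pair distances
  to plane / nearest pole / spindle centre, pair–axis angle,
  interkinetochore distance.
- **congression** — polar vs aligned classification (aligned if a sister
  is ≤ 3 µm from the plane *or* the pair midpoint is no closer to a pole
  than to the spindle centre), alignment events (midpoint first within
  2 µm of the plane), residence time (bipolarization → alignment,
  censored at anaphase), congression velocity (net midpoint displacement
  over the last 6 min before the 2-µm crossing), polar counts per cell
  and per pole, mitosis duration, and the time-to-alignment vs
  initial-pole-distance regression.
- **intensity** — background subtraction, z-plane scaling, CENP-A
  normalization, 1-µm pole-exclusion filter, centriolar/acentriolar pole
  ratios, polar-vs-aligned ratios, intensity-vs-distance gradient fits.
- **stats** — mean/SD with 95% CIs of both, one-way ANOVA + two-sided
  Tukey HSD (Tukey–Kramer for unbalanced groups, studentized-range
  p-values, star conventions), OLS with two-tailed slope test and R².
- **synthetic** — generator of full cohorts (tracks, events, intensities,
  ground truth) under the gradient-gated initiation-hazard model
  h(d) = h_max·max(0, 1 − α·A(d)/A_thr), A(d) = A_pole·e^(−d²/2σ²),
  for bipolar spindles with 0/1/2 centrioles per pole, with or without
  CENP-E activity, and with acute Aurora A attenuation.
- **io / cli** — CSV schemas for tracks, events and intensities, and a
  `spindlekin simulate | analyze | report` command line.

The numbered scripts under `analysis/` run the whole study on synthetic
cohorts (simulate → congression metrics → intensity ratios → group
statistics) and write tidy tables under `results/`.

## Worked example

Twenty simulated CENP-E-inhibited cells whose spindles carry one
centriolar and one acentriolar pole (preset `cenpe_inhibited_1v0`),
counted 5 minutes after bipolarization, with the pAurA pole-intensity
ratio computed by the intensity pipeline:

```python
import numpy as np
from spindlekin import AnalysisConfig, get_preset, simulate_experiment
from spindlekin.congression import polar_count_at_time
from spindlekin.intensity import pole_ratio

cfg = AnalysisConfig()
cohort = simulate_experiment(get_preset("cenpe_inhibited_1v0"), 20, 7)

counts = [polar_count_at_time(cell, 15.0, cfg) for cell in cohort.cells]
print("mean polar count:", np.mean([c.total for c in counts]))
print("  centriolar pole:", np.mean([c.per_pole["A"] for c in counts]))
print("  acentriolar pole:", np.mean([c.per_pole["B"] for c in counts]))

by_cell = {}
for s in cohort.intensities:
    by_cell.setdefault(s.cell_id, []).append(s)
ratios = [pole_ratio(ss).value for ss in by_cell.values()]
print("mean pAurA pole ratio: %.2f" % np.mean(ratios))
```

prints

```
mean polar count: 4.75
  centriolar pole: 3.95
  acentriolar pole: 0.8
mean pAurA pole ratio: 3.98
```

i.e. polar chromosomes accumulate almost exclusively at the centriolar
pole (~4 vs ~1 per pole), which also carries ~4-fold more active Aurora A
— the asymmetry the gradient model predicts. The same numbers are
available from the shell:

```sh
spindlekin simulate --preset cenpe_inhibited_1v0 --n-cells 20 --seed 7 -o sim/
spindlekin analyze --tracks sim/tracks.csv --events sim/events.csv \
    --intensities sim/intensities.csv -o out/
spindlekin report -o out/
```

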