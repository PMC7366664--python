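# cohmap

Mesoscale and cellular analysis of coherent-motion processing in mouse
visual cortex: stimulus synthesis, Fourier-phase retinotopy with visual
field sign area segmentation, coherent-motion correlation mapping,
retinotopic-asymmetry statistics, and a single-cell two-photon tuning
pipeline — all exercisable end to end on synthetic sessions with planted
ground truth.

## The scientific problem

Widefield calcium imaging over a 4 mm cranial window measures the pooled
activity of primary visual cortex (V1) and the higher visual areas (LM, AL,
PM, LI, RL, AM) while the animal views random dot kinematograms (RDKs):
fields of drifting dots in which a controlled fraction *c* — the
**coherence** — shares one direction. Because higher coherence drives
motion-selective populations harder regardless of direction, the
per-pixel **coherent-motion correlation**

&nbsp;&nbsp;&nbsp;&nbsp;*M<sub>x,y</sub>* = CC( r̄<sub>x,y</sub>, m )

(Pearson correlation between the trial-averaged ΔF/F response r̄ and the
frame-indexed coherence trace *m*) maps where coherent motion is processed,
both across areas and along the retinotopic axes within an area. The
supporting machinery includes:

* **ΔF/F**: (F − F̃)/F̃ per pixel with F̃ the temporal median (widefield),
  or (F − F₀)/F₀ with F₀ the mode of the corrected-fluorescence density
  (single cells);
* **retinotopy**: the phase of the first Fourier harmonic of the response
  to a periodic drifting checkerboard bar, combined across opposite sweep
  directions to cancel the indicator delay;
* **visual field sign**: sin(∠∇azimuth − ∠∇elevation), which flips between
  mirror-image area maps and delimits area borders; patches are refined by
  an iterative split (redundant visual-field coverage > 10 %) / merge
  (adjacent same-sign patches sharing < 10 % coverage) rule;
* **reliability**: R<sub>x,y</sub> = mean over trials *t* of
  CC(r<sub>t</sub>, r̄<sub>≠t</sub>);
* **motion energy**: the magnitude of the frame-summed Horn–Schunck optical
  flow field of a natural movie, used as the regressor *m* for movie
  sessions, with a 3×3 ANSI uniformity index
  1 − (B<sub>max</sub> − B<sub>min</sub>)/(B<sub>max</sub> + B<sub>min</sub>);
* **neuropil correction**: F<sub>corrected</sub> = F<sub>soma</sub> −
  α·F<sub>neuropil</sub> with α = clip(cov/var, 0, 1), the minimiser of
  |CC(F<sub>corrected</sub>, F<sub>neuropil</sub>)| on [0, 1];
* **direction tuning**: per-direction coherence correlations treated as
  vectors; the preferred direction is the angle of the rectified vector
  sum, and population non-uniformity is tested with the Hodges–Ajne
  statistic (minimal count *m* in any closed half-circle, exact tail
  (n − 2m)·C(n, m)·2<sup>1−n</sup>);
* **statistics**: two-tailed one- and two-sample t tests with Hedges' g
  (pooled s.d. with small-sample correction J = 1 − 3/(4(n₁+n₂) − 9)) and
  Bonferroni thresholds.

Real acquisitions are not required: `cohmap.synthetic` builds cortical
sheets and two-photon fields with planted retinotopy, field signs,
elevation-dependent coherence gains, von Mises direction tuning, and known
neuropil mixing, so every stage can be scored against ground truth.

## Worked example

```python
import numpy as np
from cohmap.synthetic import make_cortical_sheet, simulate_widefield_session
from cohmap.retinotopy import (recover_retinotopy, segment_areas,
                               label_areas, compute_dff)
from cohmap.stimulus import make_coherence_trace
from cohmap.motion import (coherent_motion_correlation_map, areal_summary,
                           retinotopic_asymmetry)

# a 64 x 64 cortical sheet with V1 + 6 satellite areas and a planted
# negative elevation gradient of the coherence gain
truth = make_cortical_sheet(shape=(64, 64), n_areas=7, seed=1)

# retinotopy from four simulated drifting-bar sweeps at SNR 3
ret = recover_retinotopy(truth, seed=2, snr=3.0)
labels, signs = segment_areas(ret.sign_map, ret.azimuth, ret.elevation)
names = label_areas(labels, signs)
print("areas:", sorted(names.values()))
v1 = truth.labels == 1
print("median V1 azimuth error: %.2f deg"
      % np.nanmedian(np.abs(ret.azimuth - truth.azimuth)[v1]))

# an RDK session and its coherent-motion correlation map
trace = make_coherence_trace(block_frames=50, seed=3, n_cycles=3,
                             gray_frames=20)
stack, info = simulate_widefield_session(truth, trace, "rdk", seed=4,
                                         snr=3.0, n_trials=4)
avg = compute_dff(stack).data.reshape(4, -1, 64, 64).mean(axis=0)
m_map = coherent_motion_correlation_map(avg, trace)
print(areal_summary(m_map, labels, names)[["area", "mean"]].round(3))
r_az, r_el = retinotopic_asymmetry(m_map, truth.azimuth, truth.elevation,
                                   truth.labels > 0)
print("r_azimuth = %.3f, r_elevation = %.3f" % (r_az, r_el))
```

Output:

```
areas: ['AL', 'AM', 'LI', 'LM', 'PM', 'RL', 'V1']
median V1 azimuth error: 0.68 deg
area  mean
  V1 0.420
  AM 0.331
  ...
r_azimuth = 0.007, r_elevation = -0.951
```

All seven planted areas are recovered with the correct names and field
signs, V1 retinotopy is accurate to well under a degree, and the planted
negative elevation gradient of the coherence gain shows up as a strongly
negative correlation between per-pixel coherent-motion correlation and
preferred elevation — while azimuth stays uncorrelated, the signature of a
lower-visual-field bias in coherent-motion processing.

The same study runs end to end from the command line:

```bash
cohmap run --preset tiny --seed 7 --out cohmap_out
```

which writes retinotopy maps, the area segmentation, motion-correlation
maps, areal summary and statistics tables, the per-cell two-photon table,
and a JSON report with planted-vs-recovered comparisons.

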