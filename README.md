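# synapdyn

Quantitative fluorescence-microscopy analysis of receptor microcluster
dynamics at the immunological synapse — the kind of pipeline used to ask
whether a membrane-remodelling adaptor such as SNX9 is recruited to CD28
co-stimulatory receptor clusters, how fast it exchanges there, and whether
it stabilises them.

The package turns the classic manual FIJI/ZEN workflows of this field into
tested, scriptable code:

- **Structure detection** — one global intensity threshold (manual or Otsu
  on the reference plane), per-slice connected components, 5–1000 px size
  window; per-stack counts, axial profiles at a given z-step and the axial
  peak position.
- **Colocalization** — the mask-arithmetic overlap construction
  (`clip(A − invert(B), 0)`, provably the pixelwise AND), the percentage
  of channel-A structures overlapping channel B, cluster/cytosol
  mean-intensity fold change, and nuclear/whole-cell translocation ratios.
- **Photoactivation pulse-chase** — per-frame incorporation of a
  photoactivated channel into cluster vs cytosol compartments, persistence
  at sparse chase timepoints, and post-activation vesicle counting with a
  calibration contract (a threshold that detects anything before the
  activation frame is rejected).
- **FRAP kinetics** — bleach correction against unbleached control ROIs,
  normalization to [0, 1], and weighted least-squares fitting of

  F(t) = F_∞ · (1 − Σᵢ wᵢ e^(−t/τᵢ)),  Σᵢ wᵢ = 1,

  for 1–3 components, with model order chosen by parsimony on the weighted
  SSR; recovery-at-time readouts (e.g. % recovery at t = 380 s).
- **Curve statistics** — pointwise Welch tests (Mann–Whitney optional),
  the time-of-divergence statistic (first timepoint from which two
  condition means stay significantly apart), experiment-level aggregation,
  and the internalised/surface expression ratio normalised to wild type.
- **Synthetic data** — generators for every scene kind with planted ground
  truth (spot positions, overlap fractions, kinetic constants, divergence
  times), so each stage can be validated against known answers.

## Worked example

```python
import numpy as np
from synapdyn import synthetic_data as sd, structure_detection as det
from synapdyn import colocalization as coloc, frap_kinetics as fk, curve_stats as cs
from synapdyn.structure_detection import DetectionParams

# two-channel scene: 20 clusters per channel, half co-centered
stack, truth = sd.make_cluster_scene(20, 20, overlap_fraction=0.5,
                                     noise=sd.DEFAULT_NOISE, seed=11)
params = DetectionParams(threshold_mode="manual",
                         threshold_value=truth.params["suggested_threshold"])
structures_a = det.detect_structures(det.binarize(stack, 0, params), params)
mask_b = det.binarize(stack, 1, params)[0, 0]
pct = coloc.percent_structures_overlapping(structures_a, mask_b)
print(f"{len(structures_a)} channel-A structures, "
      f"{pct:.1f}% overlap channel B")

# FRAP: bi-exponential recovery with imaging bleach, fitted and read out
bleach, controls, _ = sd.make_frap_series(w=(0.6, 0.4), tau=(20.0, 200.0),
                                          f_inf=0.7, k_b=0.002,
                                          noise_sd=0.02, seed=11)
norm = fk.process_frap(bleach[0], controls, prebleach_frames=10)
fit, fits = fk.select_model(norm, seed=11)
print(f"selected {fit.n_components} components: "
      f"tau = {fit.tau[0]:.1f} s / {fit.tau[1]:.1f} s, "
      f"weights = {fit.weights[0]:.2f}/{fit.weights[1]:.2f}, "
      f"F_inf = {fit.f_inf:.2f}")
print(f"recovery at 380 s: {fk.recovery_at_time(norm, 380.0):.1f}%")

# divergence between two conditions that separate at 94 s
ens_a, ens_b, _ = sd.make_two_condition_ensembles(t_star=94.0, effect_size=0.2,
                                                  noise_sd=0.02, seed=11)
res = cs.divergence_time(ens_a, ens_b, alpha=0.05)
print(f"time of divergence: {res.time_s:.0f} s")
```

which prints

```
20 channel-A structures, 50.0% overlap channel B
selected 2 components: tau = 23.1 s / 176.9 s, weights = 0.60/0.40, F_inf = 0.68
recovery at 380 s: 67.7%
time of divergence: 94 s
```

All 20 planted channel-A clusters are detected and the planted 50% overlap
is recovered exactly despite shot and read noise.  Model selection picks the
bi-exponential recovery (two exchange processes) and returns its time
constants, their weights and the mobile fraction F_∞; the recovery readout
at 380 s and the 94 s divergence time are the assay-level summaries compared
across conditions.

## Command line

A thin CLI wraps the library: `synapdyn simulate | detect | axial |
overlap | foldchange | incorporate | vesicles | frap | diverge`, each with
`--config run.yaml` for options.  For example:

```sh
synapdyn simulate --kind clusters --seed 3 --out scene.tif   # + scene.truth.json
synapdyn detect scene.tif --threshold 110 --out structures.csv
```

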