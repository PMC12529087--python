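# myotract

Skeletal-muscle diffusion-tensor MRI (DT-MRI) tractography, built around
the question of how the *seeding* of streamlines affects quantitative
muscle architecture. The package provides:

- a simulated bipennate muscle with fully known fiber architecture
  (orientation field, diffusion tensors, and Stejskal–Tanner signals
  S = S₀·e^(−b rᵀ D r)), plus Gaussian noise with per-trial substreams;
- weighted-least-squares tensor estimation with eigen-system and FA maps;
- three seeding schemes: **APO** (an aponeurosis boundary mesh with an
  updated floor/ceil candidate lookup so seeds digitized on the
  muscle–aponeurosis boundary never fail to initiate), **VXL** (regular
  voxel grid inside a once-eroded muscle mask), and **EDGE** (voxels one
  layer inside the outer boundary and around the aponeurosis);
- deterministic Euler tractography at a one-voxel-width step with
  muscle-specific termination (mask exit, FA window, inter-segment angle
  > 30° on two consecutive points), polynomial tract smoothing, and
  farthest streamline sampling (FSS);
- architecture quantification — fiber-tract length L_FT, pennation angle
  α (chord vs. the muscle's line of action), curvature κ (Frenet–Serret),
  and for aponeurosis-seeded tracts the aponeurosis angles γ and
  β = α − γ;
- evaluation statistics: sampling uniformity (points/voxel, CV,
  % filled), Bland–Altman limits of agreement, ICC(3,1), and a
  Monte-Carlo noise experiment.

It is aimed at researchers developing or validating muscle tractography
pipelines who need a ground-truth phantom and reference implementations
of the seeding, tracking, and quantification conventions used in the
muscle DT-MRI literature. Real datasets (NIfTI DWI + bval/bvec + masks)
run through the same pipeline.

## Worked example

Run the noise-free simulation with aponeurosis seeding and a 500-tract
FSS condition:

```bash
myotract run --scheme APO --fss 500 --out example --seed 1
```

`example/architecture_summary.csv` then contains (abridged):

| condition | L_FT (mm) | α (°) | κ (m⁻¹) | γ (°) | β (°) | ICC(3,1) | mean Δα (°) |
|-----------|-----------|-------|---------|-------|-------|----------|-------------|
| all       | 50.1      | 17.8  | 2.8     | 19.4  | −1.7  | 0.9966   | −0.0026     |
| fss500    | 47.2      | 18.0  | 2.9     | 19.3  | −1.4  | 0.9968   | −0.0004     |

Reading this: the 1545 tracts propagated from the aponeurosis mesh have a
mean fiber length of ~50 mm and a mean pennation angle of ~18° on this
phantom; the segment-wise comparison against the known fiber directions
gives an ICC(3,1) of 0.997 with a mean Bland–Altman difference well under
a degree, i.e. the tracts faithfully reproduce the simulated
architecture when no noise is present. γ is the fiber–aponeurosis angle
and β = α − γ the aponeurosis–line-of-action angle (negative here because
this phantom's sheet is steeper than its fibers' mean chord).
`sampling_summary.csv` reports the corresponding points/voxel uniformity
(e.g. `3.9 (0.9)`, CV 23.6%, 80.5% of muscle voxels sampled for the
all-tract condition), and per-tract values are in
`architecture_APO_*.csv`. Streamlines are written both as TRK and as
plain CSV. Adding `--trials 1000 --snr 39` runs the Monte-Carlo noise
experiment and writes `montecarlo_summary.csv` with
`mean [CI_low CI_high]` entries per property.

The same pipeline runs on real data in `--mode real` fashion through the
library (`RunConfig(mode="real", dwi_path=..., encoding_prefix=...,
muscle_mask_path=..., aponeurosis_mask_path=...)`), with the in vivo
presets: FA window 0.05–0.40, every-third-voxel VXL seeding, and the
L_FT/α/κ exclusion thresholds.

## Layout

```
src/myotract/
  phantom.py     geometry, orientation field, tensors, encoding, signals, noise
  tensorfit.py   WLS tensor fit, eigen-system, FA
  seeding.py     APO mesh + lookup, VXL, EDGE
  tracking.py    propagation, termination, trimming, filtering, smoothing
  quantify.py    FSS, central axis, alpha, kappa, L_FT, gamma/beta
  evaluate.py    sampling stats, Bland-Altman, ICC(3,1), Monte Carlo
  io.py          NIfTI, bval/bvec, TRK, CSV
  pipeline.py    RunConfig + run_pipeline
  cli.py         the `myotract` command
docs/methods.md  model, parameters, and design notes
```
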