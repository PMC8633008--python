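# cardiophen

Functional and structural phenotyping of cardiomyocytes differentiating in
3-D embryoid bodies (EBs), for labs that quantify contractile function and
sarcomere organization from microscopy rather than electrophysiology. The
package turns the raw observables of such an experiment — marker
trajectories from videos of beating syncytia, immunostained sarcomere ROI
images, single-cell masks, and confocal Z-stacks — into comparable
per-sample metrics, and compares experimental arms against a control with
one-way ANOVA followed by Fisher's LSD.

## What it computes

**Beating kinematics** from marker trajectories (x, y in pixels, t in
seconds; typically 12 markers per recording):

- chronotropy f [Hz] — beat frequency, by counting peaks of each marker's
  signed displacement along its dominant motion axis;
- kinematic inotropy max|v| [pixel/s] — maximum contraction velocity;
- dynamic inotropy max|dv/dt| [pixel/s²] — contraction force per unit
  mass (with H = ½m|v|² and m ≡ 1 the force along the path is the
  acceleration);
- ergotropy ⟨½|v|²⟩ [pixel²/s²] — mean kinetic energy of the motion.

**Sarcomere texture (SOTA scores)** on α-actinin ROI images:

- Fourier score — share of non-DC spectral power in the dominant peak pair
  of the 2-D power spectrum (repetitiveness, in [0, 1]);
- Gabor score — maximum mean response over an oriented band-pass filter
  bank (Z-band edge strength);
- Haralick correlation — Σᵢⱼ (i−µ)(j−µ) p(i,j) / σ² of the gray-level
  co-occurrence matrix at offset 1 px (organization, in [−1, 1]);
- sarcomere length (Z-band spacing, µm) and width (Z-band segment extent
  along the line, µm), gated by a periodicity floor.

**Cell-shape morphometry** from binary masks: area, perimeter (Crofton
estimator), eccentricity √(1−(b/a)²), circularity 4πA/P², elongation a/b —
anchored so a digitized circle scores 0 / 1 / 1.

**Corrected total fluorescence (CTF)** of EB core Z-stacks:
CTF = IntDen(SUM projection, signal ROI) − n·mean(background IntDen),
with IntDen the sum of intensities over pixels inside an ROI polygon and n
the slice count.

**Statistics**: one-way ANOVA (α = 0.05) + post hoc LSD (mean differences
with 95% CIs, unadjusted), fold changes, and reference-normalized protein
ratio tables.

A `synthetic` module generates every input with analytic ground truth
(striation textures with a disorganization knob, beating-marker
trajectories, Z-stacks, elliptical masks), and a `pipeline` module runs a
whole simulated experiment — arms × assays → measurement and comparison
tables with a reproducibility manifest.

## Worked example

```python
from cardiophen import (BeatSpec, StriationSpec, TextureROI,
                        make_beat_trajectories, make_striation_image,
                        score_roi, summarize_kinematics)

# a 1.5 Hz beating recording, 12 markers, 30 fps, 10 s
traj, truth = make_beat_trajectories(BeatSpec(beat_frequency=1.5, seed=42))
s = summarize_kinematics(traj)

# an organized striation ROI and its fully scrambled counterpart
organized, _ = make_striation_image(StriationSpec(seed=0, noise_sd=0.05))
scrambled, _ = make_striation_image(
    StriationSpec(seed=0, noise_sd=0.05, disorganization=1.0))
```

prints (via `score_roi` / the summary fields):

```
chronotropy          1.500 Hz   (true 1.5 Hz)
kinematic inotropy   18.541 px/s (true 18.850)
dynamic inotropy     171.88 px/s^2 (true 177.65)
ergotropy            85.890 px^2/s^2 (true 88.826)
organized: fourier 0.838  gabor 0.635  haralick 0.782  length 1.001 um
scrambled: fourier 0.005  gabor 0.092  haralick 0.003  length absent
```

The recovered beat frequency is exact; speed/acceleration/energy sit
within ~1.5–3% of the closed forms (finite-difference attenuation at
30 fps, see `docs/methods.md`). All three texture scores collapse for the
scrambled ROI and its sarcomere length is flagged absent rather than
invented — the behavior the group comparisons rely on.

The same stages are scriptable from the shell:

```bash
cardiophen simulate striation --out demo --seed 1
cardiophen kinematics --traj traj.csv --out summary.csv
cardiophen sota --manifest rois.csv --out scores.csv
cardiophen ctf --stack stack.tiff --rois rois.json --out ctf.csv
cardiophen run --config experiment.yaml --out bundle/
```

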