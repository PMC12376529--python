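# nucleomech

Nuclear-envelope mechanics and quantification: a simulation and analysis
pipeline for progerin-driven nuclear wrinkling.

In Hutchinson–Gilford progeria syndrome (HGPS), the mutant lamin protein
progerin accumulates at the nuclear envelope, lowers envelope tension,
and lets cytoskeletal pressure wrinkle the nucleus — first into a
faceted "buckyball" pattern, then into a deeply folded labyrinth.  This
package implements the computational side of that story for researchers
in nuclear mechanobiology:

* **Shell simulator** (`shell_mesh`, `shell_model`): the nuclear
  envelope as a closed icosphere (level 4: F = 5120 faces, V = 2562
  vertices, E = 7680 edges) evolving by an overdamped gradient flow
  `eta dr_i/dt = −∇_i U + F_i^rep + P_i^ext` with stretching
  `Σ Ke/2 (l−l0)²`, bending `Σ Kb/2 |n̂₁−n̂₂|²`, and contents elasticity
  `Σ KV/2 (V_f−V0)²`, plus 6–12 vertex repulsion and a uniform external
  pressure `−P ∇_i V` standing in for cytoskeletal load (P = 500 / 600 /
  750 P0 on soft / medium / stiff substrates).
* **Morphodynamics** (`morphodynamics`): ΔV/V0 and membrane-tension
  series, spherical-harmonic stage classification
  (smooth → buckyball → labyrinth) and buckling event times.
* **Image quantification** (`nucleus_quant`): NE wrinkling % (the
  above-mean-intensity area fraction of the nucleus), hollow-ring FRET
  ratios `(acceptor − bg)/(donor − bg)` for the nesprin tension sensor,
  and nuclear morphometry (area, circularity `4πA/P²`, aspect ratio).
* **Chromatin dynamics** (`chromatin_msd`): time-averaged MSD of
  telomere tracks and motion-regime classification
  (`MSD = 4 D_app τ^α`).
* **Kinetics** (`kinetics`): min–max normalization and Richards-sigmoid
  fitting of expression/wrinkling time courses, with inflection-time
  intervals.
* **Synthetic data** (`synthetic_data`): seeded generators with exact
  ground truth for every analysis stage, so the pipeline is fully
  testable without microscopy data.

## Worked example

```python
import numpy as np
from nucleomech import synthetic_data as sd, nucleus_quant as nq, kinetics as kin
from nucleomech import chromatin_msd as cm

# wrinkled nucleus image -> segmentation -> wrinkling % and morphometry
img, mask, frac = sd.gen_wrinkled_nucleus_image(seed=7, wrinkle_fraction=0.3, noise_sd=0.02)
seg = nq.segment_nucleus(img)
print(nq.ne_wrinkling_percent(img, seg))          # 30.0  (planted 30 %)
print(nq.nuclear_morphometry(seg.mask))           # area 15702 px, circ 0.834, aspect 2.00

# FRET tension-sensor ring
acc, don, ring, _ = sd.gen_fret_pair(seed=7, true_ratio=1.5, noise_frac=0.02)
print(nq.fret_ratio_map(acc, don, ring, 100.0, 100.0)[1])   # 1.503

# expression vs wrinkling kinetics
expr, _  = sd.gen_sigmoid_timecourse(seed=7, t_infl=20.0, rate=0.5, noise_sd=0.03)
wrink, _ = sd.gen_sigmoid_timecourse(seed=8, t_infl=25.0, rate=0.4, noise_sd=0.03)
fa = kin.fit_sigmoid(kin.minmax_normalize(expr))
fb = kin.fit_sigmoid(kin.minmax_normalize(wrink))
print(fa.t_infl, fb.t_infl, kin.inflection_interval(fa, fb))  # 20.0 h, 24.9 h, 5.0 h

# confined chromatin motion
tracks, truth = sd.gen_tracks(seed=7, model="confined_ou", sigma=0.1, theta=0.2,
                              n_tracks=20, n_frames=2000)
curve = cm.ensemble_msd(tracks)
alpha, D, plateau, regime = cm.fit_motion_model(
    curve, fit_lags=np.arange(len(curve.lags)//2, len(curve.lags)))
print(plateau, regime)                            # 0.0400 (= 4 sigma^2), 'confined'
```

The numbers in the comments are this script's actual output: the
wrinkling estimator returns the planted fraction exactly, the FRET mean
recovers the constructed ratio within noise, the inflection interval
between expression (20 h) and wrinkling (25 h) comes out at 5.0 h, and
the Ornstein–Uhlenbeck tracks plateau at 4σ² = 0.04 and classify as
confined motion.

A pressurized shell run takes a few lines:

```python
from nucleomech import shell_model as sm, morphodynamics as md

shell = sm.relax_shell(sm.reference_shell(4))
params = sm.preset_parameters("stiff", seed=1, t_max=0.05, dt=2e-5)
traj = sm.simulate(shell, params, sample_stride=1)
series = md.morpho_series(traj, shell, params)
print(series.t_first, series.t_second, series.t_breakdown)
# 0.002 0.00374 0.00422  (wrinkling onset, late collapse bend, membrane contact)
```

A command-line interface mirrors the library:
`nucleomech mesh --level 4 --out shell.vtk`,
`nucleomech simulate --preset stiff --seed 1 --out run.npz`,
`nucleomech observe run.npz --out morpho.csv`,
`nucleomech wrinkling img.tif`, `nucleomech msd tracks.csv`,
`nucleomech kinetics fit curve.csv`, `nucleomech synth tracks --out data/`.

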