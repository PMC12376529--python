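# Methods

## The mechanical model

The nuclear envelope is a closed elastic shell discretized as a
subdivided icosahedron ("icosphere"): at subdivision level 4 it has
F = 5120 triangular faces, V = 2562 vertices and E = 7680 edges, with
Euler's relation V − E + F = 2 at every level.  Vertices move by an
overdamped (inertia-free, zero-temperature) equation

    eta dr_i/dt = −∇_i U + F_i^rep + P_i^ext,

with the shape energy

    U = Σ_edges Ke/2 (l − l0)²                  (stretching)
      + Σ_edges Kb/2 |n̂₁ − n̂₂|²               (bending)
      + Σ_faces KV/2 (V_f − V0)²                (contents / volume)

a short-range 6–12 vertex–vertex repulsion F_i^rep acting below a
threshold distance D, and a uniform external pressure contributing
−P ∇_i V.  The external pressure is the coarse-grained cytoskeletal
load transmitted through the LINC complexes; stiffer substrates mean a
larger P, and the three study conditions are P = 500, 600 and 750 P0 for
soft, medium and stiff substrates.  Defaults: Ke = 1000, Kb = 4, KV = 3,
Kr = 1e-13, eta = 1, D = 0.9, dt = 0.005 (reporting step).

Two definitions deserve care:

* **Per-face volumes** V_f are signed tetrahedron volumes taken against
  the *instantaneous centroid*.  Referenced to a fixed external point the
  per-face volume energy is not translation invariant (its net force on
  the mesh is ~0.1 in simulation units for a perturbed level-2 shell);
  the centroid reference restores exact invariance, and the analytic
  gradient carries the corresponding centroid chain term.  The total
  volume Σ_f V_f — and hence the pressure force — is independent of the
  reference point either way.
* **Shared rest quantities.**  All edges share one rest length l0 (the
  mean initial edge length) and all faces one rest volume V0.  An
  icosphere is not equilateral (edge dispersion ≈ 6.5 %), so the as-built
  sphere carries a small prestress and is *not* an equilibrium.
  `relax_shell` settles the mesh into the zero-pressure minimum of U
  (L-BFGS, residual forces ~1e-6); simulations start from this relaxed
  state, which is a genuine fixed point of the unpressurized dynamics.

### Units and normalization

The model fixes no absolute length, force or time scale; P0 = F0 = t0 = 1.
The package normalizes the mesh to unit mean edge length
(`reference_shell`).  This is the scale on which the repulsion law is
meaningful — its 6–12 crossover sits exactly at the rest spacing and the
cutoff D = 0.9 engages only below it — and the scale on which the preset
pressures drive genuine membrane buckling.

No normalization reproduces the source model's printed chronology
(transitions at t/t0 ≈ 45–105): membrane elasticity can resist the preset
pressures only for radii R ≲ 2 rest edges, contents elasticity only for
R ≳ 85, and for *any* radius the damping eta = 1 sets a collapse time
eta·N/(4π·P·R) of order 1e-3–1e-2 t0.  At the reference normalization the
full chronology — smooth sphere, faceted buckling, tension-magnitude peak,
accelerated-then-arrested volume collapse, membrane self-contact — plays
out between t ≈ 0.002 and t ≈ 0.006, in the published *order* for the
three presets but not with the published times or their ratios.  The
acceptance script reports the measured times without rescaling.

### Integration

The flow is integrated by forward Euler with an adaptive substep inside
each reporting step dt: a trial substep is accepted only if the Lyapunov
functional L = U + U_rep + P·(V − V_ref) does not increase (within a
1e-12 relative roundoff slack), halving on rejection and growing 1.2× on
acceptance up to dt.  A fixed substep cannot integrate this system — the
in-plane spring stiffness (~3·Ke) makes the printed dt unconditionally
unstable, and the stable step varies by orders of magnitude along a run
(~1e-7 during the collapse).  Monotonicity of L along the trajectory is
therefore a construction, not an accident, and is what the gradient-flow
sanity test checks.  Runs are bit-reproducible for a given seed.

Repulsion pairs come from a Verlet list (uniform spatial grid, skin
0.5·cutoff) rebuilt when accumulated displacement could invalidate it;
the same list yields the minimum non-bonded distance, and a run
terminates (breakdown flag, mirroring membrane self-contact) when that
distance falls below `contact_distance` (default 0.1·l0).  Pairs closer
than 1e-9 raise a hard-core error.  Degenerate geometry (zero-length
edges, zero-area faces) raises explicit errors in the reference NumPy
terms; inside the kernels it surfaces as non-finite trial energies,
which the step control rejects.

### Symmetry breaking and initial conditions

The deterministic equation cannot buckle from an exactly symmetric
state, so runs start from a seeded Gaussian radial perturbation of sd
1e-3·l0 per vertex (`perturbation_amplitude`).  In practice the
icosahedral prestress of the discrete mesh is a stronger symmetry
breaker than the noise: buckling chronologies differ only marginally
across seeds.

## Morphodynamics observables

* **ΔV/V0**: relative enclosed volume change per sample (signed
  tetrahedron sum; first sample exactly 0).
* **F_memb/F0**: mean edge spring force ⟨Ke (l − l0)⟩/F0, the only
  tension proxy fully determined by stated model quantities.  Under
  external crushing it is compressive (negative); the rise-to-peak
  tension curve of the source phenomenology corresponds to its
  *magnitude*, which is what the tension-peak times quote.
* **Stage classification**: the radial deviation from the reference
  (rest) radius profile, uniform component removed, is projected onto
  real spherical harmonics (least squares at the reference vertex
  directions, band limit ℓ ≤ 30, capped at √V − 2 on coarse meshes).
  *Smooth*: rms deviation < 1 % of the mean radius.  *Buckyball*: one
  degree ℓ ∈ [2, 10] carries ≥ 50 % of the ℓ ≥ 2 power.  *Labyrinth*:
  otherwise.  Deviations are measured against the rest shape rather than
  a perfect sphere because the relaxed discrete shell is itself slightly
  faceted (rms 4 % of R), which would otherwise saturate the detector at
  t = 0.
* **Event times**: t_first is the first sample leaving *smooth*.
  t_second is the last prominent bend of the volume curve at or after
  t_first — the final local maximum of the Savitzky–Golay-smoothed
  (window 11, quadratic) second-derivative magnitude that exceeds a
  scale-free floor of 0.2·max|ΔV/V0|/span².  The magnitude convention
  covers both an accelerating collapse (negative curvature) and its
  arrest (positive curvature); in the realizable regime the late event
  is the arrest.  A strictly linear decline returns None.  The detector
  commutes with uniform time rescaling.  Resolving the late bend
  requires sampling at least ~200 points across the collapse; the
  chronology runs sample at dt = 2e-5.

## Image quantifications

* **NE wrinkling %**: fraction of nucleus pixels *strictly* brighter
  than the nuclear mean intensity, ×100.  Ties count as non-wrinkled, so
  uniform nuclei give exactly 0 %.  Affine-invariant in intensity.
* **Segmentation**: global threshold, largest connected component,
  holes filled.  Default threshold is the triangle method: on
  fluorescence frames whose histogram is dominated by dark background it
  finds the background/nucleus boundary, whereas Otsu's two-class
  criterion can split nucleus-vs-wrinkle instead (measured Jaccard 0.13
  vs 1.00 on the synthetic wrinkled nucleus).  Otsu and fixed thresholds
  remain selectable.
* **Ring (hollow) masks** are the nucleus mask minus its erosion by a
  configurable thickness (default 3 px) — a reproducible stand-in for
  hand-drawn polygonal hollow masks.
* **FRET ratio**: pixelwise (acceptor − bg_A)/(donor − bg_D) over the
  ring; pixels whose background-subtracted donor signal is non-positive
  are excluded, and the measurement is rejected when more than 10 % of
  the ring is excluded.
* **Morphometry**: area = pixel count (× pixel_size²); circularity
  4πA/P² with the perimeter measured as the marching-squares boundary
  contour length after a 5-point circular moving average (raw contours
  overestimate curved boundaries ~5 %; the smoothing leaves straight
  edges essentially untouched: disk 0.993, square 0.805 vs π/4 = 0.785);
  aspect ratio from the second-moment ellipse axes.

## Chromatin MSD

Time-averaged MSD with overlapping windows, lags up to 1/4 (configurable
≤ 1/2) of the track length; ensembles are per-lag means weighted by pair
counts (configurable to uniform) with standard errors across tracks.
Motion regime from the log–log slope α of MSD = 4 D_app τ^α: confined
(α < 0.3 with a plateau, plateau = median of the top-lag quartile when
its local slope < 0.1), subdiffusive (< 0.8), diffusive (≤ 1.2),
superdiffusive.  The thresholds are conventions, stated here because the
source describes regimes only qualitatively.

## Sigmoidal kinetics

Time courses are min–max normalized and fitted with the Richards
(generalized logistic) family
y = lower + (upper − lower)/(1 + e^{−rate (t − t_c)})^{1/ν}, whose
inflection time is t_infl = t_c − ln(ν)/rate (ν = 1 is the plain
logistic).  Fitting is trust-region least squares from a deterministic
multistart grid: t_c at the observed-time quartiles × ν ∈ {0.5, 1, 2},
rate initialized from the steepest finite-difference slope; best RSS
wins.  Decreasing series are rejected (fit the reversed series
deliberately if that is intended).

## Synthetic data

Generators are pure functions of (seed, parameters) with per-kind
random streams, and return machine-readable ground truth:

* wrinkled nuclei: 2:1 ellipse, bright filamentous texture (the
  near-zero set of a smoothed Gaussian field) covering an exactly known
  pixel fraction at a set contrast; additive Gaussian noise optional;
* FRET pairs: ring-localized donor plus constructed acceptor
  bg_A + ratio·(donor − bg_D);
* tracks: Brownian (cumulative Gaussian), confined Ornstein–Uhlenbeck
  (exact discretization; long-lag plateau 4σ²) and ballistic, at the
  0.07 s / 5 min live-imaging cadence;
* sigmoid time courses on the 20-min / 36-h grid.

They emulate statistical structure only — no point-spread function, shot
noise or camera artifacts — so recovery tests validate the estimators,
not robustness to real microscopy imperfections.

## Problem sizes used by tests and the acceptance script

Chronology runs use the level-4 mesh (2562 vertices), three seeds per
pressure preset, sampling dt = 2e-5 up to t_max = 0.05 (every preset
reaches membrane contact by t ≈ 0.006); the volume-modulus sweep
compares KV ∈ {1, 3, 9} at fixed t = 0.003.  Force-gradient checks use
level-2 meshes.  Estimator-recovery suites use 20–200 replicates per
claim.  The full test suite and the acceptance script each run in a few
minutes on one CPU, dominated by kernel compilation on first use.

## Known limitations

* The absolute time scale (and the preset-to-preset time ratios) of the
  published chronology are not reproducible from the printed model; see
  *Units and normalization*.  Ordering across presets is.
* No thermal noise, hydrodynamics, explicit chromatin, or discrete
  cytoskeletal elements; the environment enters only through the scalar
  pressure.
* The shell cannot remesh; after deep folding the simulation ends at
  membrane contact rather than resolving self-intersecting geometry.
* Image quantifications are strictly 2-D, single-channel, no sub-pixel
  interpolation.
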