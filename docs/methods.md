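# Methods

This note records the quantitative conventions the package implements,
the calibration choices behind the default configurations, and known
limitations. All defaults are desk-scale: every analysis runs in minutes
on one CPU from seeded synthetic data.

## Coordinate and data conventions

- Positions are micrometres, times minutes, volumes µm³. Image arrays
  are indexed `(t, y, x)` (z-stacks `(z, y, x)`); point coordinates are
  `(x, y)` with `x = column·pixel_size`, `y = row·pixel_size`.
- A `Track` is a strictly time-increasing sequence of 2D (optionally 3D)
  positions. A `TrackSet` carries the shared frame interval.
- Outline stacks store one closed, non-self-intersecting polygon per
  z-plane. Mask series are boolean `(t, y, x)` arrays with per-frame
  times.

## Trajectory statistics

- **MSD** is the time-averaged mean-squared displacement using all
  overlapping pairs per track, averaged unweighted across tracks, on a
  shared uniform frame interval. The power law `MSD = 4·D_eff·τ^α` is
  fitted by ordinary least squares in log-log space; `α = 1` is
  diffusive, `α = 2` ballistic. Fits default to the early lag window
  (`max_lag_fraction`) where time-averaged MSD is statistically solid.
- **Straightness** is net displacement over summed path length.
- **Discrete Fréchet distance** uses the standard dynamic program over
  monotone couplings. The permutation null keeps the partner track's
  start point and step magnitudes but redraws step directions uniformly;
  the empirical p-value is `(1 + #{null ≤ observed})/(n_perm + 1)`.
- **Convergence point**: each displacement vector defines a forward ray;
  all pairwise ray intersections (pairs meeting at less than 10° are
  skipped as numerically parallel, intersections must lie forward along
  both rays and inside the tissue outline) are averaged to a centroid.
- **Normalised polar coordinates**: a point is reported as a signed
  angle (degrees) from the rostral axis about the tissue origin and a
  radius divided by the origin-to-outline distance along the same
  direction, making differently sized animals comparable.

## Closure kinetics

The closure model is the underdamped, unit-mass damped harmonic
oscillator `x(t) = a·e^(−νt/2)·cos(√(k−ν²/4)·t − φ)` plus a constant
offset. Fitting uses multi-start nonlinear least squares (12 phase
starts), log-parametrised `ν` and `ω` for positivity, and canonicalises
`(a, φ)` to `φ ∈ (−π/2, π/2]`. On noiseless model curves the fit
recovers parameters to 1e-6 relative; at 1%-amplitude noise the mean of
100 fits recovers `a, ν, k` within 5%.

ROI closure curves are mean intensity inside a polygonal ROI over time,
normalised between the first and a reference (default last) time point.

## Morphometry

- **Injury volume**: shoelace polygon area per plane × z-step. A
  256-vertex discretised sphere reconstructs to within 3% of `4πr³/3`.
- **Repair index** `RI = 1 − V_late/V_early`; `RI > 0.5` classifies a
  closed wound; `RI < 0` is enlargement.
- **Area turnover**: per-interval gained/lost areas from mask set
  differences; `gained − lost` equals the total area change exactly.
- **Edge recoil**: distance from the ablation centre to the nearest mask
  edge per frame; recoil speed is the linear slope over a window. The
  synthetic recoil fixture produces a first-interval area change more
  than 10× any later interval.

## Agent-based model

Overdamped mechanics: each agent moves at `V_i = (1/η)·(ΣF_pair + F_loc)`.
Contact forces use PhysiCell-style polynomial potentials
`(1 − d/R)²` up to contact distance `R` (repulsion) and `1.25·R`
(adhesion), with geometric-mean combination of per-kind coefficients.
Any pair containing a microglia additionally feels a Hooke attraction
`k_e·(r_j − r_i)` — the hypothesised traction transmitted through the
astrocytic process meshwork. Locomotion is a persistent random walk
(per-kind speed and persistence time). Skin agents form an immobile
outer wall. Forward Euler integration; a single seeded RNG stream per
run makes repeated runs byte-identical.

Published parameters (persistence 10/10/0 min, speeds 0.01/1/0 µm/min,
repulsion 5/5/5, adhesion 0.1/0/0, `k_e = 5e-7`/min) are the
`MechanicsParams` defaults. Two calibration knobs differ in the default
*closure configuration* and are deliberate choices:

- **Elastic gain** `k_e = 2e-5`/min: at desk scale (a few hundred
  agents, ~200 µm tissue) the published per-pair coefficient moves
  agents by much less than a micrometre per simulated day; the elastic
  term is the declared calibration knob and is raised until closure
  completes within 24 simulated hours.
- **Initial lattice slack** (`pack_margin = 1.08`): neurons start on a
  hexagonal lattice packed just out of contact. Contact-packed or
  jittered lattices carry repulsion pressure that relaxes into the wound
  and masquerades as repair.

The wound readout mirrors the experimental intensity measurement: a
Gaussian density image of neuron positions; the repair analogue is
`1 − empty_end/empty_start` where a wound pixel is "empty" below half
the surrounding deep-layer median density.

With these defaults, zero-microglia runs give repair analogue ≤ 0.05
(the wound does not close; seeds 0–2 give −0.04 to −0.03), and mean
repair rises monotonically with microglia count before plateauing
(isotonic fit R² = 1.0 over counts 0/4/8/16/32 × 3 replicates).

### Model limitations

- **Geometric capacity**: the desk-scale neuropil (~2500 µm²) hosts at
  most ~32 microglia agents of radius 5 µm at the initial patch density.
  Beyond that (e.g. 64) the initial patch is over-compressed; the
  repulsion transient scatters microglia into the wound where they block
  the neuron-density readout, and mean repair dips (0.75 at count 64 vs
  0.99 at 16–32). Default sweeps therefore stop at the capacity.
- **Closure-curve shape**: with a few hundred discrete agents the
  per-snapshot wound density is jagged (single arrivals move it by
  percent), so the smooth damped-oscillator shape is not recovered from
  one run (best fit r² ≈ 0.8); it would require ensemble averaging
  beyond the desk-scale budget.
- Forward Euler: two-body elastic decay matches `r₀e^(−2k_e t/η)` to
  1e-4 relative at `dt = 0.005` min; truncation error grows linearly in
  `dt`.

## Synthetic data

The model tectum is a half-ellipse with a deep cell-body band (where
neurons sit) and an inner neuropil; an injury disc sits in the band.
Track generators: `jitter` (pure random walk with `noise_sigma` as the
per-step σ — zero noise is stationary), `random_walk`, `ballistic`, and
`directed_oscillator` (radial approach to a convergence point following
the oscillator time course, with `noise_sigma` as additive measurement
noise). Wound-series generators produce outline stacks with exact target
volumes; ablation generators produce recoil/static/drift mask series.
All generators take a seed and are deterministic given it.

## Acceptance

`tests/test_acceptance.py` freezes one test per release criterion;
`scripts/acceptance.py --seed N --out results.json` recomputes the
headline quantities (worked-example percentage, oscillator recovery
error, MSD exponents, Fréchet DP-vs-brute-force difference, convergence
error, simulator decay/zero-microglia/sweep numbers, morphometry
solids) with all randomness derived from the given seed.
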