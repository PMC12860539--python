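# Methods

## The problem

Transperineal prostate biopsy pushes a long, thin bevel-tipped needle
60–120 mm through layered soft tissue. The asymmetric reaction on the bevel
face deflects the needle away from the straight template path, and the
deflection depends on tissue elastic moduli that cannot be measured in a
patient. `needleflex` implements the three layers of a planning tool for
this problem: a mechanics-based insertion simulator, fast learned surrogates
of that simulator, and a Monte Carlo engine that converts tissue-stiffness
priors into needle-shape confidence bands.

## Mechanics-based insertion model

The needle is a planar Euler–Bernoulli beam: an 18-gauge nitinol tube
(length 140 mm, outer/inner diameter 1.27/0.838 mm, E = 35 000 MPa, bevel
angle α = 30°), discretised into 47 cubic Hermite elements (48 nodes, two
DOF per node: transverse deflection w in mm and rotation θ in rad). Units
are mm / N / MPa throughout.

Tissue is described per millimetre of depth by an elastic modulus profile
C(1..125) (MPa). The insertion advances 1 mm per quasi-static step. At the
step reaching depth n:

1. **Spring attachment.** The tissue just traversed is attached as a linear
   spring at the first node strictly proximal to the tip, with stiffness
   k = C(n) · t_ref and rest deflection z0 equal to that node's current
   deflection, so the spring is force-free at the moment of attachment and
   thereafter holds the needle to the channel it has cut. t_ref is the
   tributary depth each spring represents; the default is 1 mm (one spring
   per millimetre of advance), making k in N/mm numerically equal to C in
   MPa. This conversion constant is exposed in the module
   (`SPRING_TRIBUTARY_MM`) because the magnitude of all predicted
   deflections scales with it; see *Limitations*.
2. **Tip load.** The bevel wedge compresses the tissue ahead of it, giving a
   cutting force F_c = C_tip d² / (4 tan(α/2)) and a transverse component
   F_cz = F_c cos(α + θ_tip). The tip slope θ_tip is taken from the
   previous step's solution (zero at first contact); an optional
   fixed-point iteration (`tip_slope_fixed_point=True`, tolerance 1e-8)
   makes it self-consistent instead. The slope enters in the bevel frame,
   so flipping the bevel direction yields the exact mirror solution.
3. **Static solve.** (K_beam + K_springs) u = F_tip + Σ k·z0, solved dense
   (the system is at most 96 DOF). The template-guided region — every node
   within 140 − n mm of the base — is pinned to w = 0, with rotation fixed
   at the base node only.
4. **Spring shift.** After each accumulated element length (140/47 ≈
   2.979 mm) of advance — i.e. after every third 1-mm step — every spring
   moves one node toward the base so the tissue stays fixed in space while
   the needle advances through it. The rest deflection is remapped
   (z0' = w_new + z0 − w_old) so each spring's force is unchanged at the
   moment of the move; the test suite asserts continuity to 1e-12 N.

Consequences the suite verifies: zero-stiffness tissue gives identically
zero deflection; out-of-tissue nodes are exactly zero at every state; the
solution is linear in the loads; and every trajectory matches an
independently written step-ledger implementation (quadrature-derived element
matrices, Lagrange-multiplier constraint handling) to 1e-8 mm.

## Supervised dataset

A random anatomy has 1–10 layers (uniform); layer transition depths are
drawn uniformly without replacement from the interior integer depths and
sorted; each layer modulus is uniform on [0, 0.2] MPa. Each anatomy is
simulated to 125 mm and encoded as one sample per depth 1..124: input
x ∈ R¹²⁶ (125 per-mm moduli + depth in mm), target y ∈ R⁴⁸ (nodal
deflections, mm). Train/validation splits are by trajectory, never by
depth-state, so no anatomy leaks across the split.

The default study size in this package is 1000 training / 2000 validation
trajectories (124 000 / 248 000 samples) — large enough that the linear
baseline is well inside its asymptotic regime while a full
generate-train-evaluate cycle stays in the minutes range on one CPU core.
A 10 000 / 40 000 "full" profile is reachable through the same
`generate_dataset` call for users with hours of compute.

## Surrogate models

* **OLS** — least squares on z-scored inputs and outputs; rank-deficient
  designs (e.g. few distinct anatomies) fall back to the minimum-norm
  solution with a warning.
* **MLP** — two hidden layers of 48 ReLU units, z-scored on both sides,
  Adam with library defaults (the reference MLP implementation's defaults
  are part of the protocol).
* **FFNN** — the same network body fed with random Fourier features
  x_map = [sin(2π x Bᵀ), cos(2π x Bᵀ)], B ∈ R¹²⁶ˣ¹²⁶ with entries
  N(0,1) · s, drawn once per model from its own seed and frozen. The
  sinusoids bound every network input to [−1, 1], so raw inputs are *not*
  z-scored; outputs are. Trained full-batch with Adam for exactly 500
  epochs (defaults: learning rate 0.005, scale s = 0.2; a grid-search
  helper scans learning rate log-spaced in [1e-5, 1e-2] and s linear in
  [0.01, 1]). Fourier features counter the spectral bias that otherwise
  limits an MLP on inputs whose relevant scales span a factor of ~200
  (moduli 0.001–0.2 MPa against depths 1–125 mm).

Standardization is exact-inverse by construction; a zero-variance output
dimension is restored to its constant value by the inverse transform rather
than left to the regressor. Fitted weights are extracted into plain arrays,
so prediction is a handful of matmuls, serialization is a named-array
container plus JSON sidecar, and a reloaded model reproduces predictions
bit-for-bit. A parity test checks the extracted forward pass against the
fitting library's own predictions.

Evaluation reports, at a queried depth (65 mm by default — a typical
transperineal insertion depth), the signed per-node errors, per-insertion
MAE over all 48 nodes, its aggregate, and a tip-only MAE; both all-node and
tip-only scopes are first-class because both are meaningful clinically (the
tip is where the sample is taken). Absolute-error histograms along the
needle use 0.01-mm bins with optional count clipping.

## Uncertainty quantification

Each layer of a fixed anatomy gets an independent truncated-normal prior
TruncNormal(μ, σ, lower = 0) — the truncation keeps sampled moduli
physical. `run_uq` draws n property vectors (default n = 2000, enough that
the 2.5/97.5 empirical percentiles are not dominated by sample extremes),
expands each into a profile, batch-predicts all needle shapes with the
surrogate in one call, and summarises per-node empirical quantile bands
(default level 95%). Direct sampling is the default since the priors are
independent; a random-walk Metropolis chain sampler with the same call
signature is provided as the extension point for dependent priors, and any
callable with that signature can be plugged in. Degenerate priors (σ = 0)
collapse the band to exactly zero width; band nesting in the level and
seeded reproducibility are asserted by tests.

Thin-layer experiments place a stiff, high-uncertainty layer
(μ = 0.1, σ = 0.05 MPa) at varying depths inside a soft, certain background
(μ = 0.005 or 0.05, σ = 0.0005 MPa), mirroring the package's two-tissue
example configurations; the suite asserts the qualitative orderings of
final-tip band width across layer positions over several sampling seeds.

## Numerical choices

* Dense `numpy.linalg.solve` on the constrained system; an explicit
  structural mechanism check (no transverse support, or a single support
  with free base rotation) raises a named error instead of returning
  garbage from a numerically singular factorisation.
* Element length is exactly 140/47 mm; the spring-shift trigger fires when
  accumulated advance reaches one element length, i.e. every third 1-mm
  step.
* Depth indexing: `modulus_per_mm[i]` governs the interval (i, i+1] mm, so
  the modulus at integer depth d is entry d−1.
* Angles: the bevel angle is stored in degrees as specified and converted
  to radians at use; tip slope is the FEA rotation DOF (rad).
* Transition depths are drawn on the integer millimetre grid (the model's
  native resolution), without replacement.
* Seeds: all stochastic components (anatomy sampling, network
  initialisation, Fourier map, prior sampling) take explicit integer seeds;
  derived child seeds come from `numpy.random.SeedSequence`.

## What the synthetic generator does and does not emulate

The generator reproduces the study conditions of the simulator experiments:
piecewise-homogeneous, isotropic, linear-elastic layers with moduli in
[0, 0.2] MPa, 1–10 layers, planar deflection of a template-guided needle.
It does not emulate friction along the shaft, viscoelastic or hyperelastic
tissue response, anisotropy (muscle), needle rotation or base steering,
3-D deflection, or within-layer heterogeneity. Surrogates trained and
validated here are therefore validated *against the mechanics model*, not
against tissue: passing tests show the learned map reproduces the simulator
under the stated sampling scheme, and says nothing about fidelity to a real
insertion beyond what the mechanics model itself captures.

## Known limitations

* **Spring-conversion scale.** The mapping from tissue modulus to spring
  stiffness (t_ref) sets the absolute magnitude of every predicted
  deflection; with the default t_ref = 1 mm the simulated tissue support is
  comparatively stiff and deflections at 65 mm depth are a few tenths of a
  millimetre. Published experiments with comparable needles report
  millimetre-scale deflections, so quantitative use against real data
  requires calibrating t_ref (or equivalently the modulus profile) to
  measured needle shapes, as done when fitting phantom data.
* The explicit tip-slope update lags the force by one step; the provided
  fixed-point option changes tip deflections by at most a few percent at
  these slopes.
* The MLP's optimizer defaults include tolerance-based early stopping, so
  its effective epoch count varies with the dataset; the FFNN protocol
  fixes 500 full-batch epochs. With small training sets the advantage of
  the Fourier embedding over the plain MLP is within seed-to-seed noise;
  the ordering between the two is therefore not guaranteed at reduced
  scale.
* Posterior inference (conditioning on an observed partial needle shape) is
  out of scope; the UQ engine propagates priors forward only.
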