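# Methods

## Signal model

A multi-slice multi-echo (MSME) acquisition samples the transverse
magnetization decay of every pixel at t = k·TE, k = 1..NE. Each decay is
modeled as a finite mixture of exponentials on a constant baseline,

    f(t) = y0 + Σ_{i=1..n} A_i · exp(−t / T2_i),   n ∈ {1, 2, 3},

with A_i ≥ 0 (magnitude signal), T2_i > 0, and y0 ≥ 0. Components map to
proton pools: in the dressing, loosely bound water (short T2, high
amplitude) and propylene glycol (long T2, low amplitude); in a PG-wetted
sponge, PG in small pores (~100 ms) and large pores (~400 ms); an
"intermediate" (~50 ms) pool appears where media mix near the contact
plane. The default grid — TE = 3.644 ms, NE = 256, 256×256 matrix,
24×24 mm² FOV (pixel 24/256 = 0.09375 mm, displayed as 0.094) — spans
3.6–933 ms and conditions which T2 mixtures are identifiable: round-trip
recovery to ≤0.1% holds for noiseless mixtures whose T2s are separated
by at least a factor ~3 and whose amplitudes are not buried in noise.

## Fitting and model-order selection

`fit_decay` solves a bounded nonlinear least-squares problem
(trust-region reflective, analytic Jacobian; bounds A ∈ [0, 10·max y],
T2 ∈ [TE/2, 10·t_max], y0 ∈ [0, max y]). Initialization peels the decay
from the tail: a log-linear fit of the late echoes estimates the slowest
component, which is subtracted before the next is estimated. Up to 5
randomized restarts (seeded, log-normal jitter) run only while the
residual exceeds a noise-based target (2·N·σ², σ from the config or a
first-difference estimate of the tail), so noiseless fits are driven to
machine precision while noisy fits stop at the statistically expected
residual. Fitted T2 pairs closer than 5% are merged (amplitudes summed,
T2 amplitude-weighted): two such components are numerically one.
Non-convergence is flagged in the fit's `flags`, never silently zeroed.

`select_model` walks n = 1 → 2 → 3 and accepts the larger model only if
(a) the nested F-test on residual sums of squares favors it at the 0.05
level and (b) every component of the larger fit exceeds an amplitude
floor of 3·σ_noise (σ from late-echo residuals unless supplied). The
floor makes "undetectable component" operational: a pool below 3σ does
not exist for the pipeline. A smaller model that already fits at
numerical precision short-circuits the walk.

Choices made where the design was open:

* y0 is fitted (not fixed at zero) but bounded below at 0, as befits
  magnitude images. At SNR 100 this bound biases the faint PG component
  of the dressing characterization (8 a.u. ≈ 4σ) downward by ~13% in
  T2; freeing y0 flips the bias to ~+50%. The faint-component T2 is
  intrinsically ill-determined at that operating point (its printed
  characterization carries a ±157 ms spread around 394 ms); the
  dominant water component is recovered with <2% bias either way.
* The selection rule (F-test + amplitude floor) is a testable stand-in
  for a goodness-of-fit threshold; R² is recorded with every fit.

## Inverse Laplace transform

`ilt_t2` expands a decay on a fixed log-uniform T2 grid (default 128
points over 1–3000 ms, bracketing all expected pools with margin) and
solves

    min_w ‖K w − y‖² + α²‖w‖²,   w ≥ 0,

with K_{kj} = exp(−t_k / T2_j) plus an unpenalized constant column for
y0, as a stacked nonnegative least-squares problem. Zeroth-order
Tikhonov with nonnegativity is the standard NMR T2 choice. Modes are
local maxima above a prominence fraction (default 5% of the peak
weight), located as weight-weighted centroids over each peak's support;
boundary maxima count (the spectrum is zero-padded before peak
picking).

`choose_alpha` implements the L-curve corner (farthest point below the
chord of the log–log residual/solution-norm curve) with generalized
cross-validation as fallback when the curve has no corner — which is
exactly what happens for noiseless data, so the noiseless limit selects
the bottom of the sweep, and pure noise selects heavy smoothing. Known
limitation: for this kernel at SNR ~100 the honest L-curve corner
(α ≈ 0.5–1) over-smooths a 100/400 ms pair into one mode, while GCV
(α ≈ 0.05–0.1) resolves both; use `method="gcv"` when mode counting
matters. Growing α lowers peak heights and raises spectral entropy
monotonically (up to ~1% NNLS jitter).

## Synthetic phantoms

The generator is phenomenological: no Bloch simulation, no transport
PDE. A scenario is a set of component rules — label, layer, T2 and
amplitude anchors in time (piecewise-linear, held outside the anchored
span) — gated by moving fronts (positions anchored in time, linearly
interpolated, monotone). Component counts change exactly at front
positions; fronts are sharp (one-pixel transition), since profile plots
show them as lines, not ramps. Pixels outside all layers carry only the
baseline offset; the reference compartment holds a single 800 ms water
pool of time-constant amplitude (250 a.u.), which the
`reference_check` operation verifies mono-exponentially across scans.

The canned scenarios encode the reported behavior of two
polyvinyl-alcohol dressings (plain, and surfactant-modified) on two
substrate media:

* Serum substrate (`M8_FBS`, `M8L_FBS`, 15–120 min every 15 min):
  dressing water T2 rising 53 → 75 → 87 ms (plain; 38 → 90 → 95 ms
  modified) with a transient zone of +45 ms toward the contact starting
  at L = 5.7 mm until profiles flatten at 60 min; the dressing PG pool
  (394 ms / 8 a.u., resp. 296 ms / 14.2 a.u.) surviving only above a
  depletion front (1.5 mm at 15 min) and vanishing entirely by 30 min;
  substrate water T2 falling 133 → 103 ms (−23%), resp. 134 → 109 ms
  (−19%).
* PG substrate (`M8_PG`, `M8L_PG`, additionally 24 h and 48 h): a third
  ~50 ms component appears in a zone around the contact plane, bounded
  by a dressing front moving toward the top (4.0/3.5/3.0 mm at
  15/60/120 min; 5.5 mm at 15 min for the modified dressing) and a
  substrate front moving deeper (7.4/8.4/9.3 mm); the plain-dressing
  system ends at a flat 13/50/250 ms triplet at 48 h, the modified one
  returns to two pools (~60/~300 ms).

Values not reported anywhere (amplitudes outside the dressing
characterization, in-zone T2 triplets at early times) were chosen once
as physically plausible and kept inside the ≥3× separation regime so
that recovery failures indicate pipeline defects, not identifiability
limits. Noise is zero-mean Gaussian on magnitudes (clipped at zero;
adequate at high SNR) or Rician for low-SNR work, seeded and
bit-reproducible; the noiseless path is bit-reproducible regardless of
seed.

What the phantom does *not* emulate — and hence what passing tests do
not show about real data: partial-volume mixing at layer boundaries,
B1/slice-profile/stimulated-echo artifacts, spatially correlated noise,
receiver drift, continuous (non-discrete) T2 distributions within a
pixel, and smooth front profiles. Recovery results on the phantom are
upper bounds on real-data performance.

## Front detection and metrics

Component-count fronts: a count change between adjacent positions that
persists for ≥3 pixels on each side; position is the midpoint between
the two pixel centers, uncertainty one pixel. Trend fronts: an exact
two-segment least-squares scan over all breakpoints of a labeled
parameter profile; a front requires the split to explain ≥50% of the
single-line residual and a slope sign change or ≥3× magnitude change.
Tracking associates detections of the same kind and layer across
consecutive time points by nearest neighbor within a 2 mm gate (larger
than the largest per-interval truth displacement, smaller than the
layer spacing). `percent_change` reports signed relative change of a
layer-averaged parameter, rounding only at presentation;
`flattening_time` is the first sampled time from which the spatial
coefficient of variation stays below 5%.

## Problem sizes and determinism

The test suite fits full 256-row, 256-echo noiseless profile series for
two scenarios (shared session fixtures), runs 50-seed Monte-Carlo model
selection at SNR 200, 100-seed bias estimation at SNR 100, and a 6-seed
noisy front-robustness check restricted to the substrate window —
sizes chosen to keep the whole suite under ~2 minutes on one CPU while
still exercising every operating point. Pipelines are byte-deterministic
for a fixed config and seed; per-time-point noise seeds are derived from
the run seed, and every CSV artifact embeds the config hash.

## Known limitations

* ROI-level ILT only; no per-pixel spectral maps, no 2D (T1–T2)
  inversion.
* No vendor raw-data readers (TIFF + sidecar only) and no k-space
  reconstruction.
* Front trajectories are reported, not fitted to transport models
  (no Fickian/Case-II exponents).
* The L-curve corner over-regularizes for this kernel at moderate SNR
  (see above).
* Scenario dynamics are interpolations of sparse reported snapshots;
  between anchors the phantom is linear in time, which real transport
  is not.
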