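# relaxstack

Spatially resolved multi-exponential T2 relaxometry of layered hydrogel
wound-dressing stacks.

When a hydrogel wound dressing is applied to a wetted substrate (serum as
a stand-in for wound exudate, or propylene glycol as an in vitro release
medium), water and propylene glycol (PG) migrate in both directions
across the contact plane. Multi-echo (MSME) magnetic resonance imaging
resolves this transport non-invasively: each pixel's echo-train decay is
a superposition of exponential components — proton pools of water and PG
in different environments — and the spatial profile of their relaxation
times and amplitudes along the stack axis *L* reveals moving fronts and
evolving layers.

`relaxstack` is a tested pipeline for this analysis, aimed at researchers
characterizing dressing materials (or similar layered soft-matter
systems) with quantitative MRI:

* **phantom_sim** — a synthetic MSME stack generator with ground truth: a
  layered phantom (dressing 0–6 mm, sponge substrate 6–12 mm, water
  reference compartment) whose 1–3 components per position evolve by
  piecewise-linear interpolation of sparse anchors and appear/disappear
  across sharp moving fronts. Canned scenarios cover a dressing on a
  serum-wetted and on a PG-wetted substrate.
* **stack_io** — multi-page TIFF + JSON sidecar I/O and reduction of a
  stack to row-averaged 1D profiles (default 10-pixel segment), plus the
  reference-compartment constancy check.
* **multiexp** — per-position fitting of

  `f(t) = y0 + Σ_{i=1..n} A_i exp(−t / T2_i)`, n = 1, 2, 3,

  by bounded nonlinear least squares with analytic Jacobian; model order
  chosen by a nested F-test plus an amplitude floor of 3·σ_noise;
  physical labeling of components by layer and T2 rank.
* **ilt** — regularized inverse Laplace transform (zeroth-order Tikhonov
  with nonnegativity, solved by stacked NNLS) producing continuous
  ln(T2) distributions, with L-curve/GCV selection of the regularization
  strength and prominence-based mode finding.
* **fronts** — component-count and trend-change front detectors,
  gated nearest-neighbor tracking into trajectories, percent-change and
  profile-flattening metrics.
* **cli** — `relaxstack simulate | extract | run | report`, a
  reproducible YAML-configured pipeline whose artifacts carry the config
  hash.

The default acquisition grid matches a 9.4 T MSME protocol: TE =
3.644 ms, 256 echoes, 256×256 matrix over a 24×24 mm² field of view
(0.094 mm pixel).

## Worked example

```python
import numpy as np
from relaxstack import *

grid = AcquisitionGrid()                  # TE 3.644 ms, 256 echoes
t = grid.echo_times_ms

# 1. Fit a dressing decay: loosely bound water + a small PG pool.
decay = 195*np.exp(-t/48.9) + 8*np.exp(-t/394)
fit = fit_decay(DecayCurve(t, decay), n=2)
for c in fit.components:
    print(f"A = {c.amplitude:6.1f} a.u.   T2 = {c.t2_ms:6.1f} ms")
print(f"y0 = {fit.y0:.2g} a.u.,  R^2 = {fit.r2:.6f}")

# 2. Full pipeline on the canned PG-substrate scenario: synthesize,
#    profile, fit, and track the moving fronts.
scenario = build_scenario("M8_PG")
profiles = [extract_profile(synthesize_stack(scenario, grid, t=tp),
                            origin_row=scenario.origin_row)
            for tp in (15, 60, 120)]
series = label_components(fit_profile_series(profiles, layers=scenario.layers),
                          substrate_medium="PG")
dets = [d for tp in (15, 60, 120) for d in detect_component_fronts(series, tp)]
for tr in track_fronts(dets):
    pos = ", ".join(f"{L:.2f} mm @ {tp:g} min" for tp, L in tr.samples)
    print(f"{tr.layer:9s} {tr.direction:19s} {pos}")
```

Output:

```
A =  195.0 a.u.   T2 =   48.9 ms
A =    8.0 a.u.   T2 =  394.0 ms
y0 = 2.5e-12 a.u.,  R^2 = 1.000000
dressing  toward_dressing_top 4.03 mm @ 15 min, 3.47 mm @ 60 min, 3.00 mm @ 120 min
substrate into_substrate      7.41 mm @ 15 min, 8.44 mm @ 60 min, 9.28 mm @ 120 min
```

The fitter recovers the two proton pools exactly (water A=195 a.u. at
48.9 ms; PG A=8 a.u. at 394 ms). On the PG-substrate scenario the
pipeline finds the third-component front retreating toward the dressing
top (4.0 → 3.0 mm) while the substrate-penetration front advances
(7.4 → 9.3 mm), each within one 0.094 mm pixel of the ground truth.

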