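# mtbond

Force spectroscopy of motor–microtubule bonds: simulation of
optical-trap force-ramp unbinding assays, rupture-event detection,
rupture-force statistics, and nonparametric reconstruction of
force-dependent unbinding rates, with zero-load dwell-time and motility
estimators.

## The problem

Cytoskeletal motors such as dynein grip their track with a bond whose
lifetime depends on the magnitude *and direction* of the load. In a
constant-pulling optical-trap assay, a bead-bound motor head is held in
a trap while the stage sweeps the microtubule past it at constant
speed, loading the bond at a nominal rate r = k_trap · v_stage
(≈ 5.6 pN/s at the emulated operating point) until it ruptures. Pooling
many rupture forces per pulling direction and condition gives a
rupture-force distribution; the question is what force-dependent
unbinding rate k(F) produced it, and whether the bond is *slip*
(k grows with F), *ideal* (k constant), or a piecewise composite
(slip–ideal / ideal–slip), differently in the two directions.

## The core transformation

Under a ramp, the rupture-force density p(F), survival S(F) and loading
rate r(F) obey the hazard identity

```
k(F) = r(F) · p(F) / S(F)
```

`mtbond` estimates p with a Gaussian kernel density (Silverman
bandwidth, reflected at F = 0), S by integrating that density, and r(F)
either as a constant, the series-spring closed form
r = v · (1/k_trap + 1/k_motor)⁻¹ (the compliance correction: the
motor–bead linkage softens the ramp), or an empirical fit of per-event
pre-detachment slopes. Curves are reported for F ≥ 0.5 pN where
S ≥ 0.05, with percentile-bootstrap 95 % bands. Supporting machinery:
1-pN normalized histograms, bootstrap CIs of the mean (4,000
resamples), two-sample Kolmogorov–Smirnov tests (p_ks), a
null-centred bootstrap difference-of-means test (p_m, floored at
1/n_boot), exponential-CDF dwell-time fits under frame quantization,
and Gaussian-velocity / exponential-run-length motility fits.

Every simulator embeds its ground truth, so each estimator in the chain
is testable against the parameters that generated its input.

## Worked example

```python
import numpy as np
from mtbond import *

bond = AnisotropicBond(
    forward=RateLaw.bell_slip(0.9, 1.0),          # slip bond under forward load
    backward=RateLaw.slip_ideal(0.5, 1.2, 2.0),   # slip-ideal under backward load
)
trap = TrapConfig(k_trap=0.025, v_stage=225.0)    # nominal 5.6 pN/s
events = simulate_events(bond, trap, MotorLinkage(), PullingProtocol(), 1000, seed=1)

for direction in ("forward", "backward"):
    f = events.select(direction=direction).forces()
    ci = bootstrap_ci_mean(f, seed=2)
    print(f"{direction:8s} mean |F| = {ci.mean:.2f} pN, "
          f"95% CI [{ci.lo:.2f}, {ci.hi:.2f}], N = {f.size}")

sub = events.select(direction="backward")
curve = bootstrap_rate_bands(sub, loading_rate_fn(sub, method="constant"),
                             n_boot=500, seed=4)
for i in range(0, curve.F.size, 10):
    print(f"F = {curve.F[i]:4.1f} pN   k = {curve.k[i]:5.2f} 1/s   "
          f"95% band [{curve.lo[i]:.2f}, {curve.hi[i]:.2f}]")
```

prints

```
forward  mean |F| = 1.66 pN, 95% CI [1.61, 1.71], N = 1000
backward mean |F| = 2.98 pN, 95% CI [2.86, 3.12], N = 1000
F =  0.5 pN   k =  0.86 1/s   95% band [0.74, 0.98]
F =  1.5 pN   k =  1.64 1/s   95% band [1.47, 1.81]
F =  2.5 pN   k =  2.57 1/s   95% band [2.29, 2.87]
F =  3.5 pN   k =  3.00 1/s   95% band [2.65, 3.42]
F =  4.5 pN   k =  3.02 1/s   95% band [2.49, 3.59]
F =  5.5 pN   k =  2.63 1/s   95% band [2.10, 3.30]
F =  6.5 pN   k =  2.84 1/s   95% band [2.10, 3.72]
```

The backward bond is stronger (2.98 vs 1.66 pN mean rupture force), and
the reconstructed backward k(F) rises up to ~2 pN and then plateaus
near 2.65 1/s — recovering the slip-ideal law the events were generated
from (true plateau 0.5·e^(2/1.2) ≈ 2.65 1/s). A two-sample KS test on
the two directions gives p_ks ≈ 3e-59 and the bootstrap mean-difference
test reports p_m < 1e-05.

A `mtbond` console script exposes the same workflow
(`simulate`, `detect`, `analyze`, `compare`, `dwell`, `motility`,
`pipeline`); see `mtbond --help`.

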