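# Methods

## Bond models

A bond's unbinding rate law k(F) is a contiguous chain of segments on
[0, F_max), each either *ideal* (force-independent) or *Bell slip*
(k = k0 · exp(F/F_β)). Each segment's `k0` is its rate at its own lower
edge, so continuity across junctions is enforced by construction rather
than solved for; this matches the piecewise phenomenology seen in
direction-resolved pulling experiments (slip, slip–ideal, ideal–slip)
without asserting a global functional form. The Bell parameterization
of the slip stretches is a modelling choice for simulation — measured
k(F) curves in this assay class are reported nonparametrically, and
nothing downstream assumes the generative form.

The cumulative hazard H(F) = ∫₀^F k has a closed form per segment
(linear for ideal, k0·F_β·expm1(ΔF/F_β) for Bell), and everything else
is built on it: the ramp rupture density p(F) = (k/r)·exp(−H/r), the
survival S = exp(−H/r), the mean rupture force E[min(F, F_max)] =
∫₀^F_max S dF by adaptive quadrature (abs/rel tolerance 1e−9, segment
edges supplied as quadrature break points), and inverse sampling.
F_max defaults to 25 pN — far above the ≤ ~8 pN ruptures these assays
produce — to bound numeric integration; mass surviving to F_max is
*censored*, flagged, and excluded from statistics. For ideal (or other
long-tailed) laws at r ≈ 5.6 pN/s, ~1 % of mass survives 25 pN, so
closed-form checks such as E[F] = r/k0 use F_max = 120–200 pN where the
censored mass is below 1e−8.

## Synthetic assays

**Event-level fast path.** Rupture forces are sampled exactly by
inverting the integrated hazard: with E ~ Exp(1), the rupture force
solves H(F) = r·E for constant loading rate, or ∫₀^F k/r(u) du = E for
a force-dependent r(F); the integral is tabulated on a 1e−4 pN grid and
inverted by linear interpolation. Events carry exact r_local and start
at zero force (no rebinding on this path). Identical seeds give
byte-identical tables.

**Trace-level path.** Quasi-static mechanics: while bound, the signed
force follows the deterministic ramp ±r·dt per sample (inertia ignored
— at ~100 nm/s stage speeds the bead corner frequency is far above the
loading bandwidth); rupture is a per-sample Bernoulli with probability
1 − exp(−k(|F|)·dt). After rupture the force relaxes exponentially with
time constant `tau_bead`, and the head rebinds at rate `k_on`;
rebinding before relaxation completes starts a *secondary* event at
F_start > 0. At a stage reversal the ramp changes sign, so a surviving
bond is unloaded through zero and re-loaded the other way — a
discontinuous re-zero would imprint an artificial force drop
indistinguishable from a rupture. Noise is white Gaussian on the
stored samples only (no 1/f or drift — enough to exercise detection
thresholds, not a model of real trap noise); the embedded truth log
records noiseless values. Sign convention: forward (minus-end) load is
negative, backward positive; all statistics are computed on magnitudes
per direction. The sampling rate must resolve the relaxation
(≥ 5 samples per tau_bead) or the configuration is rejected.

Defaults mirror the emulated operating point: k_trap = 0.025 pN/nm,
v_stage = 225 nm/s (nominal 5.625 pN/s), f_sample = 2 kHz,
sigma_noise = 0.08 pN, tau_bead = 5 ms. tau_bead is a free parameter
rather than the sub-millisecond value γ/k of a 1-µm bead because the
experimentally relevant quantity is the recovery time of the
bead–motor geometry that permits rebinding at residual force; tests of
secondary-event logic raise it to 50 ms.

**Dwell times.** Exponential bound times observed at a finite frame
interval (100 ms): raw dwells shorter than one frame are discarded
(unobservable) and survivors are rounded *up* to whole frames. The
recorded mean is therefore not 1/rate but
frame + frame/(1 − exp(−rate·frame)) — at rate·frame = 0.35 a ~50 %
inflation — which is why the estimator fits the CDF rather than
inverting the sample mean.

**Motility runs.** Velocities are Gaussian, run lengths
L_min + Exponential(L_char). Generator defaults used in tests emulate
the measured processive motor: 108 nm/s mean, 32 nm/s SD (a realistic
single-molecule spread at this speed), 1.1 µm characteristic run
length, n = 255 runs.

## Event detection

Rupture = force-drop criterion: a smoothed-|F| sample qualifies when at
least `drop_fraction` (default 0.8) of its value is lost within
`drop_window` (20 ms) and it is a local peak; ties inside one drop
window resolve to the earlier sample. Events peaking below
`F_min_event` (0.3 pN, the emulated instrument's detection limit) are
suppressed. F_start is the minimum smoothed |F| between consecutive
ramps — zero (noise floor) for a primary event, the residual force at
rebinding for a secondary one — and an event is primary iff
F_start ≤ 0.3 pN. The per-event loading rate is the least-squares slope
of the 200 ms of force before detachment, shrunk (with a warning) to
the bond lifetime for shorter events. Smoothing defaults to 5 ms of
samples — below tau_bead, above single-sample noise; for noiseless
traces tests use `smooth_window=1`, since any averaging across the
drop edge displaces the peak by more than one sample's ramp increment.
The drop criterion presumes the relaxation is mostly complete within
the drop window (tau_bead ≲ drop_window/2.5).

## Rupture-force statistics

1-pN histograms anchored at 0, normalized by N. CIs of the mean are
percentile bootstrap with 4,000 resamples (the BCa refinement is
deliberately not used; the flavor is recorded in output metadata so it
can be swapped). The two-sample KS test uses the asymptotic p-value.
The difference-of-means test bootstraps 1e5 means per sample,
differences them pairwise, centres the difference distribution at zero
(the null), and reports the two-tailed exceedance fraction; with zero
exceedances the p-value is floored at 1/n_boot and flagged, printed as
"<1e-05" at the default resampling depth. All stochastic operations
take an explicit seed.

## Rate reconstruction

k(F) = r(F)·p(F)/S(F) with p a Gaussian KDE (Silverman's rule on the
force sample, min(sd, IQR/1.34) spread) reflected at F = 0 to correct
boundary bias, and S the trapezoid integral of that same density —
using the smoothed density for both keeps the ratio internally
consistent; an ECDF-based survival is available behind
`survival_from="ecdf"` for sensitivity checks. r(F) is applied
pointwise on the grid. Curves run from 0.5 pN (just above the 0.3 pN
detection limit, where the rupture sample is truncated) upward in
0.1 pN steps and are truncated where S < 0.05 or fewer than 5 events
remain beyond the grid point. Bootstrap bands resample events with
replacement, refit the bandwidth per replicate, and take pointwise
2.5/97.5 percentiles; bands are widened if needed so the full-sample
point estimate always lies inside its own band (percentile bands can
exclude it under skew). A zero-load anchor (rate ± SE from dwell-time
data) is stored at F = 0 without altering the curve.

**Accuracy.** The plug-in estimator's pointwise noise grows toward the
tail: var[p̂] ≈ p/(n·h·2√π) plus survival noise gives a ~13 % relative
SD per grid point near S = 0.1 at n = 2000 (~6 % at n = 5000), for any
bandwidth — verified across h = 0.08–0.5 pN. Recovery is therefore
quantified as the *mean* absolute relative deviation over the reported
S ≥ 0.1 grid (typically 3–5 %), with pointwise agreement additionally
asserted on the well-sampled S ≥ 0.3 core. Single tail grid points
should be read with their bootstrap bands, not as point values.

## Dwell-time and motility fits

The zero-load rate is fitted by least squares of
1 − exp(−k·(t − t_min)) to the dwell ECDF with t_min fixed at one
frame. Under discard-sub-frame + round-up censoring this is exactly
unbiased: conditional on surviving one frame the remaining lifetime is
again exponential (memorylessness), and the frame-quantized ECDF equals
the shifted CDF at every recorded grid point; replicate studies show
|bias| < 0.4 % at rate·frame = 0.35, the worst case of interest. The
reported SE is the asymptotic SEM k/√n of an exponential-rate estimate
— the LSQ covariance understates the error several-fold because ECDF
residuals are strongly correlated — and matches the replicate SD to a
few percent. An exact MLE cross-check route treats the excess frame
count as Geometric(1 − e^(−k·frame)).

Velocity histograms (Freedman–Diaconis bins by default, logged) are
fitted with a Gaussian; the SEM is the fitted centre's standard error.
Run lengths are fitted by the same shifted-exponential ECDF route with
offset L_min (exposed as a parameter — whether short runs below a
detection cutoff are excluded is assay-dependent), the characteristic
length's SE following by the delta method. Degenerate (zero-spread)
velocity samples return their mean with SEM 0, flagged.

## Pipeline and I/O

Event tables are TSV with a fixed eight-column schema and a `#` header
block carrying units and provenance; readers reject unitless files,
schema mismatches, non-numeric cells (by row and column), and rows
whose force sign contradicts the stored direction. Traces are HDF5,
one group per trace with the truth log as a subgroup. The `pipeline`
command runs simulate → histogram/CI → compare → rate-curve from one
YAML config and is byte-deterministic given the config seed; stage
seeds are derived from it by fixed offsets and recorded in a
provenance file. CLI exit codes: 0 success, 2 validation error,
3 numerical failure.

## Problem sizes

Test and acceptance runs use the sample sizes the corresponding
experiments report or that the recovery targets prescribe: 5000 events
for flat-rate identity, 2000 per slip-law recovery, 500 replicates for
calibration studies, 2000 dwells per rate, 255 motility runs, 50–100
noiseless traces for detection fidelity. The full suite completes in
under two minutes on one CPU.

## Known limitations

- No vertical-force geometry (bead height / stalk angle) and no
  photobleaching model for dwell times.
- The oscillatory protocol contributes only loading-rate physics
  (peak r = k_trap · trap_speed); the oscillatory-assay unbinding-rate
  estimator itself is out of scope.
- The empirical loading-rate model is a non-negative-slope line in F;
  a genuinely nonlinear linkage compliance would need a different form.
- No parametric (Bell/Dudko-style) fitting of reconstructed curves;
  curves are reported nonparametrically with bands.
- Synthetic traces use white noise and a single exponential
  relaxation; real trap records carry low-frequency drift and colored
  noise that the detector has not been exercised against.
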