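# Methods

## Measurement model

A reversibly photoswitchable donor is driven to its dark state by the same
excitation light used to image it, with off-switching rate constant `k_D`
at the reference illumination.  Energy transfer to a nearby acceptor opens
a competing de-excitation channel, so a donor in a complex switches off at

```
k_DA = k_D · (1 − E)
```

where `E` is the per-complex transfer efficiency.  This rate law is the
core modeling commitment of both the simulator and the rate-ratio
estimator `EfD = 1 − k_DA/k_D`; everything else in the package is either
bookkeeping around it or an independent estimator validated against it.

For a complex with `n` identical acceptors the transfer channels add:
`E_n = n·e/(n·e + 1 − e)` for per-pair efficiency `e`.  Population-level
efficiencies are occupancy-weighted averages,

```
EfD = E_eff · [DA]·n_D / ([D] + [DA]·n_D)
EfA = E_eff · [DA]·n_D / ([A] + [DA]·n_A)
```

with `[D]`, `[A]` free donors/acceptors, `[DA]` complexes, and `n_D`, `n_A`
copies per complex.  These are the ground-truth quantities the simulator
emits and every estimator is judged against.

## Decay fitting

Traces are fitted with `y = a·exp(−b·t) + c` by bounded
(`a ≥ 0`, `b ≥ 0`) trust-region least squares with an analytic Jacobian.
Initialization: the offset from the mean of the trace tail (default last
5% of points), the amplitude from the first point, and the rate from a
log-linear regression over points clearly above the offset estimate.  If
the first solve fails or lands on a non-positive rate, a deterministic
lattice of restarts around the initial rate is tried and the best sum of
squares wins; there is no stochastic jitter unless seeded explicitly, so
fits are pure functions of the data.  A constant trace returns a
not-converged result with NaN rate rather than an arbitrary number.

A single exponential is a deliberate simplification — real photoswitching
decays have multi-exponential structure — but the FRET readout is a ratio
of rates fitted with the same model to both arms, which largely cancels the
model error.  On a mixed free/bound donor population the single-exponential
rate is only an approximation to the occupancy-weighted truth; the test
suite asserts a bounded (±15%) approximation at a 50% bound fraction when
the cycle covers the slower FRET-coupled component, and makes no stronger
claim.

### Weighted reduced χ²

Goodness of fit uses photon-counting weights, with the observed signal
`f_o` (in photoelectrons) as the per-point variance estimate:

```
w_t     = (1/f_o_t) / ((1/n) Σ 1/f_o_t)
s²      = 1/(n−m) Σ w_t (f_o_t − f_e_t)²
σ̄²     = 1 / ((1/n) Σ 1/f_o_t)
χ²_ν    = s² / σ̄²
```

which is why pixel data are converted to electrons on read (camera gain
factor) and never rescaled afterwards: the Poisson variance-equals-mean
assumption only holds in electron units.  χ² is computed on unnormalized
traces for the same reason.  Points with `f_o ≤ 0` (possible after
background subtraction) carry no usable variance estimate and are dropped
from the χ² sum only, with `n` reduced and a warning; the fit itself keeps
them.  Under correctly specified Poisson noise the mean χ²_ν over many
traces calibrates to ≈ 1 (the validation suite checks the [0.9, 1.1] band);
note that a trace averaged over an N-pixel ROI has its variance reduced by
N while the weights still assume per-pixel statistics, so ROI-level χ²_ν
values are ≈ 1/N and useful only for relative comparisons.

### Pixel-by-pixel fitting

Each pixel above a first-frame threshold is fitted independently (order-
free, identical results regardless of traversal); the output is a rate map
with A0, rate, offset and χ²_ν planes, NaN outside the fitted mask.  The
default threshold, when a background series is available, is background
mean + 3 SD; otherwise it is user-supplied.  Optional `factor × factor`
spatial binning before fitting (the FLIM binning analogue) trades
resolution for photon budget and demonstrably lowers χ²_ν.  The
coefficient of variation of the rate image over a uniform fluorophore
field is the illumination-flatness QC metric, since the switching rate is
proportional to local excitation intensity.

## Sensitized emission without an acceptor-alone sample

With the donor switched off (brightness reduced `contrast`-fold), the FRET
channel reads the direct acceptor excitation in situ, so

```
Fc_on = I_DA_on − I_DA_off − d·I_DD_on
```

needs only the experiment's own stacks plus the bleed-through factor
`d = (I_DA_on − I_DA_off)/I_DD_on` from donor-alone cells (averaged across
cells, SD reported).  The classic `a = I_DA/I_AA` factor from
acceptor-alone samples is supported as an optional cross-check but is not
part of the default pipeline.  On-state levels are taken from the first
frame of the cycle (configurably the mean of the first k frames); the off
state is fit-informed — frames where the donor channel has decayed to
within 2% (default) of its fitted amplitude above its fitted offset — with
a flagged fallback to the last 10% of frames when switching is incomplete.
Negative `Fc_on` or negative efficiencies are returned flagged, never
clamped: silent clamping hides calibration errors.

The `G` factor, `G = Fc_on(1 − EfD_ref)/(EfD_ref · I_DD_on)`, is calibrated
once on a construct whose `EfD_ref` comes from a rate-ratio measurement.
Within this measurement model `G` is independent of the calibration
construct's efficiency (it equals the relative sensitized-emission
brightness `q_rel`, times `1 − 1/contrast`), so one calibration serves all
constructs on the same optical configuration — the package's tests
calibrate on one efficiency and verify on another.

### Finite-contrast bias of EfA

`EfA = (ε_A/ε_D)·Fc_on/I_DA_off` assumes `I_DA_off` is pure direct
acceptor excitation.  At finite on/off contrast the donor's off-state
residual still bleeds through and still transfers, inflating `I_DA_off`
and deflating `Fc_on` by O(1/contrast); at the default contrast of 75 and
the default scene this biases EfA low by about 5% relative (0.285 vs 0.30),
shrinking linearly with contrast.  The donor-side estimators are immune:
the rate ratio and photobleach estimators are algebraically exact at any
contrast, and the G-calibrated sensitized EfD is exact because the same
`1 − 1/contrast` factor enters `G` and `Fc_on` and cancels.  The
exact-identity tests therefore run the EfA leg in the infinite-contrast
limit (`PhotophysicsModel(contrast=math.inf)`), and a separate test pins
the finite-contrast bias to its O(1/contrast) scaling.

## Cycle drift and its correction

The donor's off-switching rate increases slowly and approximately linearly
with the number of on-off cycles, by about the same absolute amount per
cycle whether or not an acceptor is attached.  The correction is additive
and anchored at cycle 1: an OLS line fitted to a donor-only control's
rate-vs-cycle series gives a slope, and `k_corr(c) = k(c) − slope·(c − 1)`
is applied to both arms before the rate ratio.  Additive (rather than
multiplicative) correction follows from the equal-absolute-slope
observation; anchoring at cycle 1 takes the first cycle as the reference
state.  Both choices are interpretations — the correction is empirical,
not mechanistic — and with equal injected slopes on both arms the
corrected efficiency is exactly cycle-independent, which is the property
the tests assert.  When a concurrent per-cycle control exists, its rate is
used directly instead (preferred); this absorbs most but not exactly all of
an additive drift, since the drift enters numerator and denominator of the
ratio unequally.

## The simulator

`simulate` generates expectations analytically and adds noise only at the
final step, so every intermediate quantity has a closed form the tests can
check against.  Per region, the donor-channel expectation is

```
S_DD(t) = B·([D]·g(t; k_D) + [DA]·n_D·(1 − E_eff)·g(t; k_DA)) + bg
g(t; k) = (1 − 1/contrast)·exp(−k·t) + 1/contrast
```

and the FRET channel adds donor bleed-through `d·(S_DD − bg)`, direct
acceptor excitation `∝ (ε_A/ε_D)·([A] + [DA]·n_A)`, and sensitized
emission `∝ [DA]·n_D·E_eff·g(t; k_DA)` — the sensitized term decays with
the donor's on-state population, which is what makes first-frame `Fc`
measurements meaningful.  Noise is Poisson on the expectation plus
Gaussian read noise; the flat-field multiplies brightness *and* rates,
since switching is excitation-driven.  Repeated cycles add the drift
offset to all rates and scale amplitudes by the reactivation efficiency;
acceptor photobleaching moves a fraction of complexes into the free-donor
pool (whole complexes only — partial bleaching within a multi-acceptor
complex is not modeled).

Defaults represent the emulated system: `k_D = 1 s⁻¹` (a Dronpa-scale
off-switching rate at moderate 488-nm power, giving a few-second cycle),
contrast 75 (mid-range of the 50–100× on/off ratio), bleed-through
`d = 0.08`, extinction 62,600/7,700 mol⁻¹cm⁻¹, 100 frames at 50 ms,
500 photoelectrons initial per unit concentration per pixel, 2 e⁻ read
noise.  `q_rel = 0.9` (detected sensitized-acceptor brightness per
transferred excitation) has no single literature value — it folds together
acceptor quantum yield and the red channel's collection efficiency — and
any positive value is self-consistently removed by the G calibration.

What the simulator does *not* emulate: diffraction/PSF blur, single-
molecule blinking, triplet states, acceptor photophysics during a cycle
(optional photofatigue hooks excepted), 405-nm reactivation kinetics
(treated as instantaneous between cycles), cell morphology and expression
heterogeneity beyond region maps, and sub-pixel channel misalignment.
Passing tests therefore demonstrate the correctness of the estimators and
their calibrations under the stated noise model — not robustness to
optical artifacts a real microscope would add.

## Numerical and interface choices

* Pixel data are float photoelectrons from the moment of reading
  (`ADU × gain`); all downstream math is in e⁻.
* Coordinates are `(t, y, x)`, 0-based, y down; ROI masks share frame
  coordinates.
* Background is scalar or per-frame (default per-frame, matching a
  separately acquired background series); post-subtraction negatives are
  kept, since the fitted offset absorbs the baseline.
* Dual-View registration is integer-pixel translation only, by exhaustive
  normalized cross-correlation over a bounded (±10 px default) window with
  ties broken toward the smallest shift; no rotation, scaling or sub-pixel
  refinement.  Halves can be analyzed in place or registered — the package
  supports both and asserts neither as the canonical workflow.
* Fit bounds: `a ≥ 0`, `b ≥ 0`, `c` unbounded (background over-subtraction
  legitimately produces small negative offsets); non-finite optimizer
  output means not-converged.
* Validation problem sizes (24×24 pixel maps, 100-cell ensembles, 500-trace
  χ² calibrations, 60-cycle drift runs) are chosen so the whole validation
  suite re-simulates from scratch in seconds on one CPU while keeping
  Monte-Carlo standard errors well inside the asserted tolerances.

## Known limitations

* The rate law `k_DA = k_D(1 − E)` is adopted as the model consistent with
  the rate-ratio estimator rather than derived from photophysical first
  principles here; all estimator cross-validation is internal to that
  model.
* Single-exponential fitting of genuinely mixed populations is biased (see
  above); the package reports the fit, not a mixture decomposition.
* EfA carries the O(1/contrast) bias described above; for low-contrast
  photoswitchers the acceptor-side readout degrades accordingly.
* Drift correction assumes linearity in cycle number and equal absolute
  slopes across constructs; both are empirical observations, not laws.
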