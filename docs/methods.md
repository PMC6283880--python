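# Methods

This note records the models implemented in `smtkin`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the package's own design decisions where the underlying
procedures left room.

## Physical model of a photoactivated, chromatin-bound molecule

A molecule appears (photoactivates) at wall time `t0`, belongs to the
transient class (dissociation rate `k1`) with probability `1 − frac_stable`
or the stable class (`k2 < k1`) with probability `frac_stable`, and is
lost at the earlier of:

* unbinding — exponential in wall-clock time with rate `k_i`;
* photobleaching — exponential with rate `kb` in *illuminated* time,
  i.e. the bleaching clock only runs while the laser is on.

Visibility is discretized by the **half-frame rule**: a molecule is
visible in a frame if it is present for at least half of that frame's
illumination. The rule is symmetric (it neither systematically extends
nor truncates lifetimes) and makes the sampled on-times exactly
geometric per class with decay constant
`exp(−(kb·τ_on/τ_tl + k_i)·τ_tl)` — the discrete counterpart of the
continuous bi-exponential density. Unbound molecules diffuse with
`D_free = 2 µm²/s` (a conventional nuclear-protein mobility; its only
role is to separate free from bound molecules at the 166 nm/0.2 µm²
gates, which it does by three orders of magnitude in displacement
probability).

## Time-lapse residence-time fitting

Histograms of on-times (units of frames × `τ_tl`, per-bin error √N with
empty bins assigned error 1 so they constrain the tail) from several
time-lapse conditions are fitted globally: shared `kb, k1, k2, B`, one
free amplitude per condition, Levenberg–Marquardt on weighted residuals
with stopping criterion 1e-7 on the relative change of the squared-error
sum. Parameters are bounded (`rates ∈ [1e-4, 1e3] s⁻¹`, `B ∈ [0, 1]`)
and canonicalized to `k1 ≥ k2` after the fit (swapping `B ↔ 1−B` with
the rates). Initial values are derived from the data: the long-interval
condition (bleaching suppressed by the duty cycle) seeds `k1`, the
shortest condition seeds `kb` through the effective-rate difference,
`k2 = k1/10`, `B = 0.5`.

**Binned versus density fitting.** Evaluating the continuous density
`f_T(t)` at the bin times mis-weights the two classes by factors
`(e^x − 1)/x`, `x = (kb·τ_on/τ_tl + k_i)·τ_tl`, and at strong bleaching
(`kb·τ_on ≈ 1.8` for the default TBP-like conditions) this bias is large
enough to corrupt the recovered rates at any sample size. The default
`binning="discrete"` therefore fits the exact binned (geometric-mixture)
form, which has the same parameters and reduces to `τ_tl·f_T(m·τ_tl)` in
the continuum limit; `binning="density"` reproduces the naive fit for
comparison.

**Identifiability.** A single `τ_tl` condition only determines
`kb·τ_on/τ_tl + k_i`; the double model refuses to fit one condition, and
single-model fits on one condition are flagged `ill_conditioned`.
Reduced χ² uses `Σ bins − (3 + 1 + #conditions)` degrees of freedom for
the double model. Model comparison (single versus double) prefers the
lower reduced χ²; the package's linearity diagnostic, by contrast, uses
an extra-parameter F-test (α = 0.01) because the saturating alternative
nests the line and AIC's fixed penalty miscalls small cohorts.

**Information content at experimental scale.** At the TBP-like truth
(`kb = 7.3 s⁻¹`, `τ_on = 250 ms`, five conditions spanning 0.25–4 s,
~4800 detected molecules) a Cramér–Rao analysis of the multinomial
duration data bounds the standard deviation of the recovered stable
residence time at ≈ 4 s regardless of estimator — single datasets of
that size simply cannot pin `1/k2` tightly, and fitted standard errors
there should be read with care. The package's own validation therefore
measures parameter recovery on datasets of 10⁶ detected molecules
(medians over seeded replicates), where the recovery error is a few
percent; tests at the ~4800-molecule scale check consistency, not
precision. These problem sizes are stated in the acceptance script and
run in seconds.

## ITM bound-fraction estimation

The interlaced schedule is two back-to-back 165 ms frames followed by a
750 ms dark time (1.08 s cycle). Classification of a track: *detected*
(≥ 1 frame), *all binding* (≥ 2 successive acquisitions within the
166 nm gate), *long binding* (visible span crosses ≥ 1 dark time);
`long ⊆ all ⊆ detected` always.

**Observation probabilities.** For a bound molecule of class `i`
appearing at a uniformly random phase of the cycle, the probability of
surviving to the visibility threshold `m` of a given frame is
`exp(−k_i·(m − t0) − kb·g(t0, m))` with `g` the illuminated time between
appearance and threshold. The cycle splits into five phase segments on
which the thresholds for detection / all / long classification are
affine in `t0`; the phase average is evaluated per segment by 48-point
Gauss–Legendre quadrature (the integrand is smooth, so this is exact to
machine precision for practical purposes). The closed form is validated
against the event simulator (10⁶ molecules) within 3 Monte-Carlo
standard errors at bleaching-dominated, moderate and zero-bleach
parameter sets — simulator and formulas are independent codes.

**Correction.** With per-class probabilities `(p_det, p_all, p_long)`,
the observed `(N_all, N_long)` are a linear map of the true class
numbers `(n1, n2)`; solving the 2×2 system and clipping negative
solutions (sampling noise at small counts, logged) gives the stable
proportion `B = n2/(n1+n2)`. For the bound fraction the detected
denominator is decomposed as free + bound detections, with each free
molecule assumed detected exactly once: between 165 ms frames a molecule
with µm²/s-scale mobility has ~1% probability of staying within the
166 nm gate, and out-of-plane diffusion removes it from the ~3 µm light
sheet, so free molecules cannot sustain multi-frame events. Then
`D = (n1+n2)/(n_free + n1 + n2)`. Applied to expectation counts the
correction returns the generating numbers exactly; applied to simulated
stage series it recovers the generator's `D` and `B` within count noise.
Embryos contributing ≤ 1 bound molecule are excluded (logged).

**Bootstrap.** Estimates pool embryos; errors resample embryos (not
molecules): 900 subsets of 80% without replacement. For an `n`-embryo
cohort this subset spread is a delete-d jackknife scatter and
understates the full-sample s.e.m. by `sqrt(m/(n−m))` (`m` = subset
size); the reported s.e.m. applies that calibration by default
(`calibrate=False` gives the raw subset SD). Fold-change confidence
intervals treat the ratio as log-normal and use Student-t quantiles with
`min(n_embryos) − 1` degrees of freedom, since the variance itself is
estimated from a handful of embryos. Measured coverage of the 95% CI on
simulated two-stage series is 93–98%.

## Localization and tracking

Detection thresholds at mean + 3.5 SD of the whole frame, computed on a
PSF-matched Gaussian-smoothed copy (σ = 1 px by default; `smooth_sigma=0`
applies the rule to raw pixels). Near the detection limit the matched
filter is what makes a 3.5 SD rule usable: raw pixel values of SNR 3–4
spots fall below threshold at typical sub-pixel offsets. Each connected
supra-threshold component yields one candidate (brighter peaks absorb
neighbours within the fit-window radius); candidates within one window
of the edge are dropped. Sub-pixel positions come from least-squares
isotropic 2D-Gaussian fits (amplitude, center, σ, constant background)
in a 7×7 window on the *raw* image; SNR is amplitude over the residual
standard deviation in the window (the field has no single SNR
convention; this one is self-contained). Pixel size defaults to
0.166 µm, pixel centers at integer indices, origin top-left, 0-based.

Linking is greedy nearest-neighbour between consecutive acquisitions
(ties by smaller displacement, then earlier index), with links across
scheduled dark times under the same gate; gates are 166 nm for ITM and
the 0.2 µm²-equivalent radius for time-lapse. A missed acquisition
terminates visibility (no gap closing within bursts) so that on-time
counting matches the duration model. The bound criterion — some
sub-track of ≥ 100 ms within 0.2 µm² — uses the axis-aligned bounding
box as the area construction (deterministic and cheap; a max-pairwise-
distance alternative is a switch) and requires at least two
localizations, since one position cannot demonstrate confinement.

In the measured regime (SNR drawn uniformly from 3–5, ~5 visible spots
per 64×64-px frame), the combined miss + false-positive rate against
ground truth within 1 px is 12–14%. Misses concentrate at SNR ≈ 3;
false positives are threshold exceedances of smoothed noise and scale
with frame area, so the error ratio depends on spot density — the quoted
regime is the package's standard benchmark, stated in the acceptance
script.

## Synthetic data: what it does and does not emulate

The generator reproduces: two-class exponential binding, illumination-
gated bleaching, uniform-phase photoactivation (staggered activation in
rendered movies, emulating repeated activation pulses), per-embryo
log-normal expression variation (CV 0.3), law-of-mass-action bound
counts without saturation, Gaussian PSF spots (σ = 0.15 µm) at target
SNR on a Poisson + Gaussian-read-noise background (gain 1), and
stage-dependent nuclear volumes. Default kinetic parameter sets
(`TBP_LIKE`: 0.3 s/6.8 s residence, `kb = 7.3 s⁻¹`, 20% stable;
`SOX19B_LIKE`: 0.3 s/2.0 s, `kb = 5.8 s⁻¹`) represent the two TF
species studied with this pipeline.

Not emulated: 3D PSFs and depth-dependent scattering (depth enters only
as an SNR knob), EM-CCD excess noise, fluorophore blinking, nuclear
drift or envelope breakdown, and saturation of binding sites. Passing
tests therefore demonstrate correctness of the estimators under the
stated physics, not robustness to all artifacts of real acquisitions —
notably, out-of-focus loss during long dark times would bias measured
residence times downward in real data, as acknowledged wherever the
rates are interpreted.

## Mass action

`predict_bound_fraction` and `invert_for_sites` are exact algebraic
inverses; apparent site numbers are reported relative to a reference
stage because the association rate constant is not separately
measurable. Error propagation is parametric bootstrap by default
(Gaussian draws truncated to the parameter domains, reference-stage
uncertainty folded into every ratio) with a first-order Taylor
alternative; the two agree within ~10% at typical uncertainties.
Nuclear volumes use an ellipsoid model, with the out-of-plane semi-axis
taken as the geometric mean of the in-plane axes by default (oblate and
prolate closures as options) when only a cross-section is available;
in-plane axes from a contour come from its second moments. Relative
concentrations divide first-frame-after-activation counts by the
volume; they are relative quantities only.

## Reproducibility

Every stochastic function takes a seed or Generator; identical seeds
give bit-identical outputs (asserted in tests). Pipeline runs write a
manifest (version, seed, config digest, all parameters). The bundled
problem sizes — 10⁶-molecule duration datasets, 10⁶-molecule Monte-Carlo
oracles, 120-frame rendered movies, 50-replicate diagnostics — keep the
full test suite and the acceptance script in the minutes range on a
single CPU.
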