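# smtkin

Single-molecule tracking kinetics of transcription-factor (TF) chromatin
binding in early embryos: spot detection and tracking, photobleaching-
corrected residence-time analysis, interlaced time-lapse bound-fraction
estimation, and a mass-action occupancy model — together with a seeded
synthetic-data generator so every stage can be validated against known
ground truth.

## Who this is for

Labs doing single-molecule imaging of nuclear proteins in systems with
fast cell cycles (early zebrafish or *Drosophila* embryos, cleaving
*Xenopus* blastomeres), where acquisition time per condition is scarce and
photobleaching is severe. The package turns image stacks or localization
tables into dissociation rate constants, chromatin-bound fractions,
stable-bound proportions and apparent binding-site numbers per
developmental stage.

## The models

**Residence times from time-lapse imaging.** A bound, photoactivated
molecule disappears by dissociation (rate `k_off`, wall-clock time) or by
photobleaching (rate `k_b`, illuminated time only). Imaging one frame of
length `τ_on` every `τ_tl` seconds makes the fluorescent "on" times decay
with the effective rate `k_b·(τ_on/τ_tl) + k_off`, so histograms from
several `τ_tl` conditions separate bleaching from dissociation. With two
binding classes (transient/unspecific and stable/specific) the on-time
density is

```
f_T(t) = A·[ B·(k_b·r + k₁)·exp(−(k_b·r + k₁)·t)
           + (1−B)·(k_b·r + k₂)·exp(−(k_b·r + k₂)·t) ],   r = τ_on/τ_tl
```

fitted globally across conditions (shared `k_b, k₁, k₂, B`; one amplitude
per condition) by error-weighted Levenberg–Marquardt. The default fit
uses the exact frame-binned form of this model (a two-component geometric
mixture with the same rates), which stays unbiased when
`(k_b·r + k_off)·τ_tl` is not small; `f_T` itself is available as
`eval_model` / `binning="density"`.

**Bound fractions from interlaced time-lapse microscopy (ITM).** Bursts
of two 165 ms frames separated by 750 ms dark times classify detected
molecules into *all binding* events (≥ 2 successive frames within 166 nm)
and *long binding* events (survive ≥ 1 dark time). Raw ratios are biased
— stable molecules that bleach early are counted as transient, and bound
molecules are detected more often than free ones — so the package derives
closed-form per-class observation probabilities from the exponential
survival model (phase-averaged over the ITM cycle, validated against a
Monte-Carlo simulator) and solves the linear system for the true class
numbers. Errors come from an embryo-level bootstrap (900 subsets of 80%,
with delete-d jackknife calibration).

**Mass action.** At equilibrium the occupancy ratios are
`f_i/f_free = λ_i/k_i` with pseudo-association rates `λ_i ∝ N_app,i/V_n`,
giving a bound fraction `D = (r₁+r₂)/(1+r₁+r₂)` independent of TF copy
number. Inverting measured `(D, B)` with the fitted rates and nuclear
volume yields the apparent number of chromatin binding sites per stage,
reported relative to a reference stage.

## Worked example

```python
import pandas as pd
from smtkin import (TBP_LIKE, simulate_timelapse_experiment, build_histogram,
                    global_fit, compare_models, interlaced, EmbryoScenario,
                    generate_stage_series, class_probability_matrix,
                    bootstrap_estimates, fold_change_ci, invert_stage_table)

# 1. residence times: simulate 10^5 detected molecules over five
#    time-lapse conditions and fit the global bi-exponential model
data = simulate_timelapse_experiment(TBP_LIKE, 0.25, [0.25, 0.5, 1, 2, 4],
                                     100_000, seed=8)
hists = [build_histogram(m, 0.25, tl) for tl, m in data.items()]
fit = global_fit(hists)
pref, chi_s, chi_d = compare_models(global_fit(hists, model="single"), fit)

# 2. bound fractions: a two-stage ITM series with a 6-fold rise
scens = [EmbryoScenario("64-cell", 400.0, 8000, 0.04, 0.2),
         EmbryoScenario("oblong", 150.0, 8000, 0.24, 0.2)]
counts = generate_stage_series(scens, TBP_LIKE, seed=8, n_embryos=5)
probs = class_probability_matrix(TBP_LIKE.k1, TBP_LIKE.k2, TBP_LIKE.kb,
                                 interlaced())
ests = {s.stage: bootstrap_estimates(counts[counts.stage == s.stage],
                                     probs, seed=9) for s in scens}
fold, lo, hi = fold_change_ci(ests["64-cell"], ests["oblong"])
```

prints (via the obvious `print` statements):

```
transient residence time: 0.29 s
stable residence time:    6.79 s
photobleaching rate:      7.11 1/s
model preference: double (reduced chi2 1.082 vs 31.516)
64-cell: D = 0.038 +/- 0.007, B = 0.11 +/- 0.06
oblong: D = 0.225 +/- 0.016, B = 0.21 +/- 0.05
bound-fraction fold change: 6.0 (95% CI 3.5-10.1)
64-cell: N_app = 1.00 +/- 0.00
oblong: N_app = 2.49 +/- 0.66
```

The fit recovers the generator's ground truth (0.3 s and 6.8 s residence
times, 7.3 s⁻¹ bleaching) and clearly prefers two dissociation classes;
the ITM correction turns raw event counts into bound fractions whose
fold change matches the simulated 6-fold rise; and the mass-action
inversion attributes part of that rise to more apparent binding sites
(`N_app` 1 → 2.5) on top of the shrinking nuclear volume (400 → 150 µm³).

A command-line interface mirrors the stages (`smtkin sim|locate|track|
fit-kinetics|itm-estimate|massaction|run|report`); `smtkin run config.cfg`
executes a whole configured pipeline and writes tab-delimited tables plus
a manifest for bit-identical reruns.

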