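# Methods

This note records the statistical model behind `pdxsyn`, the defaults and
why they were chosen, the numerical conventions, and what the simulation
-based validation does and does not demonstrate.

## Data model and preprocessing

Input is a long table of raw tumor volumes: one row per (mouse, arm, day)
with arms C (control), A, B (monotherapies) and AB (combination). Within
each mouse, the response is the **relative tumor volume**
v<sub>t</sub> = V(t)/V(baseline); the baseline is the mouse's *earliest
measured day*, not necessarily day 0, which is robust to staggered
enrollment. Relative volumes are scale-free: multiplying a mouse's raw
volumes by any constant changes nothing downstream.

Missing interior days are filled by linear interpolation between the
nearest measured neighbors,
v<sub>t</sub> = v<sub>t0</sub> + (v<sub>t1</sub> − v<sub>t0</sub>)/(t1 − t0)·(t − t0).
Interpolation is never applied outside a mouse's observed span: mice
leave PDX studies when tumors hit a size limit, so extrapolating past the
last measurement would fabricate data under informative dropout — those
mice simply drop out of later per-day summaries. Duplicate (mouse, day)
rows are an error by default (they usually indicate data-entry problems),
with an opt-in to average. When more than half of an arm's values at a
day are interpolated, a warning is raised rather than an error: the
threshold is a recommendation about trustworthiness, not a validity
condition.

Per-arm, per-day summaries use the unweighted sample mean and the
unbiased (n−1) sample variance. The default analysis grid is the sorted
union of observed days at which every arm retains at least two
contributing mice; it can be overridden.

## Treatment effect

At a fixed day, the effect of arm g is the tumor growth inhibition
δ<sub>g</sub> = (μ<sub>C</sub> − μ<sub>g</sub>)/μ<sub>C</sub>, estimated
by plugging in sample means. The delta method on the independent group
means gives

se(δ̂) = ( v̄<sub>g</sub>²·σ̂²<sub>C</sub>/(v̄<sub>C</sub>⁴ n<sub>C</sub>)
        + σ̂²<sub>g</sub>/(v̄<sub>C</sub>² n<sub>g</sub>) )<sup>1/2</sup>,

and the reported bound is the one-sided lower limit
δ̂ − z<sub>1−α</sub>·se (α = 0.05 by default). One-sided is the default
because the scientific question is directional — is the drug at least
this active? — and matches how such bounds are read in practice; a
two-sided option exists. Effects outside [0, 1] do not abort anything:
they flag the Bliss-interpretability report (below).

## Combination indices

All three indices are log-scale contrasts of the observed combination
mean against a reference model's no-interaction prediction, so that
CI > 0 ⇔ synergy. Natural logarithms are used throughout (only the sign
convention matters; any base rescales index and SE identically).

- **HSA**: CI = log μ<sub>g*</sub> − log μ<sub>AB</sub>, where g* is the
  monotherapy with the larger δ. On an exact tie, the arm with the
  smaller TGI standard error is used — the operational meaning of "the
  narrower interval", since one-sided bounds have no finite width — and
  a remaining tie goes to A (deterministic). The control arm enters only
  through the selection of g*; the index itself ignores it, which is
  both HSA's convenience and its weakness (a t-test-like comparison of
  AB against the better single agent).
- **RA**: CI = log(μ<sub>A</sub> + μ<sub>B</sub>) − log(μ<sub>AB</sub> +
  μ<sub>C</sub>), the additive-effects reference rewritten as a ratio.
- **BI**: CI = log μ<sub>A</sub> + log μ<sub>B</sub> − log μ<sub>C</sub>
  − log μ<sub>AB</sub>, the probabilistic-independence reference. Its
  reading as "one minus a product of survival fractions" presumes every
  δ<sub>g</sub> ∈ [0, 1]; when an estimate falls outside, the index is
  still computed and reported but carries `bliss_valid = False`.
  Suppressing it would hide information; flagging lets the analyst
  decide.

Delta-method SEs for all three are the plug-in formulas obtained from
the gradients of these log contrasts; the test suite verifies each
against a finite-difference delta method to < 10⁻⁶ relative error.

With both monotherapies no worse than control, CI_HSA ≥ CI_BI always,
and whenever CI_RA ≥ 0 also CI_RA ≤ CI_BI ≤ CI_HSA: HSA is the most
permissive synergy caller and RA the most conservative. The ordering is
**conditional** — for some antagonistic configurations CI_RA > CI_BI —
so the property tests assert it only where it is provable.

## Interval calibration

The asymptotic interval is the Wald interval ĈI ± z<sub>1−α/2</sub>·se.
With 5–10 animals per arm and right-skewed volume distributions it runs
narrow, so the **bootstrap-t** interval is provided: for b = 1…B,
resample n<sub>g</sub> animals with replacement within each arm,
recompute the index (for HSA, the reference arm is re-selected inside
every replicate) and its delta-method SE, form
Z\*<sup>b</sup> = (ĈI\*<sup>b</sup> − ĈI)/se\*(ĈI\*<sup>b</sup>), and invert
the empirical Z* distribution:

(ĈI − t̂<sup>(1−α/2)</sup>·se(ĈI), ĈI − t̂<sup>(α/2)</sup>·se(ĈI)).

Numerical conventions, fixed so runs are bit-reproducible:

- t̂<sup>(α)</sup> is the ⌈αB⌉-th order statistic of Z* (exact inversion
  of #{Z* ≤ t̂}/B = α), monotone in α.
- B defaults to 1000 — standard for bootstrap-t at α = 0.05 —
  and is configurable.
- A replicate in which *every* arm happens to be resampled to constant
  values has se* = 0 and an undefined Z*; such replicates are redrawn
  (keeping B effective replicates) and counted in the diagnostics. Data
  degenerate in every arm raise an error: studentization is impossible.
- One seeded generator drives all resampling in a fixed arm order.

## Global index and the nested bootstrap

gCI is the unweighted mean of per-day indices over a user-chosen window
(default: every analysis day after baseline, "the study interval of
interest"). Because the same mice are measured repeatedly, per-day
indices are correlated across days and gCI has no analytic variance.
The bootstrap therefore resamples **whole growth curves** within each
arm — never individual time points across animals — and studentizes
each outer replicate with an inner loop: L resamples of the b-th
resample give se\*(ĝCI\*<sup>b</sup>) as their standard deviation
(L = 25 by default). The standard error of the original ĝCI, needed by
the interval formula, is estimated by the same inner-loop scheme applied
once to the original curves — the only estimator the nested procedure
itself supplies. Only animals with complete (post-interpolation) curves
on the window contribute; a window day on which any arm would fall below
two such animals is dropped with a warning.

## Power analysis

The planning tool treats the index as asymptotically normal:
ĈI ~ N(γ, var(CI)) with var(CI) the delta-method variance at
prespecified population means, SDs and group sizes. The two-sided
level-α test of H₀: CI = 0 then has power

1 − β = Φ(−z<sub>1−α/2</sub> + λ) + Φ(−z<sub>1−α/2</sub> − λ),
λ = γ/√var(CI).

This is the standard normal-shift form; it returns exactly α at γ = 0,
as a test's power at the null must equal its size. (A literal
upper-quantile reading of the second term as Pr(Z ≥ −z<sub>α/2</sub> − λ)
would give 1 at γ = 0; we treat that as a notation slip and use the
standard form.)

Synergy thresholds — the largest μ<sub>AB</sub> still giving CI > 0 at
fixed μ<sub>C</sub>, μ<sub>A</sub>, μ<sub>B</sub> — are HSA:
min(μ<sub>A</sub>, μ<sub>B</sub>); RA: μ<sub>A</sub> + μ<sub>B</sub> −
μ<sub>C</sub> (unattainable when ≤ 0); BI:
μ<sub>A</sub>μ<sub>B</sub>/μ<sub>C</sub>. RA ≤ BI ≤ HSA when the
monotherapies beat control, which is the threshold-side statement of the
conservativeness ordering. Sample-size search is bisection on the
(monotone in n) power function, with a minimality check.

One caveat worth knowing: power is *not* globally monotone decreasing in
μ<sub>AB</sub>. As μ<sub>AB</sub> → 0 the variance of the log-scale
index grows like σ²<sub>AB</sub>/(μ²<sub>AB</sub>n), so λ → 0 and power
decays back toward α; the curve has an interior maximum (near
μ<sub>AB</sub> ≈ 0.57 in the worked scenario). On the design-relevant
region μ<sub>AB</sub> ≥ 1 — no net regression below baseline — power
decreases monotonically toward α at the threshold, and that is the
region the tests assert.

## The simulator

Arm-level mean growth follows the Gompertz law
V(t) = V₀·exp[(a/b)(1 − e<sup>−bt</sup>)] (plateau V₀e<sup>a/b</sup>);
treatment attenuates the rate a. Defaults emulate a typical three-week
PDX study and the worked power scenario: measurements every 2–3 days
through day 21; control relative volume reaching 2.8 at day 21,
monotherapies 2.4 and 2.0 (b = 0.1/day, rates solved from those
targets), a directly-parameterized AB arm reaching 1.5 when no null
model is requested; per-arm SDs at day 21 of 0.7 (control) and 0.3
(treated); 10 mice per arm; per-mouse baseline volumes lognormal around
100 mm³ with CV 0.2 (exercising baseline normalization without
affecting relative volumes).

Noise is multiplicative lognormal with mean exactly 1 (the log-SD per
arm is converted from the target day-21 SD and held constant across
days, so the SD scales with the mean). Mean-one noise matters: it makes
the *arm mean* equal the Gompertz curve exactly, so when the AB mean is
set to a reference model's null prediction — min(μ<sub>A</sub>,
μ<sub>B</sub>) for HSA, μ<sub>A</sub> + μ<sub>B</sub> − μ<sub>C</sub>
for RA, μ<sub>A</sub>μ<sub>B</sub>/μ<sub>C</sub> for BI — the true
index is exactly 0 at every day, giving coverage studies a known truth.
Optional per-point dropout (never the baseline) exercises the
interpolation path. All randomness flows from one seed.

What the simulator does **not** emulate: within-mouse serial correlation
beyond the shared mean curve (noise is independent across days),
measurement-error structure of caliper readings, informative dropout
(tumors culled at a size limit), and resistance/PK-PD dynamics. Passing
coverage tests therefore show the inferential machinery is calibrated
under the stated generative model, not that real PDX data meet its
assumptions; the bootstrap layers exist precisely to soften those
assumptions in practice.

## Validation design and problem sizes

The acceptance suite simulates at the study conditions above: per-day
bootstrap-t coverage at day 21 under each model's null with 1000
replicate experiments and B = 1000; one-sided TGI bound coverage with
1000 two-arm replicates; the n = 5 comparison (asymptotic vs bootstrap-t
coverage, paired replicate-for-replicate over 1000 simulations); and
nested-bootstrap gCI coverage with 500 replicates at B = 500, L = 25.
Property checks (exact nulls, orderings, SE oracles, test size) use
10³–10⁴ randomized draws. These sizes give binomial standard errors of
0.7–1 percentage point on coverage estimates while keeping the full
suite to a few minutes on one core.

## Known limitations

- The one-sided asymptotic TGI bound undercovers slightly at n = 10
  (true coverage ≈ 94% under the default conditions; the z-quantile with
  estimated variances and the ratio nonlinearity both contribute). This
  is a property of the asymptotic bound itself — the same phenomenon
  that motivates the bootstrap-t for the indices — and is visible in the
  acceptance outputs as coverage a point or so below nominal.
- Bootstrap-t intervals are not guaranteed to contain the point
  estimate (a known feature of studentized bootstrap inversion).
- The HSA index inherits the non-smoothness of the max() selection; its
  delta-method SE conditions on the selected arm and understates
  uncertainty when the two monotherapy effects are nearly tied.
- gCI weights all window days equally; late days with few surviving
  animals can be dropped from the window entirely but are never
  down-weighted.
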