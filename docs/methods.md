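# Methods

This note documents the models implemented in `zfswim`, the assumptions
they make, the default parameters and why they were chosen, what the
synthetic-data generators do and do not emulate, and the numerical and
design decisions that were genuinely open.

## Respirometry

Oxygen in a sealed Blazka-style tunnel falls linearly while a fish of mass
M (g) respires at a constant rate; the mass-specific uptake is

    MO2 = |d[O2]/dt| · V / M      [µmol O2 g⁻¹ h⁻¹]

with V the tunnel water volume (L) and d[O2]/dt the slope of an
ordinary-least-squares line through the closed-phase record, time in hours
and oxygen in µmol L⁻¹. Only samples flagged `closed` enter the fit;
configurable leading/trailing trims (default 0 s) drop mixing artefacts.

**Solubility model.** Readings in percent air saturation are converted to
concentration with the Benson & Krause (1984) freshwater/seawater oxygen
solubility fit in the form standardised by the USGS (the DOTABLES
equation), including the moist-air barometric pressure correction. The
implementation is tested against published table values at 20, 25 and 28 °C
(9.092, 8.263, 7.827 mg/L at 1 atm; ≈244.6 µmol/L at the 28 °C working
temperature). Conversion is linear in %AS, so the choice of solubility
model scales all rates by a common factor but never changes curve shapes,
speed optima or any between-group statistics.

**Quality control.** A decline fit with r² below 0.9 (default) warns but is
retained — rejection is the analyst's call. At routine speeds the true
decline over a 20-min closed phase is shallow (a ~0.43 g fish at
~40 µmol g⁻¹ h⁻¹ in 1.8 L removes only ≈1 %AS), so under realistic sensor
noise per-trace r² is legitimately low while the slope itself — averaged
over ~600 samples — remains precise; the QC threshold is a flag, not a
filter. No electrode-drift or blank (microbial) respiration correction is
applied by default; an optional blank-slope subtraction is available and
flagged when used.

## Critical swimming speed

Stepped-velocity trials (defaults: 0.05 m/s increments, 600 s intervals)
end when the fish can no longer hold station; Brett interpolation gives

    U_crit = U_i + (T_i / T_ii) · U_ii.

The protocol fatigues each fish repeatedly (three events); the default
estimate scores the **first** fatigue event, with a `mean` policy available
— which event the original protocol scored is ambiguous, and the first
event is the one unconfounded by accumulated exhaustion. Relative speeds
always use standard body length (snout to caudal peduncle), not total
length. Ammeter currents convert to water speed through the linear motor
calibration (defaults 0.3257 cm s⁻¹ µA⁻¹, −1.238 cm s⁻¹); implied negative
speeds clamp to zero with a warning.

## Metabolic model and cost of transport

Oxygen uptake against speed is fitted per fish as a free-intercept
least-squares quadratic V̇O₂(U) = SMR + aU² + bU; the intercept is reported
as the standard metabolic rate. The **%U_crit axis is the default**: the
published group coefficients are only dimensionally consistent on that
axis, and normalising each fish's speeds by its own U_crit removes
between-fish performance variation before averaging. A cm/s axis is
supported by configuration. The measurement at 5% U_crit (minimal flow) is
the routine metabolic rate (RMR) and is excluded from the curve fit; V̇O₂max
is the measured uptake at the fastest step, not a curve value.

Cost of transport is V̇O₂ divided by speed. Two scales are reported side by
side, because no standard unit pairing reproduces an absolute COT of
~25 µmol g⁻¹ m⁻¹ at the optimum from these V̇O₂ magnitudes:

- the **curve scale** — V̇O₂ divided by the numeric speed on the chosen
  axis, the scale on which the group polynomial is expressed; and
- the **strict scale** — V̇O₂ divided by metres travelled per hour
  (µmol O2 g⁻¹ m⁻¹).

The vertex location is invariant to any constant rescaling of COT, so
U_opt is identical on both; only the COT_opt magnitude differs, and outputs
label which scale they carry. COT is never extrapolated below the slowest
measured speed (the 1/U divergence near zero is physical, not
informative).

U_opt and COT_opt come from the analytic vertex of a second quadratic
fitted to the (speed, COT) points, U_opt = −b₂/(2a₂), which is the global
minimum whenever a₂ > 0 (a₂ ≤ 0 is an error). A grid-search oracle over
[0, 120] at 10⁻³ resolution confirms the vertex in the test suite.
**Per-fish-first is the default policy**: curves are fitted per fish and
the derived quantities (SMR, U_opt, COT_opt) averaged as mean ± SEM
(sample SD, n−1, over √n). A pooled mode fits one curve through the
speed-wise mean V̇O₂ values; the two modes genuinely differ — the vertex of
a pooled curve sits a few %U_crit above the mean of individual vertices —
and both are reported.

## Growth statistics

Normality is screened with a one-sample Kolmogorov–Smirnov test against a
normal with the sample mean and SD; with estimated parameters the test is
conservative, and it is advisory only. The comparison battery is: unpaired
two-tailed Student t for baseline group equivalence, paired one-tailed t
for within-group change, unpaired one-tailed t for the final
swimmer-vs-rester contrast. One-tailed directions are **declared in the
design** (swimmers gain length and weight; resters lose weight), never
inferred from the data. Pooled-variance Student t is the default, Welch by
flag. All-zero paired differences return the degenerate limit t = 0,
one-tailed p = 0.5. Percent differences are 100·(A−B)/B on group means with
the rester group as reference; they are computed from the pipeline's own
inputs and are not comparable to figures derived from differently rounded
summary tables.

## qPCR expression

Triplicate wells are averaged arithmetically and flagged when the replicate
SD exceeds 0.5 cycles. ΔCt = Ct(target) − Ct(rps18) uses the rps18 well of
the **same primer set** (the panel spans two sets, A and B, with different
rps18 primers; cross-set normalisation is an error). Housekeeping stability
is checked first: a between-group difference in rps18 Ct at p < 0.05
(two-sided Mann–Whitney) flags the whole dataset.

Fold changes follow Livak with amplification efficiency fixed at 2.0 (no
standard-curve efficiencies are available; an efficiency-corrected mode
exists but is off by default): per swimmer j,
ΔΔCt_j = ΔCt_j − mean(rester ΔCt) and fc_j = 2^−ΔΔCt_j. Reporting is the
arithmetic mean ± SEM of the fc_j, the conventional presentation. The
group-mean form 2^−(ΔΔCt of group means) — equal to the geometric mean of
the fc_j — is carried alongside: fold changes are lognormal under Gaussian
Ct noise, so the arithmetic mean carries a small Jensen (convexity) bias
upward while the group form is unbiased on the log scale. For this reason
the Monte-Carlo *recovery* check averages replicate estimates
geometrically (equivalently, averages log₂ fc) and converts the SEM to the
fold-change scale by the delta method; with 500 replicates the Monte-Carlo
SEM is small enough that the arithmetic estimator's bias alone would
exceed it, which is a property of the estimator, not a defect of the
pipeline.

Outliers are screened per gene and group with an iterative two-sided
Grubbs test at α = 0.05, capped at two removals per gene per group, **on
the ΔCt scale** — where the Gaussian assumption of the test is plausible —
rather than on the lognormal fold changes. The critical value is
G = ((n−1)/√n)·√(t²/(n−2+t²)) with t the α/(2n) Student quantile at n−2 df,
verified against published tables (n=5 → 1.715, n=10 → 2.290). Samples
smaller than 4 are never screened. Grubbs is known to mask when several
comparable outliers coexist; the cap matches the most removals observed per
gene in practice.

Group differences use two-sided Mann–Whitney U on the ΔCt values: exact
null distribution for tie-free combined samples of at most 20, normal
approximation with tie correction otherwise. The exact p is verified in
the tests against full permutation enumeration for every group-size pair
up to 6×6.

## Synthetic-data generators

Every generator is a deterministic function of a `SyntheticTruth` and its
seed; per-fish streams are derived by hashing the fish id into the seed
tree (`SeedSequence(seed, spawn_key=crc32(key))`), so adding a fish never
perturbs another fish's data. Defaults are the study conditions: metabolic
curve (43.79, 0.0081, −0.4353) on the %U_crit axis, true U_crit 0.548 m/s,
2-s oxygen sampling in a 1.8 L tunnel at 28 °C with 0.5 %AS sensor noise,
0.05 m/s × 600 s stepped trials, cohort effects +0.18 cm TL/+0.10 g BW
(swimmers) vs 0/−0.07 g (resters) around baselines of ≈3.6 cm/0.41 g,
post-mortality group sizes 78/79, and a 14-gene panel with stable
housekeeping Ct 18, rester ΔCt baseline 7, triplicate noise SD 0.2 cycles
and programmed fold changes {ghrb 0.58, igf1ra 0.53, stnnc 3.47, smyhc1
3.60, tnni2 3.42, myhz2 7.92, mstnb 5.44}, all others 1. Baseline cohort
SDs (0.18 cm, 0.09 g) are back-computed from reported SEMs at n≈80; change
SDs (0.05 cm, 0.03 g) are set so within-group changes are overwhelmingly
significant at these n, as observed.

What the generators emulate: linear closed-phase declines with i.i.d.
Gaussian sensor noise; interpolation-exact fatigue times (plus optional
jitter); Gaussian morphometrics with paired structure; Gaussian Ct noise
with plate-stable housekeeping expression. What they do **not** emulate:
electrode drift and autocorrelated sensor noise, background respiration,
partial-interval habituation or refusal behaviour, non-Gaussian growth
(skew, shared tank effects), amplification-efficiency variation between
genes, or genuine biological between-fish expression variance beyond
triplicate noise. Passing recovery tests therefore demonstrate that the
estimators invert the stated measurement model — not that they are robust
to every artefact of real traces or plates.

## Problem sizes and runtime choices

The demo study simulates 10 economy fish × 5 speeds × 10-minute traces at
2-s sampling, a 78/79 cohort, and 8 + 8 qPCR fish — the sizes of the
experiments being modelled. The fold-change recovery runs 500 Monte-Carlo
replicates of the full plate-to-fc pipeline (a few seconds); property
tests use derandomised hypothesis profiles and exhaustive enumeration
only where the state space is tiny (Mann–Whitney up to 6×6).

## Known limitations

- The absolute COT magnitude depends on the chosen scale (see above); the
  strict µmol g⁻¹ m⁻¹ values are the physically interpretable ones.
- Grubbs screening assumes approximate normality of ΔCt and loses power
  under masking; it is a reproducible convention, not a robust method.
- The pooled group curve and the per-fish average answer slightly
  different questions; users should pick one a priori and report which.
- Exact Mann–Whitney p-values require tie-free data; heavy ties at small n
  fall back to the tie-corrected normal approximation, which is anti-
  conservative for very small samples.
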