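# Methods

## The discordance analysis

For a subject wearing a CGM sensor, the glucose management indicator
GMI(%) = 3.31 + 0.02392 × (mean glucose in mg/dL) converts average glucose
exposure to the HbA1c scale. Discordance is the signed gap
d = HbA1c − GMI for one *pair*: a laboratory HbA1c joined to the half-open
window [draw − 60 d, draw) of that subject's cleaned CGM trace. The draw
day itself is excluded (the assay reflects exposure *before* the draw);
windows of consecutive pairs may overlap, since repeat draws closer than
60 days apart are legitimate.

Cleaning removes duplicate timestamps (keeping the first occurrence, which
is deterministic under stable input order) and readings outside
[40, 400] mg/dL; the bounds themselves are physiologic sensor limits and
are retained. No interpolation is ever applied — dropout simply leaves
missing samples. A calendar day counts as *active wear* when it holds at
least 70 % of the expected samples (288 at 5-minute sampling, 96 at
15-minute); 70 % is the consensus CGM-reporting convention and is
configurable. A pair is eligible with ≥ 14 active days in its window, and
a subject enters the longitudinal analysis with ≥ 2 eligible pairs. The
window mean is the unweighted mean over all retained readings (matching
the GMI definition), not a day-weighted mean.

Pairs are phenotyped positive (d ≥ +0.5 %), negative (d ≤ −0.5 %) or
neutral. The boundary ±0.5 belongs to the positive/negative groups — the
inequality definitions take precedence over the informal "within ±0.5 %"
description of the neutral band. Longitudinal behaviour is summarised by:

* transition tables from the baseline (first-pair) group to the group at a
  later pair index, restricted to subjects actually observed at that
  index, so each row total is conserved;
* persistence (diagonal fraction of a row) and the reclassification rate
  over consecutive-pair transitions. The reclassification denominator
  restricts to transitions *originating* in the positive or negative
  groups; this is a genuine analytic choice (the alternative counts all
  origins) and the origin set is an argument of
  `reclassification_rate`;
* the Pearson correlation between days-since-baseline and |d| over all
  follow-up pairs (two-sided p from the t distribution with n − 2 df), a
  negative value indicating attenuation of discordance over time;
* Kruskal–Wallis H across baseline groups at each pair index, implemented
  explicitly (mid-ranks, tie correction 1 − Σ(t³−t)/(N³−N), chi-square
  reference) because the tie-correction factor is part of the reported
  result; post-hoc pairwise rank-sum tests use Bonferroni correction.

## The adjusted GMI

For every follow-up pair the regression predicts the current HbA1c from
the current GMI, the subject's discordance at the immediately preceding
pair, and the HbA1c of that preceding pair:

aGMI = β₀ + β₁·GMI + β₂·prior d + β₃·last HbA1c.

`GmiAdjuster` solves the least-squares problem by an explicit
column-pivoted QR factorisation; rank deficiency raises an error naming
the collinear columns, and standard errors come from the unbiased residual
variance. Rows are pooled across subjects with no random effects; optional
age/sex covariates are off by default (they carry no effect in the
generator, and the model surface mirrors an analysis in which they added
nothing). Agreement metrics are Pearson r, R² reported as the *squared
correlation* between prediction and observation (so r = 0.83 pairs with
69 %), and MAE. Cross-validated metrics assign folds at subject level —
never splitting one subject's repeated pairs across folds — from a seeded
permutation; both pooled out-of-fold and in-sample numbers are reported,
since either convention is defensible for a pooled regression.

The gain of aGMI over GMI is tested with the Meng–Rosenthal–Rubin z-test
for two dependent correlations sharing an outcome, with the f term capped
at 1 as in the test's original definition.

`GamLite` probes for nonlinearity: each predictor is expanded in a natural
cubic-spline basis (5 interior knots at quantiles, boundary knots at the
1st/99th percentiles, linear extrapolation beyond them) and fitted with a
ridge penalty chosen per outer fold by an inner 3-fold subject-level CV
over a fixed grid (0.01–100). It is deliberately a lightweight additive
spline model, not a full GAM with smoothing-parameter optimisation: its
role is a directional comparison against the linear model, and on linear
truth its cross-validated R² should not exceed the linear model's by more
than noise.

Note one structural fact: algebraically, last HbA1c = prior GMI + prior d,
so the three predictors are exactly collinear whenever GMI is constant
within subject. Real (and simulated) window means vary between visits,
which is what identifies β₃.

## The synthetic cohort

The generator's defaults are the reference study conditions; they are
fixed, not tuning knobs.

| parameter | default | meaning |
|---|---|---|
| `n_subjects` | 477 | cohort size |
| `visits_min..visits_max` | 2–5 | HbA1c draws per subject (uniform) |
| `gap_median_days`, `gap_log_sd` | 126, 0.58 | lognormal inter-visit gap |
| `gap_offset_coupling` | 0.22 | shortens gaps for large-\|δ\| subjects |
| `mean_glucose_mean/sd` | 163, 31 mg/dL | habitual mean glucose, truncated to [70, 300] |
| `sigma_window_mean` | 15 mg/dL | per-visit deviation of the 60-day window mean |
| `diurnal_amplitude` | 25 mg/dL | sinusoidal day profile (peak mid-afternoon) |
| `noise_sd`, `noise_tau_minutes` | 20 mg/dL, 60 min | mean-reverting AR(1) sensor/physiology noise |
| `sampling_interval` | 15 min | native sensor grid (5 also supported) |
| `wear_mean_days`, `dropout_mean_days` | 25, 4 | exponential wear/gap segment durations |
| `sigma_persistent` | 0.40 % | SD of the per-subject glycation offset δ |
| `sigma_transient` | 0.25 % | baseline SD of the visit-level offset ε |
| `tau_transient`, `transient_floor` | 180 d, 0.4 | ε decay timescale and stationary floor |
| `sigma_lab` | 0.10 % | HbA1c assay noise |

Observed HbA1c at visit j is GMI(window mean_j) + δ + ε_j + assay noise.
δ ~ N(0, σ_p) is the stable high/low-glycator offset. The transient is an
AR(1) anchored at baseline: ε₀ ~ N(0, σ_t), and
ε_j = e^(−Δt/τ) ε_{j−1} + η_j with innovation SD
(floor·σ_t)·sqrt(1 − e^(−2Δt/τ)), so ε's marginal SD decays from σ_t
toward floor·σ_t. Setting `transient_floor = 1` recovers the stationary
AR(1), in which the across-visit correlation of ε is exactly e^(−Δt/τ)
(this regime is what the correlation-decay test uses). The default floor
of 0.4 makes discordance magnitude genuinely attenuate with time from
baseline — a stationary transient cannot produce the observed negative
interval–|d| correlation, because its marginal is constant in time.

Two design choices were calibrated a priori, by closed form and small
Monte-Carlo runs, to place the default cohort near its structural targets
and then frozen: (i) the baseline offset SDs give first-visit
P(|d| ≥ 0.5) = 2Φ(−0.5/0.483) ≈ 0.30; (ii) `transient_floor`, `tau_transient`
and `gap_offset_coupling` jointly put the follow-up interval–|d| correlation
near −0.17. The coupling shortens the visit interval for subjects with a
large persistent offset (median gap ≈ 93 d one SD above the mean of |δ|,
≈ 170 d below), mirroring clinical scheduling: out-of-target patients are
re-tested sooner. It is centred so the overall median gap stays at 126 d;
the realised IQR (≈ 85–190 d) is slightly narrower than the 90–196 d
target and we accept that.

In full-fidelity mode the CGM trace level is a step function: each
inter-visit stretch runs at the *next* visit's true window mean, so any
60-day window that fits inside its stretch realises that mean exactly up
to sensor noise. When a gap is shorter than 60 days (≈ 10 % of gaps) the
window straddles a step and the recovered discordance absorbs a small
blending error; the recovery report budgets this (RMSE tolerance 0.15 %).
The visit-level mode (`simulate_visits` / `visits_to_pairs`) skips trace
synthesis and uses the true window means directly — identical offset
model, ideal wear — and is what replicated studies of the downstream
statistics use.

What the generator does **not** emulate: meals, insulin dynamics and
hypoglycaemic excursions (glucose is a stationary sinusoid-plus-AR
process); device-specific error models and calibration drift; assay method
differences between laboratories; informative dropout (wear gaps are
independent of glycaemia); and any real-world relationship between
demographics and discordance (age/sex are carried but inert). Passing
tests therefore demonstrate that the *pipeline machinery and statistics*
behave correctly under the assumed data-generating structure — not that
the structure itself, or any cohort-level headline number computed from
real registries, is reproduced. Synthetic results are systematically
cleaner than real ones (e.g. adjusted r ≈ 0.98 here, because the
persistent offset is exactly linear and the noise exactly Gaussian).

## Numerical and procedural choices

* Problem sizes: the reference cohort is 477 subjects (~1,600 eligible
  pairs, ~18 M CGM samples at 15-minute sampling) and runs end to end in
  well under a minute; replicated property studies use visit-level cohorts
  of 60–400 subjects × 50–100 seeds, and exhaustive small-sample checks
  (Kruskal–Wallis vs a rank-counting oracle) enumerate all two-group value
  tuples over {1, 2, 3} up to total size 8.
* All randomness flows from a single integer seed per run (simulation,
  fold assignment, ridge selection); identical config + seed gives
  byte-identical artifacts.
* Degenerate inputs are signalled, not silently absorbed: zero-variance
  correlations, empty transition rows, rank-deficient designs, inverted
  windows and single-group rank tests all raise with a description. A
  fully noiseless simulation makes the prior-discordance predictor
  constant, so the regression is rank-deficient by construction; the
  pipeline handles that case with the published default coefficients.
* Ties in Kruskal–Wallis use mid-ranks; an all-identical pooled sample has
  an undefined H (0/0 tie correction) and is reported as H = 0, p = 1.
* p-values are reported to machine precision; 0.05 is the nominal
  significance threshold wherever one is needed.

## Known limitations

* The pooled regression ignores within-subject correlation of repeated
  pairs; standard errors are slightly optimistic. Subject-level CV guards
  the predictive claims but not the inferential ones.
* GAM-lite's fixed knot count and penalty grid are adequate for a
  directional comparison, not for smooth-function estimation.
* The discordance phenotype thresholds (±0.5 %, ±1.0 %) are conventions
  carried as arguments, not biologically derived quantities.
* `active_days` uses calendar days in the trace's local clock; shift
  workers or travel across time zones would blur day boundaries.
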