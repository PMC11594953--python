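# Methods

## Instruments and scoring

The long form is the 12-item Partners in Health (PIH) questionnaire, each
item an integer 0–8 (8 = best). Domain subtotals are plain sums: K = items
1–2, P = items 3–6, M = items 7–8, C = items 9–12, with composites
KC = K + C, PM = P + M and the 96-point total. Missing items are rejected,
never prorated or imputed: the instrument's published scoring defines no
imputation rule, and silently filling a patient-reported item would change
the category a patient lands in.

### Banding

Each scale maps to four ordinal categories (0 good … 3 poor) by closed
integer intervals. The published cut-off rows overlap at two points — a
16-point score of exactly 6 sits in both the borderline ("6–8") and poor
("≤ 6") rows, and a 32-point score of exactly 20 in both average and good.
We resolve best-first: bands are evaluated good, then average, then
borderline, then poor, so the better category keeps its printed lower
bound. The effective intervals are

| scale | good | average | borderline | poor |
|---|---|---|---|---|
| 16 | ≥ 12 | 9–11 | 6–8 | ≤ 5 |
| 32 | ≥ 20 | 17–19 | 12–16 | ≤ 11 |
| 48 | ≥ 30 | 24–29 | 18–23 | ≤ 17 |
| 96 | ≥ 56 | 49–55 | 41–48 | ≤ 40 |

This choice makes the partition property testable (every integer score has
exactly one category) and treats the "≥" upper edges as closed. The tables
are data (`data/banding.yaml`), re-validated on load, so a different
resolution of the ambiguity needs no code change.

### Short form and the LF→SF mapping

The short form is three binary nurse judgements summing to a 0–3 risk
score. Two published descriptions of its long-form shadow differ: one
lists per-domain pass marks (> 8/16, > 16/32), the other defines the
domains on the composites KC and PM. We default to the **composite** rule —
Ma passes iff KC > 24, Mx iff PM > 24, Mse iff total > 48, all strict —
because the composite definition is the one the study's result tables use;
the conjunctive per-domain variant (Ma iff K > 8 and C > 16, etc., strictly
harder to pass) is selectable via `mapping="conjunctive"`. Strictness
matters at the boundary: a total of exactly 48 fails self-efficacy. By
construction a long-form-poor patient (total ≤ 40) can never derive a good
short form, and raising any item never raises short-form risk.

The cohort carries both the nurse-scored assessment (the instrument as
fielded) and the derived equivalent; every analysis takes
`sf_source="nurse"` or `"derived"` explicitly.

## Contingency statistics

The good-vs-poor readmission analysis uses the uncorrected Pearson
χ² = n(ad−bc)²/(r₁r₂c₁c₂) at one degree of freedom. No Yates continuity
correction by default: on the study-shaped table [[5,8],[31,7]] the
uncorrected statistic is 8.674 whereas the corrected one is 6.72, and only
the former matches the published two-significant-figure value (8.69; the
residual 8.67 vs 8.69 gap is treated as upstream software rounding and not
reverse-engineered). The correction is available behind a flag. A zero
margin raises with advice to use the exact test.

The exact test enumerates every 2×2 table with the observed margins and
sums hypergeometric probabilities no larger than the observed table's
(relative tolerance 1e-10 against float ties) — the standard two-sided
Fisher construction. Note the two tests can disagree near a threshold: on
the table above the exact p is 0.0106, so at α = 0.01 the χ² rejects and
the exact test does not; both reject at 0.05.

Category distribution moments use the sample (n−1) standard deviation; on
the study's short-form counts the population SD (1.038) happens to round
to the same 1.04, so the choice is documented rather than consequential.

## Validity fits

Concurrent validity: OLS of the long-form total on the short-form score,
adjusting for age, sex (male = 1, female = 0) and comorbidity count (kept
as an integer covariate, not banded). Predictive validity: the same design
with the 12-month composite event count (unplanned CV + HF admissions +
death) as outcome, fitted as a linear count model for transparency rather
than a Poisson family — at cohort sizes around 100 the linear fit's
coefficient and CI are the quantities of interest and keep the two validity
stages directly comparable. Standard errors are conventional homoskedastic
OLS; p values two-sided; CIs at 95%. Rank-deficient designs raise an error
naming a collinear column. The study's published coefficients (−14.692
concurrent, −1.327 predictive) depend on its raw per-patient data, which
are not deposited; they are out of reproduction scope, and the machinery is
instead validated by parameter-recovery and CI-coverage simulations.

## Synthetic cohorts

One latent self-management trait z ~ N(0, trait_sd) per patient drives
everything observed:

* **Items**: `clamp(round(4 + item_loading·z + ε_j), 0, 8)` with
  independent ε_j ~ N(0, item_noise_sd²) per item — a single-factor model,
  the simplest structure consistent with correlated domains; no per-domain
  factor structure is claimed. Defaults item_loading = 1.0,
  item_noise_sd = 1.5, trait_sd = 1.0 put the 96-point total near
  N(48, 13²), matching the study total's location and scale (47.55,
  SD 12.7) before clamping.
* **Nurse short form**: the derived LF equivalent with each binary domain
  flipped independently with probability `nurse_flip_prob` (default 0.1 —
  the study reports no misclassification rate; a small nonzero default
  keeps nurse/derived discordance present, as observed between the fielded
  instruments).
* **Outcomes**: drawn conditional on the *nurse* category — the study's
  stratification variable — with admission-composite probabilities
  (5/13, ·, ·, 31/38), the middle two linearly interpolated (the study
  reports no intermediate-category rates; flagged as an assumption).
  Death probabilities (0, ·, ·, 4/38) likewise. Death is drawn as a
  sub-event of the composite, so death implies a composite event, the
  marginal death rate is preserved, and stratifying the pipeline by nurse
  category recovers the conditional rates exactly in expectation.
  Admission counts among event patients are 1 + Poisson(1.0) (Poisson for
  the deceased), split into HF vs other CV admissions at 45%, roughly the
  study's HF share of CV readmission reasons.
* **Demographics**: age N(66.8, 13.5²) clipped to 18–100, 75% male,
  comorbidity counts drawn from the study's banded distribution.
  Appointments, renal labs and side-effect flags are generated at
  clinically plausible levels (per-appointment miss probability 0.12→0.32
  across categories, reproducing an FTA rate near the study's 34%) and are
  carried mainly as pass-through fields.

Seeding: one master seed spawns an independent substream per patient
(`numpy` `SeedSequence.spawn`), so cohorts are reproducible under partial
regeneration — extending n never changes earlier patients.

`calibrate_to_margins` inverts latent-normal quantiles so expected
short-form category proportions hit target counts exactly; a calibrated
parameter set assigns nurse categories directly from trait thresholds
(low trait = high risk), decomposing a category total into domains in the
order self-efficacy, self-maintenance, self-tailoring (most stringent
fails first). In calibrated mode the nurse score is no longer the derived
equivalent, so the ε = 0 round-trip applies only to the default path.

**What the generator does not emulate**: the joint distribution of domain
scores (published marginal means/SDs imply skew the symmetric item model
does not reproduce — calibration targets category counts, not domain
moments), ethnicity/medication/NYHA/depression covariates beyond labels,
visit-level longitudinal structure, and informative loss to follow-up.
Passing tests therefore show the *pipeline* is correct under the stated
generative assumptions, not that the study's raw data would reproduce.

## Numerical and design choices

* Likert responses and all banded scores are validated as integers;
  non-integer or out-of-range values raise naming the item/row/column.
* Problem sizes: property suites run at 100–200 random cases; pipeline
  recovery and agreement checks use cohorts of 2,000–5,000 patients, where
  binomial noise on a rate is below ±0.02 — small enough to separate the
  category-conditional rates cleanly.
* The acceptance script derives its generator seed from `--seed` modulo
  2³¹ and touches no network or external data.

## Known limitations

* The intermediate-category outcome rates are interpolation assumptions;
  any inference about average/borderline patients from synthetic data
  reflects that assumption, mirroring the study's own silence on those
  groups.
* The exact test enumerates the hypergeometric support directly; for the
  cohort sizes here (margins ≤ a few thousand) this is instant, but it is
  not the right tool for very large tables — use the χ².
* The linear predictive-validity model treats a small count outcome as
  continuous; with larger cohorts or rarer events a Poisson/negative
  binomial family would be preferable.
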