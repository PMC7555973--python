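# Methods

## Scoring model

The analysis treats a study as a judges × targets × traits cube of Likert
ratings plus a targets × traits criterion matrix on the same 1–5 scale.
Criteria from instruments with other ranges are mapped affinely from the
instrument's *theoretical* range, `1 + 4·(x − min)/(max − min)`; we use the
theoretical rather than the observed sample range so that a target's
standardized score does not depend on which other targets happened to be
sampled. Ratings a judge gave to targets they know are treated as missing
throughout, exactly like absent cells.

Three per-judge indices are computed:

* **Trait accuracy.** For each trait × modality cell, the Pearson
  correlation across that modality's targets between the judge's ratings
  and the criteria. Cells, and all other component correlations, are
  undefined (never 0) when fewer than 3 complete pairs remain or either
  vector is constant. The 24 cells are Fisher-z averaged; subscores
  average a trait's 3 modality cells or a modality's 8 trait cells.
* **Overall profile accuracy.** Per target, the correlation across traits
  of rating profile vs criterion profile; Fisher-z averaged over the 30
  targets, with modality subscores over each modality's 10 targets.
* **Distinctive profile accuracy.** As above after subtracting the
  normative rating profile (grand mean per trait over all judges and
  targets) and the normative criterion profile (mean per trait over all
  targets). Normative profiles are always computed on the full sample and
  full target set, including inside modality and gender-restricted
  subscores, so that every restricted score measures sensitivity to the
  same distinctive signal. The judge being scored is included in the
  normative rating profile by default (an `exclude_self` option exists;
  with ~120 judges the difference is negligible, which a test verifies).

**Aggregation and missingness.** Fisher z = artanh(r) stabilizes variance
before averaging; |r| is clipped to 0.999 first because a single perfect
correlation would otherwise contribute an infinite z (the clip constant is
configurable). An aggregate is missing unless defined components / total
components ≥ `min_prop` = 0.8 — equivalently at least 20 of 24 cells and
at least 24 of 30 profiles. The same proportional rule is applied to every
subscore; the source procedure states it only for totals, so extending it
to subscores is this package's choice (the alternative — no gate on
subscores — would report subscores built from as little as one cell).
Undefined components count against availability rather than entering as
zeros.

**Inference.** One-sample Student t tests compare each index to the
chance level 0; same-gender comparisons (male judges on male targets vs
female judges on female targets) use the pooled-variance two-sample t,
whose integer degrees of freedom match the conventional reporting of this
design. Associations with external measures use Spearman rank
correlations (accuracy and test-score distributions in this paradigm are
typically non-normal); p values are two-sided and no multiplicity
correction is applied, mirroring standard practice in this literature.

**Reliability.** Trait accuracy: Cronbach's α across judges over the 24
Fisher-z cells, complete-case. Profile indices: the named estimator in the
source literature is a package, not a formula, so we define replicability
explicitly as repeated random split-half over targets — per split, average
each judge's z within each half, correlate the half-scores across judges,
step up with Spearman–Brown 2r/(1+r); report the mean of 200 seeded
splits. A mandatory seed makes the estimate exactly reproducible.
Disattenuation divides an observed correlation by √(rel_x·rel_y);
reliabilities of the external instruments are user inputs (defaults .89 /
.78 / .93 for the emotion-recognition, emotion-understanding and trait-EI
instruments' published internal consistencies) because item-level data are
out of scope. Corrected values can exceed 1; they are reported as-is with
a warning flag. Index reliabilities outside (0, 1] cannot be used for
disattenuation and skip the correction with a warning.

## Synthetic studies

The generator produces the design the analysis assumes: default 121
judges, 30 targets in three modality blocks (photo, muted video, video
with sound) of 10 targets (5 male, 5 female), 8 traits.

* criterion(t, a) = clip(normative(a) + δ(t, a), 1, 5), δ ~ N(0, σ_d²)
* rating(j, t, a) = normative(a) + w_j · m(t) · δ(t, a) + ε,
  ε ~ N(0, σ_noise²), then clipped to [1, 5] and (by default) rounded to
  the integer Likert grid — clipping before rounding
* w_j = w0 + (1 − w0) · θ_j, θ_j a [0, 1]-truncated normal ability with a
  mean shift for female judges
* each judge–target pair is flagged "acquainted" with probability
  34/3630 ≈ .0094, reproducing the rare acquaintance missingness of the
  reference design
* the emotion-recognition score is a noisy linear readout of θ on the
  0–100 percent scale; the other two external scores are independent of θ

One master seed spawns named substreams for targets, judges and ratings,
so enlarging the judge sample never perturbs the target draws and
identical seeds give bit-identical studies.

**Parameter defaults and why.** σ_d = 0.7 gives criterion trait SDs
across targets of ≈ 0.7 on the 1–5 scale, matching target pools
preselected for trait variance. σ_noise = 1.2 with Likert rounding makes
single ratings weakly informative, as they are empirically. Ability mean
.12 / SD .15 with w0 = .03, modality multipliers (0.5, 1.0, 1.1) for
photo / muted video / audio video, and a normative profile with spread
≈ 0.10 were calibrated once so that the three index totals land in the
.05–.15 band this paradigm typically produces, photo is the weakest
channel, and latent ability is recoverable (Spearman of θ with trait
accuracy ≈ .6 at 100 judges). The gender ability gap of 0.1 (attenuated
to ≈ .07 by truncation) yields a female advantage of the conventional
small-to-moderate size. A `null()` configuration variant sets ability and
w0 to zero and flattens the normative profile, which makes the expectation
of *all three* indices exactly zero — the flat normative profile matters,
because a shared normative component alone already produces positive
overall profile accuracy.

**What the simulator does not emulate.** Judges differ only in one
scalar ability (no trait-specific skills, no idiosyncratic stereotype
profiles, no response styles such as extreme or acquiescent responding);
targets differ in expressivity only through modality, not individually;
criterion error is absent (self-reports are taken as truth). Passing
tests therefore show that the pipeline recovers what this model encodes,
not that real judges behave this way.

## Numerical choices

* Correlations over fewer than 3 complete pairs or with a zero-variance
  vector are undefined, and aggregates inherit missingness via the
  availability rule; nothing is silently imputed.
* Fisher clip 0.999 (≈ z = 3.8) bounds the influence of perfect
  correlations; results are insensitive to the constant because clipping
  binds only in degenerate, near-noiseless data.
* Cronbach's α uses complete-case rows and sample (n−1) variances.
* Spearman is Pearson on mid-ranks (ties averaged), so tied data are
  handled identically to the conventional definition.
* The report rounds to 2 decimals; `report.json` keeps full precision,
  and the rendered text is a pure function of the JSON, so a report read
  back from disk renders identically.

## Problem sizes used in the checks

The packaged verification runs use one default-size study (121 judges)
for the structural report check, 500 simulated judges for the
signal-free null, 1000 replicates of n = 115 for the t-test type-I-error
rate, and 20 seeds × 100 judges for ability recovery; oracle-equivalence
checks compare ≥ 1000 random small instances per primitive against
brute-force loop implementations at 1e−10.

## Known limitations

* The split-half replicability estimator is this package's explicit
  definition of profile-score reliability; other estimators (e.g.
  item-level α over per-target z, or other software's conventions) will
  give somewhat different values on the same data.
* Disattenuation with low reliabilities is unstable and can exceed 1;
  values are flagged, not truncated.
* Gender handling is binary in the pairing analyses because the design
  crosses judge gender with target gender; judges with other labels are
  retained in all non-gendered analyses.
* The trait axis is ordered alphabetically on CSV read; criteria and
  ratings are aligned by label, so axis order never affects results.
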