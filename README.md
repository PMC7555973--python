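# persacc

Scoring, reliability and simulation for **personality judgment accuracy**
studies — designs in which judges rate a set of unacquainted target
individuals on several traits (e.g. the Big Five plus cooperativeness,
empathy and intelligence) from photos or short videos, and each rating is
scored against the target's own criterion score (self-report scales or an
objective reasoning test), all standardized to the same 1–5 scale.

The package is for researchers in interpersonal accuracy / impression
formation who want the standard accuracy indices computed reproducibly
from long-format rating tables, together with their reliabilities,
significance tests and attenuation-corrected correlations with external
ability measures (e.g. emotion recognition tests).

## The indices

For judge *j* with ratings *R<sub>jta</sub>* (target *t*, trait *a*) and
criteria *C<sub>ta</sub>*:

- **Trait accuracy** — for every trait × exposure-modality cell, the
  Pearson correlation across that modality's targets between
  *R<sub>j·a</sub>* and *C<sub>·a</sub>* (inter-target discrimination).
  With 8 traits and 3 modalities this gives 24 correlations per judge,
  which are Fisher *z* transformed and averaged into one total
  (back-transformed with tanh).
- **Overall profile accuracy** — for every target, the correlation across
  traits between the judge's rating profile *R<sub>jt·</sub>* and the
  criterion profile *C<sub>t·</sub>* (intra-target discrimination); the
  per-target correlations are Fisher-*z* averaged.
- **Distinctive profile accuracy** — the same after subtracting the
  normative profiles: the grand mean rating per trait (over all judges and
  targets) from ratings, and the mean criterion per trait (over all
  targets) from criteria. This removes the credit a judge gets for merely
  attributing the *typical* profile to everyone.

An aggregate is reported only if at least 80% of its component
correlations are defined (≥ 20 of 24 cells; ≥ 24 of 30 profiles); a
correlation is undefined when fewer than 3 complete pairs remain or a
vector is constant, and undefined components count against availability.
Reliability is Cronbach's α over the 24 Fisher-*z* cells (trait accuracy)
or a seeded repeated split-half of targets stepped up with Spearman–Brown
(profile indices). Observed Spearman correlations *r* with external tests
are disattenuated as *r* / √(rel<sub>x</sub> · rel<sub>y</sub>).

The simulator generates studies with the matching generative structure —
criterion = normative profile + target-specific deviation δ, rating =
normative profile + *w<sub>j</sub>* · *m(t)* · δ + noise, with judge
ability θ driving the distinctive pickup *w<sub>j</sub>* and modality
multipliers *m(t)* — plus Likert rounding, rare acquaintance-driven
missingness and ability-linked external test scores. Latent θ and δ are
returned for recovery tests.

## Worked example

```python
from persacc import SimulationConfig, simulate_study, JudgmentAccuracyModel

study = simulate_study(SimulationConfig(seed=7))        # 121 judges, 30 targets
model = JudgmentAccuracyModel(study.cube, study.criteria, study.judges)
results = model.fit(reliability_seed=7)
print(results.summary())
```

prints (excerpt):

```
Descriptives
--------------------------------------------------------------------
measure                     mean      sd     n
trait_accuracy              0.10    0.11   121
overall_accuracy            0.13    0.10   121
distinctive_accuracy        0.11    0.11   121
era                        65.14    9.01   121

One-sample t tests against zero
--------------------------------------------------------------------
trait                   t(120) = 10.511, p = 0.0000
overall                 t(120) = 13.510, p = 0.0000
distinctive             t(120) = 10.978, p = 0.0000
```

Mean accuracies around .10 say that judges discriminate targets (and
trait patterns within targets) reliably better than chance but far from
perfectly — the typical order of magnitude for this paradigm. The t tests
reject the chance-level (zero) hypothesis for all three indices. The full
report adds trait and modality subscores, gender-pairing means with pooled
t tests, Spearman correlations with the external measures, reliabilities
and disattenuated correlations. `results.scores` is the per-judge table;
`results.report()` the full-precision JSON form.

The same pipeline runs from the shell:

```bash
persacc simulate --seed 7 --out-dir study/
persacc score --ratings study/ratings.csv --criteria study/criteria.csv \
              --targets study/targets.csv --judges study/judges.csv \
              --out-dir results/
persacc recovery --seed 7 --n-seeds 5
```

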