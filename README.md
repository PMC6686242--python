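# adatier

Tiered anti-drug-antibody (ADA) immunogenicity assessment for therapeutic
monoclonal antibodies, built around the analysis used for pembrolizumab
(anti–PD-1) clinical programs. It is aimed at quantitative pharmacologists
and biostatisticians who need to run — or stress-test — the standard
clinical immunogenicity pipeline without access to clinical data: the
package pairs the full rule set with a synthetic cohort simulator so every
step is executable and testable at desk scale.

## What it implements

**Sample level (3-tier assay).** Each serum sample passes through
screening (tier 1: reactive iff signal ≥ screening cut point),
confirmation by drug competition (tier 2: positive iff fractional
inhibition ≥ confirmatory threshold), and titer determination (tier 3:
titer = reciprocal of the highest reactive serial dilution). Circulating
drug interferes with the assay above a vendor-specific drug tolerance
level (DTL; 25 µg/mL at vendor 1, 124 µg/mL at vendor 2).

**Patient level.** A patient with a pretreatment and ≥ 1 postdose sample
is *assessable* and classified as

- **positive** if any sample is tier-2 confirmed positive,
- **inconclusive** if all samples are negative but the drug concentration
  of the last postdose sample exceeds the DTL (a negative result the assay
  could not support),
- **negative** otherwise.

Positive patients are **treatment-emergent (TE)** when the baseline is
negative and any postdose sample is positive, or when a positive baseline
titer is boosted at least *f*-fold (default *f* = 2; the conventional
4- and 9-fold rules are one configuration switch away):

```
TE  ⇔  (pre −  ∧  ∃ post +)  ∨  (pre +  ∧  max_t titer_post(t) ≥ f · titer_pre)
```

TE and non-TE positives are each split into NAb-positive / NAb-negative
by the neutralizing-antibody assay run on confirmed-positive samples.
Incidence percentages use the *evaluable* count (negative + positive) as
denominator.

**Simulation.** Cohorts are generated with the study's sampling schedule
(baseline; predose at cycles 2, 4, 8, …; end of treatment; follow-up at
1/3/6 months), the four regimens (2 mg/kg Q3W, 10 mg/kg Q2W, 10 mg/kg
Q3W, 200 mg Q3W), one-compartment superposition PK troughs
C(t) = Σ (D/V)·e^(−(CL/V)(t−t_d)), latent ADA onset/titer dynamics, and a
rational interference curve 1/(1 + C/S) that suppresses the true ADA
signal at high drug concentration — the mechanism that produces
inconclusive patients. Latent truth is recorded for recovery testing.

**Reporting.** Stratified incidence tables (by regimen, by indication,
pooled), adverse-event summaries by ADA category (drug-related AEs and
the eight-preferred-term infusion-reaction definition), per-visit
exposure summaries, and best-percent-change tumor summaries.

## Worked example

```python
from adatier import CohortConfig, classify_cohort, generate_cohort, incidence_table

cfg = CohortConfig(n_patients=500, seed=42)
patients, truth = generate_cohort(cfg)
statuses = classify_cohort(patients, cfg.assay)
print(incidence_table(statuses, patients, stratify_by="treatment").to_text())
```

prints

```
                                 2 mg/kg Q3W 10 mg/kg Q3W/Q2W   200 mg Q3W All treatments
Assessable patients                      141              146          213            500
Inconclusive patients                     23               55           35            113
Evaluable patients                       118               91          178            387
Negative                         114 (96.6%)       85 (93.4%)  166 (93.3%)    365 (94.3%)
Non-treatment-emergent positive     2 (1.7%)         4 (4.4%)     7 (3.9%)      13 (3.4%)
  Neutralizing negative             2 (1.7%)         4 (4.4%)     6 (3.4%)      12 (3.1%)
  Neutralizing positive                    0                0     1 (0.6%)       1 (0.3%)
Treatment-emergent positive         2 (1.7%)         2 (2.2%)     5 (2.8%)       9 (2.3%)
  Neutralizing negative             1 (0.8%)         1 (1.1%)     5 (2.8%)       7 (1.8%)
  Neutralizing positive             1 (0.8%)         1 (1.1%)            0       2 (0.5%)
```

Of 500 simulated patients all are assessable; 113 finish with residual
drug above the DTL and no positive sample, hence inconclusive; the 387
evaluable patients split into negative / non-TE / TE columns whose
percentages use each column's evaluable count as denominator. The latent
truth table for this seed contains 9 TE and 13 pre-existing positives —
exactly the patients the classifier recovered. The same pipeline runs
from the shell:

```bash
adatier simulate --seed 42 --n 500 --out sim/
adatier classify --samples sim/samples.csv --patients sim/patients.csv --out cls/
adatier summarize --status cls/status.csv --patients sim/patients.csv \
    --ae sim/ae.csv --by treatment --out tables/
```

## Layout

- `adatier.assay` — tier-1/2/3 sample logic, assay configuration, DTL.
- `adatier.classify` — patient records and the assessable / inconclusive
  / negative / positive / TE / NAb classification.
- `adatier.simulate` — cohort simulator and deterministic count fixtures.
- `adatier.report` — incidence, AE, exposure and tumor summaries.
- `adatier.io`, `adatier.cli`, `adatier.plots` — CSV/YAML I/O, the
  `adatier` command line, and figures.

See `docs/methods.md` for the modeling assumptions, parameter defaults
and known limitations.
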