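# pewrisk

Scoring and validation tools for a six-component protein-energy-wasting
(PEW) risk score in maintenance hemodialysis patients, for nephrology and
dialysis-unit analysts who want to apply the score to their own cohorts or
audit its published multicenter validation.

## The score and its validation

PEW — depletion of protein and energy stores driven by uremia, inflammation
and dialysis itself — is common in hemodialysis populations and predicts
hospitalization and death. The score summarizes six routinely collected
markers, each banded 0–3 by severity:

| Component | 0 | 1 | 2 | 3 |
|---|---|---|---|---|
| BMI (kg/m²) | ≥20 | 18–<20 | 16–<18 | <16 |
| Functional capacity | normal | occasional difficulty | dependent difficulty | bed/chair-bound |
| Years on HD | <1 | 1–<3 | 3–4 | >4 |
| Serum albumin (g/L) | ≥35 | 32–<35 | 28–<32 | <28 |
| Serum ferritin (µg/L) | ≤700 | >700–800 | >800–1000 | >1000 |
| Comorbidity count* | ≤1 | 2 | 3 | ≥4 |

\*among diabetes mellitus, hypertension, ischemic heart disease, and
cerebrovascular disease.

The total T = Σ components ∈ [0, 18] is dichotomized at T ≥ 6 into low/high
risk. Validation cross-tabulates each factor (sex, marital status, the
comorbidities, EPO use) and each outcome (vascular admission, non-vascular
admission, death) against the risk group and reports, per 2×2 table
(a, b; c, d):

- odds ratio OR = ad / bc,
- the Woolf 95% interval exp(ln OR ± z·√(1/a + 1/b + 1/c + 1/d)),
- the Pearson chi-square test Σ (O − E)²/E (r×k for the 3-level marital
  table, where an OR is not applicable).

A synthetic cohort generator reproduces the published cohort's marginal
band frequencies and lab moments, with a configurable logistic
score→outcome model (logit p = α + β·T), so the whole pipeline is testable
end to end without patient data.

## Worked example

```python
import pewrisk as pr

cohort = pr.generate(pr.SimulationConfig(n=868, seed=7))   # synthetic
report = pr.run_validation(cohort)
print(f"n={report.n}  low={report.group_sizes['low']}  high={report.group_sizes['high']}")
print(f"score range {report.score_min}-{report.score_max}")
est = next(r for r in report.outcomes if r.name == "death").estimate
print(f"death OR {est.odds_ratio:.3f} (95% CI {est.ci_low:.2f}-{est.ci_high:.2f}), "
      f"chi2={est.chi2_stat:.1f}, p={est.p_value:.2e}")
```

prints

```
n=868  low=382  high=486
score range 0-14
death OR 2.845 (95% CI 1.90-4.26), chi2=27.4, p=1.69e-07
```

i.e. in this synthetic cohort 486 of 868 patients score ≥6, and high-risk
patients have 2.8 times the odds of death — the association the generator's
default death model (log-odds +0.30 per score point) induces. Scoring is
also available as a scikit-learn estimator:

```python
scorer = pr.HashmiScorer(threshold=6).fit(cohort.data)
scores = scorer.transform(cohort.data)   # six components + total per patient
risk   = scorer.predict(cohort.data)     # "low" / "high"
```

The published aggregate tables ship as fixtures and their statistics
recompute exactly:

```python
stats = pr.fixture_statistics()
stats["gender"]   # OR 1.757 (95% CI 1.34-2.30)
```

A CLI wraps the same pipeline:

```
pewrisk simulate --n 868 --seed 7 --out cohort.csv
pewrisk score    --input cohort.csv --out scores.csv
pewrisk validate --input cohort.csv --out report.md
pewrisk fixtures --out fixtures.json
```

## Layout

- `pewrisk.scoring` — component scorers, `HashmiScorer`, quarterly aggregation
- `pewrisk.bands` — the band grid and YAML config
- `pewrisk.contingency` — OR, Woolf CI, chi-square, row percentages
- `pewrisk.io` — cohort CSV round-trip with data-dictionary validation; packaged fixtures
- `pewrisk.simulate` — synthetic cohorts and the parameter-recovery harness
- `pewrisk.pipeline` — stratify / cross-tabulate / test / render reports
- `pewrisk.cli` — the `pewrisk` command

See `docs/methods.md` for modelling assumptions and design choices.
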