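# Methods

## The score

Six components — BMI, functional capacity, hemodialysis vintage, serum
albumin, serum ferritin, and the count of comorbidities among diabetes,
hypertension, ischemic heart disease and cerebrovascular disease — are each
banded into 0–3 points by severity and summed to a total in [0, 18]. The
total is dichotomized at a configurable threshold (default 6, the validated
cutoff): low risk below, high risk at or above.

### Band-edge resolution

The published band grid leaves gaps and one overlap when read literally
("18–19.9" vs "≥20"; "≥35" vs "32–35"; "28–31" vs "32–35"; "<700" vs
"701–800"; "801–1,000"). The package resolves them with half-open intervals
that partition the whole positive axis while preserving every printed
anchor value:

- BMI and albumin: the boundary belongs to the less-severe side, so
  BMI 20.0 → 0, BMI 18.0 → 1; albumin 35.0 → 0 (the overlap at exactly 35
  resolves in favor of the better score), 32.0 → 1, and the 31/32 gap is
  closed by extending the 2-point band to [28, 32).
- Ferritin: the boundary belongs to the lower band, so 700 → 0,
  (700, 800] → 1, (800, 1000] → 2, >1000 → 3; the printed 700/701 and
  800/801 gaps close onto the band above.
- Vintage: read literally, "1–<3" excludes 3 and ">4" excludes 4, so the
  middle band is closed at both ends: [3, 4] → 2.
- Comorbidity count 0 lies below the least-severe printed band (which
  starts at 1) and scores 0.

Whether a patient with albumin exactly 35 g/L was scored 0 or 1 in the
original study cannot be determined from the printed bands; 0 is the
package default and the band edges are YAML-configurable.

### Quarterly aggregation

Scores were recorded quarterly in the validation study, but the study does
not state which quarterly score stratified a patient for the two-year
outcome comparison. The package default is the component-wise **maximum**
across quarters — the most conservative screening rule (a patient flagged
in any quarter stays flagged); `baseline`, `latest` and `mean_rounded`
policies are selectable. Note the component-wise maximum can exceed every
single-quarter total. Missing scoring inputs always raise an error naming
the field; a risk score silently computed on partial data would be unsafe,
so there is no imputation.

## Contingency statistics

Each factor level and each outcome is cross-tabulated against the risk
group. For 2×2 tables (a, b; c, d):

- OR = ad/bc;
- Woolf interval: exp(ln OR ± z₁₋ₐ/₂ · √(1/a + 1/b + 1/c + 1/d)). The
  original report does not name its interval method; Woolf's log-OR
  interval reproduces every printed interval to the printed two decimals,
  which is why it is the default (and the published tables double as its
  regression test).
- Pearson chi-square Σ(O−E)²/E with E = row total × column total / grand
  total, df = (r−1)(k−1); Yates continuity correction is off by default and
  flag-selectable. The 3-level marital table gets an r×k chi-square only —
  an OR is not applicable and is reported as such.

Zero cells raise a hard error in the low-level functions; the
Haldane–Anscombe +0.5 correction is opt-in. The pipeline layer applies the
correction automatically for a zero-cell OR/CI (annotating the row) while
the chi-square, which remains well defined, is computed on the raw counts.

Report rounding follows the published print style: ORs to 3 decimals, CI
bounds to 2, percentages to 1, p-values floored at "<0.001".

### Known non-reproduction

The published mortality OR is printed as 3.388, but the printed death
counts (31 of 429 low-risk, 92 of 439 high-risk) give
(398×92)/(31×347) = 3.404. The counts are the primary source, so the
pipeline reports 3.404 and footnotes the printed figure rather than forcing
agreement. Similarly, the ischemic-heart-disease OR appears in the source
text as both 4.38 and 4.830; the packaged counts reproduce 4.830 exactly,
so that is the fixture-verified value. Absolute admission counts were
published only as percentages, so no admission fixture tables are packaged;
admission statistics are computed on patient-level data only, counting
patients with ≥1 admission of each type (whether the original analysis
counted patients or admission events is not stated).

## Synthetic cohort generator

The generator emulates the validation cohort's **marginals**: n = 868 by
default; age ~ N(59.6, 15.57²) truncated to [19, 103] y; hemoglobin
~ N(113.6, 11.99²) g/L; Kt/V ~ N(1.7, 0.49²); male fraction 467/868;
marital split 680/100/88; and per-component band probabilities taken from
the published frequencies (BMI band 0: 0.906; albumin band 0: 0.884;
vintage band 3: 0.72; ferritin band 0: 0.77; functional capacity
0.380/0.226/0.190/0.203 — renormalized from the printed values, which sum
to 0.999; comorbidity counts 0.218/0.320/0.297/0.165 over 1/2/3/4). Where
only one band's frequency was published, the residual mass is split evenly
over the remaining three bands (config-overridable).

Within a sampled band, continuous values are drawn uniformly, with
open-ended bands truncated at physiologic limits (BMI [12, 45] kg/m²,
vintage ≤25 y, albumin [15, 50] g/L, ferritin [10, 3000] µg/L). Uniformity
within bands is a declared modelling choice — the real within-band
distributions were not reported. Values are rounded for CSV output only
where rounding cannot cross a band edge; otherwise full precision is kept,
so a written cohort always rescores identically.

Components are drawn **independently**: the study reports marginals, not a
joint distribution, so independence is the minimal assumption. Which
specific comorbid conditions are present is a uniform random subset of the
drawn count. Consequences: synthetic cohorts match the published
band frequencies and lab moments but not, in general, the published
risk-group split, the factor-vs-risk-group associations (which arise from
real-world correlation between factors and score components), or the
printed ORs — those are reproduced exactly from the packaged count tables
instead. Passing simulation tests therefore demonstrate pipeline
correctness and statistical calibration, not clinical validity on real
data.

Outcomes are Bernoulli with logit p = α + β·T, logistic in the **total**
score (the published validation is entirely score-mediated). Defaults were
chosen once to give event rates and high-vs-low odds ratios of the same
order as the published ones (death: α = −3.5, β = 0.30 per point, implying
OR ≈ 3 for high vs low; vascular admission: −1.0, 0.072; non-vascular:
−1.5, 0.24). Because components are independent, the implied total-score
distribution is the sixfold convolution of the band probability vectors
(`total_score_pmf`), which makes the model-implied OR exactly computable
(`implied_outcome_or`) — the oracle the parameter-recovery harness checks
against.

## Numerical and design choices

- Band scoring uses `searchsorted` on the cut arrays; ties are resolved by
  the side conventions above, so every finite positive input maps to
  exactly one band (fuzzed in tests, including at the edges).
- The chi-square statistic and tail probability come from scipy
  (`chi2_contingency`, `chi2.sf`); tests verify them against a direct
  Σ(O−E)²/E summation and numerical quadrature of the density. The Woolf
  interval is computed from its closed form and cross-checked against
  statsmodels' `Table2x2`.
- One row per patient is the canonical analysis grain; quarterly long
  format is accepted and collapsed through the aggregation policy before
  stratification.
- The scorer is exposed as a scikit-learn estimator (`HashmiScorer`):
  `fit` validates configuration and records the schema (the rule itself has
  no free parameters), `transform` returns component scores, `predict` the
  risk category. This gives pipeline/`clone`/grid-search compatibility for
  threshold sweeps.
- Monte-Carlo problem sizes: calibration checks use 200 replicates at the
  published n = 868 and 10,000 simulated tables for interval coverage —
  large enough for the ±3- and ±2-point tolerances asserted, small enough
  to keep the suite fast.

## Limitations

- Independence across components overstates score dispersion relative to a
  real cohort where malnutrition markers correlate; an induced correlation
  structure is out of scope.
- The generator reproduces marginals of one specific published cohort;
  transport to other populations is a user decision.
- No survival modelling, covariate adjustment, multiple-testing correction
  or center effects: the validation design being reproduced pools all
  centers and compares groups with unadjusted contingency tests.
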