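# dicentrix

Cytogenetic biodosimetry with the dicentric chromosome assay (DCA).

After a radiological accident — or when a radiation worker's physical
dosimetry is missing or suspect — the absorbed dose can be estimated from
the frequency of dicentric chromosomes in peripheral-blood lymphocyte
metaphases. `dicentrix` implements the full analysis pipeline used in
biodosimetry laboratories that score dicentrics manually or with
semi-automated (software-detected, scorer-validated) systems:

* **Poisson conformity testing** of per-dose dicentric distributions via the
  dispersion index σ²/ȳ and Papworth's u statistic,
  `u = (σ²/ȳ − 1)·√((N−1)/(2(1 − 1/X)))`, approximately N(0, 1) under the
  Poisson hypothesis;
* **calibration-curve fitting** of the linear-quadratic dose response
  `Y = C + αD + βD²` by identity-link Poisson maximum likelihood on
  aggregated counts, with non-negativity constraints, Wald z tests and a χ²
  goodness-of-fit test;
* **dose estimation** by curve inversion,
  `D = (−α + √(α² + 4β(y − C))) / 2β`, with ~95% confidence limits that
  combine exact (Garwood) Poisson limits on the observed yield with the
  delta-method confidence envelope of the curve (Merkle's 83%/83% recipe);
* **triage evaluation**: accuracy/sensitivity/specificity for the standard
  binary dose categories (never vs. ever exposed at 0.1 Gy; ≤0.1 vs.
  >0.1 Gy; ≤1.5 vs. >1.5 Gy) and the CI-or-±0.5 Gy dose-correctness rule;
* **method agreement**: Cohen's κ, McNemar's test and Spearman rank
  correlation for paired manual vs. semi-automated dose estimates;
* **synthetic scoring simulation** at the count level (Poisson biology,
  binomial detection thinning, false-positive candidates, metaphase
  rejection, 1,000-cell/100-dicentric stopping rule) so the whole pipeline
  is testable without slides.

The package ships a nine-dose Co-60 calibration scoring table (0–4 Gy,
semi-automated scoring) and the published manual and semi-automated curves
as plain-CSV fixtures.

## Worked example

```python
import dicentrix as dx
from dicentrix.datasets import calibration_distributions

dists = calibration_distributions()          # nine dose points, 0-4 Gy

# 1. Poisson conformity: every |u| < 1.96
table = dx.poisson_conformity(dists)
print(table.attrs["overall_conforms"])       # True

# 2. Fit the calibration curve
res = dx.fit_linear_quadratic(dists, label="semi_automated")
print(res.summary())

# 3. Estimate the dose of a scored case: 56 dicentrics in 500 cells
case = dx.SubjectSample("case-1", cells=500, dicentrics=56,
                        method="semi_automated")
est = res.estimate_dose(case)
print(f"{est.dose:.2f} Gy  95% CI [{est.ci_low:.2f}, {est.ci_high:.2f}]")
```

The fit prints

```
Linear-quadratic dicentric dose-response (Poisson ML, identity link)
label: semi_automated   dose points: 9   iterations: 3   SEs: expected information

  coef     estimate      std err         z      P>|z|
     C  0.000974199     0.000212     4.590   4.44e-06
 alpha    0.0164703      0.00223     7.400   1.37e-13
  beta    0.0178375      0.00122    14.570   4.35e-48

goodness of fit (pearson): chi2 = 4.049, df = 6, p = 0.670
```

so the background yield is C ≈ 0.00097 dicentrics/cell with α ≈ 0.016 /Gy
and β ≈ 0.018 /Gy², every coefficient is significantly positive, and the
model shows no lack of fit across the nine dose points. The case with a
yield of 56/500 = 0.112 dicentrics/cell then estimates at

```
2.08 Gy  95% CI [1.80, 2.38]
```

i.e. an acute whole-body dose of about 2 Gy, with the interval reflecting
both the Poisson counting error on 56 dicentrics and the uncertainty of the
fitted curve.

## Command line

The same stages are exposed as `dicentrix` subcommands operating on the CSV
formats in `dicentrix.io`:

```sh
dicentrix dispersion   --distributions calib.csv
dicentrix fit-curve    --distributions calib.csv --out curve.csv
dicentrix estimate-dose --curve curve.csv --samples samples.csv --out est.csv
dicentrix triage-report --estimates est.csv
dicentrix compare-methods --estimates-a manual.csv --estimates-b semi.csv
dicentrix simulate     --spec cohort.yaml --out-dir sim/
dicentrix reproduce    --seed 7 --out-dir reports/
```

`dicentrix reproduce` chains everything on the packaged fixtures: the
dispersion table, the calibration refit with its z tests and goodness of
fit, the worker-cohort agreement statistics (κ = 0.71; McNemar χ² = 1.80,
p = 0.18), and a seeded synthetic triage study.

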