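# Methods

## The assay and its statistical model

The dicentric chromosome assay estimates absorbed ionizing-radiation dose
from the frequency of dicentric chromosomes in peripheral-blood lymphocyte
metaphases. Dicentrics are radiation-specific, have a very low background
frequency (~1 per 1,000 cells), and after acute whole-body low-LET exposure
their per-cell counts are Poisson distributed to a good approximation. Both
properties are load-bearing: the Poisson assumption drives the counting
error attached to every dose estimate, and the low background makes small
doses detectable at all.

All dose-response modelling uses the linear-quadratic (LQ) form

    Y(D) = C + alpha*D + beta*D^2

with Y the yield in dicentrics per cell, D the dose in Gy, C the background
yield (dicentrics/cell), alpha the linear coefficient (Gy^-1, dominating
below ~1 Gy) and beta the quadratic coefficient (Gy^-2, dominating above).
The model applies to acute exposures at a fixed dose rate; no dose-rate or
protraction generalisation is attempted.

## Poisson conformity (dispersion module)

For one dose point with N cells, X total dicentrics and multiplicity
histogram D_k, the per-cell mean is ybar = X/N and the sample variance uses
the N−1 denominator. The dispersion index is sigma^2/ybar (1 under Poisson)
and Papworth's u statistic

    u = (sigma^2/ybar − 1) * sqrt((N − 1) / (2*(1 − 1/X)))

is approximately standard normal under the Poisson hypothesis, so |u| <
1.96 is the conventional 5% conformity criterion. Two conventions are
unstated in most reports: the variance denominator (N vs. N−1) and the
exact u normalisation. The adopted pair — N−1 denominator and the (1 − 1/X)
term with X = total dicentrics — reproduces all nine dispersion-index and u
values of the packaged calibration table to the two printed decimals, which
is the selection criterion. A distribution with no dicentrics has an
undefined index (0/0) and is reported as missing, never as 0; u needs X ≥ 2
to be finite.

## Calibration fitting (calibration module)

At dose point i the total count X_i is modelled as Poisson with mean
N_i * Y(D_i): an identity-link Poisson regression with cells as exposure.
Aggregating dicentrics per dose point is sufficient under the Poisson
assumption (the per-cell likelihood factorises through the totals), so the
fit is exactly equivalent to per-cell fitting. The identity link is the
field convention because the published curve coefficients are the
regression parameters themselves.

Fitting is Fisher scoring: Newton steps on the expected information
Sum_i N_i g_i g_i' / Y(D_i) with g_i = (1, D_i, D_i^2), step-halving until
the candidate keeps every predicted mean positive and does not decrease the
log-likelihood, and an active-set treatment of the non-negativity
constraints (a coefficient pinned at 0 whose gradient points outward is
dropped from the Newton system; it re-enters when its gradient turns
positive). Negative C, alpha or beta are physically meaningless for this
endpoint, and datasets without low-dose information genuinely produce
boundary solutions (alpha = 0), so the constraint handling is not
decorative. Convergence is a relative log-likelihood change below 1e-10,
capped at 100 iterations; non-convergence raises an error carrying the last
iterate. Starting values come from clipped weighted least squares on the
yields.

Standard errors come from the inverse information at the optimum — expected
information by default, observed information as an option (the two differ
only in how far the data sit from the fitted means; for the packaged table
they agree to ~2%). The full coefficient covariance is retained on the
fitted curve for downstream error propagation. Coefficient significance
uses Wald z = estimate/SE with two-sided normal p.

Goodness of fit is the Pearson chi-square Sum (X_i − mu_i)^2 / mu_i on
df = (dose points − 3), with the residual deviance as an option. On the
packaged table this gives chi2 = 4.05, df = 6, p = 0.67 (deviance: 4.13,
p = 0.66) — comfortably non-significant. Published analyses of this design
have quoted a higher p for the same fit (consistent with Pearson chi2 ≈ 4
referred to ~8–9 degrees of freedom, i.e. a different df convention in the
fitting software); since the statistic and the correct df are what the
package can defend, that is what it reports.

The confidence band on the curve is the pointwise delta method:
var(Yhat(D)) = g' Sigma g, band = Yhat ± z*sqrt(var). For literature curves
published with standard errors but no covariance, the off-diagonals are
assumed zero with an explicit warning.

## Dose estimation (dose_estimation module)

The point dose inverts the LQ curve at the observed yield y = x/n:

    D = (−alpha + sqrt(alpha^2 + 4*beta*(y − C))) / (2*beta)

(linear fallback when beta = 0). Samples with zero dicentrics, or whose
yield is at or below the fitted background, are assigned dose 0 flagged
``truncated`` — the working convention for reporting, at the cost of a
small upward bias in cohort-level summaries near 0 Gy.

Confidence limits (default "merkle") combine the two error sources the way
the IAEA manual recommends: 83% exact Poisson (Garwood) limits on the
yield, intersected with the 83% delta-method envelope of the curve. The
lower dose limit solves upper-envelope(D) = lower yield limit; the upper
limit solves lower-envelope(D) = upper yield limit; each by Brent's method
on [0, 10] Gy at 1e-6 Gy tolerance (the 10 Gy cap is an argument; exceeding
it raises rather than extrapolating a triage curve). Two 83% components
combine to approximately 95% overall confidence; this 0.95→0.83 mapping is
hard-wired, and any other requested level uses that level directly for both
components. The "poisson-only" alternative inverts 95% Garwood limits
through the point curve, ignoring curve uncertainty — appropriate when the
calibration is treated as known. The end-to-end acceptance simulations show
the default construction covers the true dose in ≥90% of 500-cell samples
at 0.5–3 Gy (it is conservative, as expected from intersecting two 83%
envelopes).

Garwood limits on X events are chi2(a/2, 2X)/2 and chi2(1−a/2, 2X+2)/2
(lower limit 0 at X = 0); they guarantee ≥ nominal coverage.

The dose-correctness rule for known delivered doses is: correct iff the
delivered dose lies in the 95% CI **or** the point estimate is within
0.5 Gy — the standard triage criterion.

## Evaluation (evaluation module)

Triage categories dichotomise doses at 0.1 Gy (never vs. ever, positive
class ≥ 0.1 Gy; and ≤0.1 vs. >0.1 Gy, positive class > 0.1 Gy) and 1.5 Gy
(acute-radiation-syndrome risk, positive > 1.5 Gy). Classification uses the
point estimate only — per-sample triage categories are assigned from the
reported dose, not its interval. Metrics are the textbook percentages;
an empty denominator yields NaN rather than a fabricated 0 or 100.

Cohen's kappa uses the marginal-product expected agreement. McNemar's test
defaults to the uncorrected (b − c)^2/(b + c) against chi-square(1) — on
the packaged worker table (discordant cells 4 and 1) this gives chi2 = 1.8,
p = 0.18, matching the published analysis, which is why the uncorrected
variant is the default; continuity-corrected and exact-binomial variants
are options. Spearman correlation uses mid-ranks; its p value is a full
permutation enumeration for n ≤ 10 and the t approximation otherwise.

## Synthetic scoring (simulate module)

The generator works at the count level only. Per cell at dose D the true
dicentric count is Poisson(Y(D)) from a generating curve; scoring then
applies, in order: metaphase rejection (each captured image independently
rejected with probability ``rejection_rate``), binomial thinning of true
dicentrics with ``detection_efficiency``, additive Poisson false positives
at ``fp_rate_per_cell * fp_survival`` per analyzed cell, and the stopping
rule (stop at ``stop_cells`` analyzed metaphases or on the cell that
reaches ``stop_dicentrics``). Paired cohorts share each subject's true
per-cell counts between the two scoring models, so method differences are
scoring effects on identical biology.

Default scoring models encode the study conditions of the semi-automated
workflow the package targets: manual scoring is the reference (efficiency
1.0, no false positives, no rejection); semi-automated scoring has 0.081
false-positive candidates per cell before validation with none surviving
validation (fp_survival 0), a 0.5 rejection rate, and detection efficiency
0.45 — the ratio of the published linear coefficients (0.016/0.0355 ≈
0.45). A single thinning scalar cannot simultaneously match the quadratic
ratio (0.018/0.0644 ≈ 0.28): uniform thinning of a Poisson LQ process
scales alpha and beta equally, so the real semi-automated detection loss is
evidently dose-dependent (e.g. worse in heavily damaged spreads). This is a
documented limitation; per-study calibration of the efficiency, or
simulating directly from the semi-automated curve with efficiency 1, are
the supported alternatives. Both stopping caps default to 1,000 metaphases
/ 100 dicentrics.

What the generator does **not** emulate: image quality and its correlation
with dose, scorer-to-scorer variability, partial-body exposure
(overdispersed, zero-inflated distributions), culture artefacts, or any
correlation between rejection and dicentric content. Passing pipeline tests
on synthetic cohorts therefore demonstrates statistical correctness of the
estimators under the model's own assumptions — not robustness to those
real-data effects.

All randomness derives from one integer seed through a single
`numpy.random.Generator`; identical seeds give byte-identical outputs.

## Problem sizes in the shipped checks

The simulation-based checks use: 2,000 replicates of 500-cell Poisson
distributions for the u-test size; 500 replicates per dose point
(0.5/1/2/3 Gy, 500 cells) for dose-CI coverage; 40 samples for the
end-to-end triage study; and 100–120 replicate refits of the nine-dose
calibration design for parameter recovery. These sizes give Monte-Carlo
standard errors comfortably below the acceptance margins they are checked
against.

## Known limitations

* Whole-body acute exposure only: no Dolphin/contaminated-Poisson
  partial-body estimation, no protracted-exposure G-function correction.
* The truncation-at-zero reporting rule biases cohort summaries (MAD,
  correctness rates) slightly optimistic near 0 Gy.
* Literature curves without covariance get a diagonal approximation, which
  typically overstates the envelope width at mid-range doses.
* The LQ fit assumes Poisson counts; for overdispersed field data the SEs
  would need a dispersion correction the package deliberately omits.
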