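# Methods

## The classification model

The package implements a traffic-light risk classification for prolonged
second-stage labor with a transverse fetal head position. Four geometric
parameters measured on intrapartum translabial ultrasound — the angle of
progression (AoP, degrees; larger is more favorable), the head–symphysis
distance (HSD, mm; the source tables call it SPD), the midline angle
(MLA, degrees) and the asynclitism degree (AD) — are each coded GREEN
(favorable for vaginal delivery), YELLOW (intermediate) or RED (high risk
of cesarean delivery) against per-parameter threshold bands. The AIDA
class of a case is the number of parameters coded non-GREEN:

    class(pattern) = #{ p in {AoP, HSD, MLA, AD} : color(p) != GREEN }

giving an ordinal 0–4 scale with class 0 all-green and class 4 no green
left. The counting rule is the unique rule consistent with every row of
the packaged 66-case cohort (e.g. one RED plus one YELLOW gives class 2),
and a test asserts zero mismatches across all 66 recorded classes.

## Position geometry

Occiput direction is handled on two equivalent scales: the ISUOG clock
face (12:00 = occiput anterior midline, one clock minute = 0.5°) and the
rotation angle θ ∈ [0, 360), increasing toward the maternal left. Sector
bands are closed on the transverse intervals: left occiput transverse is
θ ∈ [75°, 105°], right occiput transverse θ ∈ [255°, 285°]; (105°, 255°)
is posterior and the rest anterior. Right-sided angles are folded onto
the canonical scale c = min(θ, 360 − θ), which drives the transverse
strata used throughout:

| stratum      | canonical MLA | note                       |
|--------------|---------------|----------------------------|
| CLASSIC      | [75°, 105°]   | closed: "≥ 75°" forces 75 in |
| NEAR         | [70°, 75°)    | half-open to avoid overlap |
| TRANSITIONAL | [60°, 70°)    | half-open                  |
| OTHER        | elsewhere     | incl. posterior-side angles |

Posterior-side canonical values (105°, 180°] deliberately get no stratum
of their own: the stratification is defined only for the transverse
spectrum. A 0.5° sweep test checks that the four labels partition the
circle and that CLASSIC always lies inside a transverse sector.

## Thresholds are configuration

The clinically validated numeric cut-offs behind the published color
codes are external to this package. `placeholder_thresholds()` ships a
clearly non-canonical default (AoP risk-decreasing with breakpoints
110/120°; HSD 13/15 mm; MLA 45/60° on the canonical scale; AD 8/12,
units chosen as degrees) so that simulation and the raw-value
classification path are exercised end to end; every analysis of recorded
color codes consumes the codes directly and never touches these bands.
Values exactly on a breakpoint take the riskier adjacent color — a
conservative tie-break appropriate for screening.

## The packaged cohort

66 cases of transverse fetal head position (from a parent cohort of 135
nulliparous women with prolonged second stage), with per-case midline
angle, four color codes, recorded AIDA class, binary delivery outcome
(cesarean "ICD" vs vaginal "NOICD"; the ICD label includes cesareans
after a failed vaginal attempt) and the recorded per-case predictions of
three machine-learning algorithms (SVM, RF, MLP). The detailed outcome
(spontaneous / operative vaginal / ICD-after-failure / ICD) was published
only as a class-by-stratum aggregate, which ships as a second CSV; the
package never invents a per-case detailed label. Both files are
checksummed (SHA-256) and verified on load.

Two published prose statements disagree with the per-case tables (seven
vs six vaginal deliveries; whether any vaginal delivery occurred in the
classic stratum). The package follows the tables in both cases and
reports what they contain.

## Machine-learning stage

Two strictly separated evaluation routes:

* **Recorded-prediction scoring** compares prediction columns already in
  a cohort against outcomes — no fitting. This is the route that
  reproduces the published per-stratum accuracies exactly (e.g. classic
  SVM 27/29 = 93.1%).
* **Retraining** fits fresh scikit-learn backends — SVC and MLP behind a
  standardizing pipeline, a random forest raw — on a 70/30 split
  repeated over seeds (default 1, 0, 250, 500, 750), with the run seed
  injected into both the permutation and the estimator. The train size
  is ⌊0.7·n + 0.5⌋ (135 → 95/40). Aggregation over seeds is the
  unweighted mean with per-seed detail retained. Feature encodings: RAW
  (four raw measurements), COLOR_ORDINAL (GREEN=0/YELLOW=1/RED=2 per
  parameter plus canonical MLA degrees — the only retraining encoding
  available for the packaged cohort, which has no raw AoP/HSD/AD), and
  CLASS_ONLY. Decision threshold 0.5 on the cesarean probability; scores
  are retained so AUC is computable. Splits are unstratified by default
  (a stratified option exists behind a flag).

## Statistics

Confusion metrics follow the standard formulas with the positive class =
cesarean; zero-denominator metrics are reported as undefined (`None`),
never 0 — specificity on an all-cesarean stratum has no value. Wilson
score intervals use the exact normal quantile; McNemar's test uses
(|b−c|−1)²/(b+c) with the continuity correction on by default (off by
flag) and treats b+c=0 as a flagged degenerate case with χ²=0, p=1. Both
are cross-checked against statsmodels in the test suite; Pearson
correlation and rank-based AUC delegate to scipy and scikit-learn, with
a brute-force pairwise oracle validating AUC up to n=200.

## Synthetic cohorts

The generator emulates the study-cohort structure: stratum mixture
(defaults fitted to the packaged cohort, 29/9/28 over classic/near/
transitional, OTHER weight 0), per-stratum categorical distributions over
four-color patterns, class from the counting rule, and outcome drawn
Bernoulli with class-conditional cesarean probability. The default
cd_prob keeps the empirical class-2/3/4 rates (0.9, 29/32, 1.0) and
smooths the single-case class-0 and two-case class-1 cells to a monotone
0.25/0.5 ramp — a calibration choice, not observed data.

Raw AoP/HSD/AD values are drawn via a Gaussian copula (optionally
correlated through `latent_correlation`) and mapped into the threshold
band of the assigned color, so raw values and color codes can never
contradict under the active thresholds. The MLA color is handled
differently: the packaged cohort shows the published MLA code is not a
pure function of the angle (a 60° case coded GREEN beside 64° cases
coded RED), so the generator samples the MLA code as part of the pattern
and samples the angle uniformly (integer degrees) in the stratum band,
emitting right-sided cases in ROT coordinates with probability ½. Color/
threshold consistency is therefore guaranteed — and tested — for
AoP/HSD/AD, not for MLA.

What the generator does **not** emulate: longitudinal parameter
evolution during labor, measurement error, inter-observer variability,
any biomechanics. Passing tests on synthetic cohorts validate pipeline
arithmetic and statistical calibration, not clinical performance on real
ultrasound data.

## Problem sizes and numerical choices

Tests use cohorts of 20–400 cases for pipeline checks, 10,000 for the
parameter-recovery check (class-conditional rates within 3 binomial
standard errors), and 20,000 draws for the Pearson simulation oracle —
sizes at which every check runs in seconds. All randomness flows through
`numpy.random.default_rng(seed)`; identical config and seed give
byte-identical CSV output. Percentages in reports are printed to one
decimal next to their exact fraction, matching the source convention.

## Known limitations

The true clinical cut-offs (and the AD unit) are unknown here, so raw-
value classification with the placeholder bands must not be read as the
published system. Classes 0–1 are nearly empty in the 66-case cohort
(3 cases), so their fitted cesarean rates are unstable — hence the
smoothed defaults. Published overall metrics, McNemar statistics,
Wilson bounds and Pearson coefficients whose underlying data or pooling
were not published are deliberately not reproduced numerically.
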