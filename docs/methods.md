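# Methods

`posuse` measures adolescents' use of public open spaces (POS) — and the
physical activity accumulated there — from paired GPS and accelerometer
streams, and models the individual and social correlates of that use.
This note documents the processing rules, the statistical model, the
synthetic data generator that serves as the package's known-answer test
surface, and the numerical choices behind both.

## Measurement model

**Input streams.** Each participant wears a hip accelerometer producing
one activity count per 15 s epoch and a GPS logger producing one fix per
30 s. A cohort table supplies demographics and home coordinates; a
school table supplies school coordinates and per-class timetables
(school hours, physical-education and recess blocks); an annotation
table — the data product of map-assisted interviews — types each
stationary leisure location (nine POS categories, company, reasons,
activities); a weather table gives daily rain, sunshine and temperature.

**Intensity.** Counts per 15 s map to intensity by the Evenson youth
cutpoints: sedentary ≤ 100, light 101–2295, moderate 2296–4011,
vigorous ≥ 4012. The four half-open bands partition the count range, so
classification is a total function. Intensity minutes are always
accumulated from 15 s classifications (0.25 min each); the 30 s count
sum on a fused epoch is diagnostic only, because the cutpoints are
defined at 15 s and doubling thresholds is not an equivalent rule.

**Non-wear and valid days.** Any maximal run of consecutive zero-count
epochs lasting ≥ 60 min is non-wear and is removed from every total.
The rule carries no spike allowance — one nonzero epoch breaks a run —
and runs truncated by the recording edge still count. Days are local
civil dates; runs crossing midnight are split there. A day is valid
with ≥ 9 h (540 min) of worn time, and a participant enters the
analysis with ≥ 1 valid day. Validity is an accelerometer-only notion:
GPS dropout never invalidates a day, it only removes epochs from the
spatial domains.

**Fusion and plausibility.** Each fix anchors a 30 s fused epoch
carrying the two count epochs in [fix, fix + 30 s), matched with ± 5 s
tolerance for clock drift. Worn count epochs with no fix become
location-missing epochs: they count toward wear and intensity but never
toward spatial domains. A fix is implausible relative to the last valid
fix when speed exceeds 130 km/h, displacement exceeds 1 km, or the
elevation change exceeds 100 m; the comparison chain restarts from the
last valid fix, and a missing elevation skips the elevation test only.

**Movement.** Speed (great-circle distance over actual elapsed time,
km/h) is banded: stationary < 1, pedestrian [1, 10), bicycle [10, 25),
motorized ≥ 25. The stationary band is the complement the pedestrian
threshold leaves; epochs with undefined speed (first of a chain,
post-dropout) default to stationary, which avoids phantom trips.
Single-epoch movement flickers flanked by one identical state on both
sides are absorbed before segmentation (`smooth_epochs = 1`), as
one-epoch GPS noise otherwise fragments trips. An optional correction
table — the interview's role — can overwrite movement inside declared
windows (e.g. a congested bus ride banded as bicycle).

**Domains.** Stationary worn epochs are school when within 100 m
(great-circle, boundary inclusive) of the school point during school
hours on a school day — subclassified PE / recess / class by the
timetable — otherwise home within 100 m of home, otherwise leisure.
School precedes home where buffers overlap during school hours, being
the more specific rule; being at school outside school hours is
leisure. Maximal runs of one label become events; runs of one transport
mode become trips; location-missing epochs break runs.

**POS visits.** A leisure event with an annotated POS category is a
visit. The trip abutting the event start (within one epoch) is its
inbound trip, the trip abutting its end the outbound trip; a trip
bridging two POS events counts once, as outbound of the earlier visit.
Trips whose adjacent events are home, school or unannotated leisure are
never attributed, whatever territory they cross: cycling through a park
to school contributes nothing, while cycling to a park contributes the
ride and the dwell. Only the leg adjacent to the event is attributed in
multi-leg journeys; chained attribution is available behind
`--attribute-chain`-style options but off by default. Events at
public-transport stops remain visits even when followed by a motorized
trip — no "pure transfer" exclusion is attempted, since waiting time
cannot be separated from leisure time in these data.

**Aggregation.** Per-participant rows average over valid days: wear
min/day, visits/day, POS min/day, total and POS intensity min/day
(POS intensity includes attributed trip minutes), company-specific
visit rates, demographics, and weather means over the participant's
valid days.

## Statistical model

POS time per day is semicontinuous — a point mass at zero (non-users)
and a right-skewed positive part — so associations are estimated with a
two-part hurdle: a Bernoulli GLMM with logit link for any POS use
(exponentiated coefficients are odds ratios) and a gamma GLMM with log
link on the positive subset (exponentiated coefficients are
proportional differences in minutes per one-unit covariate
difference). Both parts carry a normal random intercept per school.

The marginal likelihood integrates the school intercept by adaptive
Gauss–Hermite quadrature (9 points; 1 point is the Laplace
approximation), centring the nodes on each group's conditional mode
found by Newton iteration. Parameters (fixed effects, the intercept
standard deviation σ ≥ 0, and the gamma log-shape, profiled jointly)
are maximized by L-BFGS-B with a relative gradient tolerance of 1e-6
and at most 500 iterations; starting values come from the single-level
GLM. Wald standard errors come from a central finite-difference Hessian
of the negative marginal log-likelihood at the optimum; when σ sits at
the zero boundary its row is dropped. Confidence intervals are
exp(β ± 1.96 SE); p-values are Wald z. Complete separation in the
occurrence part is raised as an error, never silently penalized,
because automatic Firth-style correction would change the estimand.

**Covariate screening and model building.** All candidates (residence,
wear time, visits/day, days of data, rain, sun, temperature, plus the
matching total-intensity term and total POS time for intensity
outcomes) enter one model; those with p < 0.05 are retained, forced
terms regardless. Then four steps per outcome: each individual factor
(age, gender, ethnicity, education, sport club) separately with
covariates; the significant ones jointly; each social variable (visit
rates by company) separately, adjusted for the joint factors. Trends
(p < 0.1) are flagged distinctly but only p < 0.05 moves a factor
forward. One structural rule: in the occurrence part of the overall
POS-use hurdle, per-visit aggregates (visit rates, POS minutes, company
rates) are excluded, since they are zero by construction for every
non-user and would separate the indicator perfectly; they remain in the
amount part, where they are well defined.

## Synthetic cohort generator

The generator emulates the measurement design so every stage has a
known answer: school-recruited adolescents (default 173 across 6
schools, ages ~N(14.2, 1.1) clipped to 12–16, 54.4% girls, 28.3%
non-western-European, education 68.8/22.0/9.2% general/vocational/
technical, 22.5% low SES, 58% sport-club members, residence
6.9/16.8/76.3% rural/suburban/urban), measured two consecutive days
(Friday + Saturday) in staggered weekly waves per school, wearing both
devices 07:30–22:00.

Days are built from anchors — home, school, POS sites — joined by
constant-speed great-circle trips snapped to the 30 s grid (pedestrian
5, bicycle 16, motorized 35 km/h, chosen by distance; durations round
up, so realized speeds stay inside their bands). School days follow the
timetable; weekends differ only by the absence of the school block.
POS visits occur with per-day probability 0.5 on the logit scale,
shifted by the configured true demographic log-odds and a school
intercept (σ = 0.3); visiting days carry 1–3 visits (mean 1.8); dwell
times are gamma (shape 2, mean 20 min) scaled by the true amount
effects; categories follow the observed visit mix (71% transit stops).
These behavioural defaults are free parameters of the generator, not
estimates of any cohort: trip and dwell distributions are not reported
quantities anywhere, so they were fixed once at values a field study of
urban adolescents would find unremarkable.

Counts are drawn per 15 s from context-conditional mixtures of
lognormals whose class medians sit inside the target intensity band
(e.g. motorized transport is sedentary-dominated, PE is MVPA-heavy),
with zero-inflated sedentary draws so genuine zero epochs occur;
intensity ground truth is whatever the Evenson rule says about the
generated counts, which keeps conservation exact. Noise processes —
evening non-wear bouts (p = 0.15/day, 60–120 min), early device
removal producing invalid days (p = 0.08), per-fix GPS dropout
(p = 0.005) and 1.5 m positional jitter (approximating
post-smoothing GPS error) — are all switchable; `noise_free()` turns
them all off for exact-recovery tests.

One master seed is split into counter-based per-participant streams,
so datasets are byte-reproducible and independent of generation order.
Timestamps are zone-naive local civil time with no DST transition
inside a window.

**What the generator does not emulate** — and hence what passing tests
cannot show about real data: road networks (trips are straight lines),
urban GPS multipath and canyon effects, indoor signal loss at specific
building types, device clock drift beyond the ± 5 s matching tolerance,
behavioural feedback between weather and going out, and interview
recall error (annotations are exact windows). Recovery results on the
noise-free cohort certify the bookkeeping of the pipeline, not the
field validity of the measurement chain.

## Problem sizes

Defaults were chosen so the whole suite exercises realistic structure
at desk scale: partition and recovery checks use 50 participants × 2
days; oracle-equivalence checks use 1000 random streams/tracks;
Monte-Carlo recovery and calibration use 200 cohorts of n = 1000 in 6
schools; the end-to-end determinism check runs 40 participants twice.
The acceptance script runs the full default cohort (173 × 2 days) plus
a 100-replicate recovery experiment.

## Known limitations

* The event/transport split is purely speed-based; accelerometer-
  informed event detection (as in dedicated fusion software) is not
  reconstructable from published descriptions and is approximated by
  the stationary band plus one-epoch smoothing.
* Location-missing gaps split events, so heavy GPS dropout inflates
  visit counts; the adjacency tolerance of one epoch absorbs single
  missing epochs only.
* With few schools (6) the random-intercept SD is weakly identified;
  Wald intervals for σ itself are not reported, only for fixed effects.
* The hurdle parts share no parameters, so joint likelihood is the sum
  of the part likelihoods; correlated random effects across parts are
  out of scope.
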