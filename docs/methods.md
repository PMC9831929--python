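# Methods

This note records the modelling assumptions, numerical choices and generator
design behind maculatrack, and what the test suite does and does not
establish about real data.

## The contiguity decision rule

A scan is the nine ETDRS sector mean thicknesses of one eye (µm). The rule
declares an interval change between two scans meaningful when the signed
per-sector difference reaches ±τ in at least k *contiguous* sectors, in a
single direction, in a single eye. Defaults are τ = 4 µm — twice the 2 µm
test–retest coefficient of repeatability (CoR) of the instrument class the
package targets — and k = 3. The threshold comparison is inclusive (a
difference of exactly 4.00 µm qualifies), and all thicknesses are stored to
0.01 µm, so threshold comparisons are exact float comparisons with no tie
ambiguity.

Contiguity needs a convention, because the printed grid does not define one.
The default adjacency graph joins sectors that share a boundary arc: the
centre touches the four inner quadrants, each ring is a 4-cycle, and
matching inner/outer quadrants are radially adjacent (16 edges; every sector
has degree ≥ 2). Alternatives (for example, excluding the centre) can be
supplied as an explicit edge set. The component search is an ordinary BFS;
an exhaustive 2⁹-subset enumeration and networkx serve as independent
oracles in the tests, and a vectorised label-propagation path (verified
against the BFS) lets the null calibration sweep tens of thousands of pairs.

Thickening and thinning are evaluated independently; both can fire on one
pair (patchy effacement next to residual thinning does exactly this).

### Empirical-null calibration

Replicate scans taken at the same encounter differ only by test–retest
noise, so pooled replicate pairs form an empirical null for the rule. For
each weaker rule (τ′, k′) on the grid {1, 2, 3, 4} µm × {1, …, 9}, the
calibration reports the fraction of null pairs on which that rule fires in
either direction; the entry at the configured (τ, k) is the rule's empirical
exceedance probability. Frequencies are non-increasing in τ′ and k′ by
construction. The calibration reports whatever the supplied pairs imply; no
reference value is built in. Under independent Gaussian sector noise at the
CoR the default rule essentially never fires — spatially correlated
instrument artefacts are what make real nulls heavier, which is precisely
why the calibration is empirical.

## Trajectory classification

Eyes are classified from their time-ordered selected scans (better of the
two replicates by signal strength; ties keep the first):

* **Early thinning** — the rule fires in the thinning direction for
  (non-pregnant baseline → pregnancy scan); the gestational age of the first
  firing is recorded. The first observed firing right-censors the true
  onset: timing resolution is the visit schedule.
* **Loss of thinning (LOT)** — the rule fires in the thickening direction on
  a sequential within-pregnancy pair. Sequential differencing is deliberate:
  it makes the call available without a baseline image. Partial effacement
  below τ or under k sectors does not count; the calibrated rule is the sole
  decision instrument.
* **Sudden thinning events** — sequential thinning firings after thinning or
  LOT is already established; with a MAP drop ≥ 15 mmHg against the previous
  encounter (threshold configurable; no published definition of
  "significant drop" exists) the eye is flagged for hypoperfusion injury.
* **Overt thickening** — a pregnancy scan thicker than baseline by the rule.

Participant labels aggregate the two eyes: any LOT eye ⇒ `loss_of_thinning`
(with `single_eye_lot` when confined to one eye); otherwise
`maintained_thinning` if any eye showed early thinning, else
`no_early_thinning`. `no_injury` requires both eyes free of LOT, sudden
thinning, hypoperfusion and overt thickening — early thinning is the normal
physiological response, not an injury.

## The interval mixed model

The response is change from the same participant/eye/sector non-pregnant
thickness, one row per (participant, eye, sector, pregnancy encounter).
Change-from-baseline (rather than absolute thickness with a fourth level) is
modelled directly; it is the scale on which every quantity of interest is
defined. Fixed effects are cell means for interval × group; random
intercepts are nested — participant, eye within participant, sector within
eye — and the residual within each (participant, eye, sector) series has
continuous-time AR(1) correlation ρ^|Δweeks| (the correlation family is a
configurable default; three encounters per series cannot identify the
family). Estimation is REML: the marginal covariance is block diagonal by
participant, the deviance is accumulated over blocks (batched by block size
so numpy's stacked Cholesky/solve applies) and minimised by L-BFGS-B over
log-variances and logit ρ, with a Nelder-Mead restart if the line search
aborts near a variance boundary. Non-convergence raises an error carrying
the iteration trace; components estimated at the zero boundary raise a
warning.

Confidence intervals are Wald with a t reference on containment degrees of
freedom (participants − group levels). With normal quantiles, replicate
calibration showed genuine undercoverage at these cohort sizes (0.895 for a
four-participant group where 0.95 is nominal); the t reference restores
calibration without touching the point estimates. Epoch contrasts within
group use the same reference.

Two-level sanity anchor: with the serial correlation pinned to 0 and a
single sector, the fit reproduces the closed-form balanced-ANOVA REML
solution (mean squares → variance components → GLS means and SEs) on a
3 × 2 × 2 design; with one sector the eye and sector components are
identified only through their sum, which is what the comparison checks.

Variance components and ρ are reported but should be read with care: the
planted spatial patterns of the synthetic cohorts (below) inflate the
residual, and the generator's eye-level visit fluctuation is shared across
sectors, which the model does not represent. The fixed effects are the
reliable output; this is why only they are calibration-checked.

## Mean arterial pressure

MAP = DBP + (SBP − DBP)/3, kept to 0.1 mmHg internally and rounded to
integer mmHg only for presentation; both conventional conversions (112/70 →
84, 150/100 → 117) reproduce exactly, which is the validation of the
formula choice. Anchor summaries (enrollment = first pregnancy encounter;
LOT = encounter of first firing; delivery) are means of per-participant
values with Student-t 95% CIs; a single-participant anchor yields a
degenerate-CI flag rather than an interval. Rises are paired within
participant — on complete balanced data the paired rise equals the
difference of anchor means, but the paired version is authoritative.
Participants whose LOT is first seen at the delivery encounter are excluded
from the LOT anchor: the pressure at the true moment of loss cannot be
estimated for them.

## The synthetic cohort generator

No clinical data ship with the package; the generator produces cohorts with
the study design's statistical structure and known ground truth.

**Design.** 38 participants — 11 non-hypertensive controls, 12 de novo HDP,
8 chronic hypertension with LOT, 7 chronic hypertension maintaining
thinning. Visits at 12, 30 and 38 weeks (±2 weeks uniform jitter; none in
the fixture) plus a postpartum baseline 31 weeks after delivery; two
replicate scans per eye per encounter with signal strengths drawn on
[7, 10].

**Thickness truths.** Per-sector non-pregnant means (centre lowest, ≈250–286
µm) plus level offsets (participant SD 12, eye 2.5, sector 1.5 µm) that
cancel in change-from-baseline. Pregnancy change is −(group × epoch effect)
plus response heterogeneity (participant 0.6, eye 0.35, sector 0.35 µm — 
declared defaults: the scale of biological response heterogeneity plausible
beside a 2 µm CoR; no published decomposition exists), plus an eye-level
AR(1) visit fluctuation (SD 0.5 µm, correlation e^(−Δweeks/20)), plus
replicate noise SD = CoR/(1.96·√2) = 0.7215 µm. The default group × epoch
effects are the published interval estimates, so parameter-recovery runs
target those printed values as truths. MAP trajectories hit group anchors
(de novo: enrollment 84, LOT 82, delivery 101 mmHg with a paired rise of 19;
the printed LOT/delivery/rise triple is internally inconsistent by 5 mmHg,
and the generator preserves the delivery mean and the paired rise, the two
quantities checked downstream). MAP jitter (enrollment SD 4, step SD 3
mmHg) is declared slightly narrower than the printed CI widths imply,
favouring stable small-n anchor recovery.

**Planted events.** LOT is a contiguous 3-sector effacement: extra early
thinning on the effaced sectors, then a rebound whose sequential jump equals
`seq_jump` (default 6 µm) at the onset visit, growing 0.5 µm to delivery.
Sudden hypoperfusion thinning is planted at delivery; those participants
get one extra pre-delivery encounter with surged pressure so the delivery
encounter carries both the thinning and a ≥ 16 mmHg MAP drop while the
delivery MAP still lands on the group anchor. Every planted pattern in the
default configuration is mean-preserving within the eye — the six unaffected
sectors absorb the negated total, quantised to the 0.01 µm grid with exact
zero-sum — so at zero noise the sample group × epoch mean changes equal the
configured effects to machine precision, and compensation stays below 4 µm
so it can never fire the rule itself.

**Fixture vs default.** The fixture configuration (used for the
deterministic classification counts: 20 LOT / 7 single-eye / 26 early
before 20 weeks / 5 hypoperfusion, incl. exactly one participant first
thinning at 30 weeks) boosts all planted signals to ≥ 6 µm sequential
margins, removes visit jitter, keeps non-LOT trajectories monotone (a
thinning rebound in the group mean would itself approach the thickening
threshold), and plants the sudden thinning uncompensated at 10 µm. The
default configuration keeps the published effect sizes, whose ~4 µm signals
sit deliberately at the detection threshold — on it, classification is
realistically imperfect (≈19/20 LOT detected per run) while the interval
model and MAP summaries are exact-truth recovery problems.

**Calibration mode.** `plant_spatial=False` keeps the composition and
labels but omits all fixed spatial patterns. The 200-replicate CI-coverage
study runs half-size cohorts in this mode: fixed mean-zero patterns add
zero across-replicate variance while inflating the fitted residual, so
with them the study would measure conservatism of the planting scheme, not
the calibration of the model — which is what the coverage band (90–99%,
tolerating the serial-correlation mismatch) is meant to test.

## What the tests do and do not show

The suite establishes internal correctness (oracle equivalence of the
contiguity search and calibration, antisymmetry and shift invariance of the
rule, zero-noise exactness, closed-form agreement of the REML fit, label
recovery when signals dominate noise) and statistical calibration under the
generator's assumptions (CI coverage, truth recovery within Monte-Carlo
error). Real SD-OCT data differ in ways the generator does not emulate:
spatially correlated segmentation artefacts (the reason the empirical null
is heavier than Gaussian and the published rule exceedance is ~0.05 rather
than ~0), missed visits and variable schedules, treatment effects on blood
pressure, and drift in instrument calibration. Passing tests therefore
validate the machinery and its statistics, not clinical performance.

## Problem sizes

Default analyses use the 38-participant cohort (2,142 model rows; a fit
takes well under a second). The coverage study uses 200 half-size cohorts
(6/6/4/4); the repeatability check uses ≥ 10,000 replicate pairs; the
calibration oracle comparison uses 10,000 simulated pairs. These sizes give
Monte-Carlo error comfortably below every asserted tolerance.
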