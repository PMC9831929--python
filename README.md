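# maculatrack

Sequential analysis of macular thickness in hypertensive disorders of
pregnancy (HDP): a contiguity-based change-detection rule for ETDRS-grid
SD-OCT scans, longitudinal classification of eyes and participants,
hierarchical estimation of interval mean thickness change, and linkage of
retinal events to mean arterial pressure — together with a seeded
synthetic-cohort generator that emulates the statistical structure of a
prospective repeated-measures pregnancy study.

The package is aimed at clinician-statisticians working with per-sector
macular thickness tables (not raw OCT cubes): each scan is the nine ETDRS
sector means (µm) of one eye, acquired in duplicate at every clinical
encounter, with encounters at <20 weeks gestation, between 20 weeks and
delivery, at delivery, and once in the non-pregnant state.

## The methods

**Decision rule.** An interval change between two scans of one eye is called
clinically meaningful when a directionally identical difference of at least
τ = 4 µm — twice the instrument's 2 µm test–retest coefficient of
repeatability — appears in k ≥ 3 *contiguous* ETDRS sectors. Contiguity is a
declared convention on the printed grid (centre adjacent to the four inner
quadrants, rings cyclic, matching quadrants radially adjacent; 16 edges) and
is configurable. Because no parametric null exists for spatially correlated
sector maps, the rule is calibrated empirically: same-encounter replicate
scan pairs form a null difference distribution, and the firing frequency of
every weaker rule (τ′, k′) ∈ {1,…,4} µm × {1,…,9} is tabulated.

**Trajectory classification.** Per eye: *early thinning* fires the rule in
the thinning direction against the non-pregnant baseline; *loss of thinning*
(LOT) fires in the thickening direction on a sequential within-pregnancy
pair (no baseline needed); *sudden thinning* after established thinning,
coincident with a mean arterial pressure (MAP) drop ≥ 15 mmHg, flags
hypoperfusion injury; a scan thicker than baseline by the rule is overt
thickening. Eyes are analysed independently, but both eyes must be normal
for a participant to count as free of microvascular injury.

**Interval model.** Change from baseline y is modelled per (participant,
eye, sector, encounter) with cell-mean fixed effects for group × interval,
nested random intercepts (participant / eye / sector) and a residual whose
correlation decays continuously with time separation within a sector series
(corr = ρ^|Δweeks|). Estimation is REML; intervals are Wald with a t
reference on containment degrees of freedom.

**Hemodynamics.** MAP = DBP + (SBP − DBP)/3 (112/70 → 84; 150/100 → 117
after integer presentation rounding), summarised at the enrollment, LOT and
delivery anchors with Student-t CIs; rises are paired within participant.
Participants whose LOT is first seen at delivery are excluded from the LOT
anchor.

## Worked example

The deterministic demonstration cohort (11 controls + 27 HDP) plants the
response pattern with unambiguous ≥ 6 µm signals:

```bash
maculatrack run-all --fixture --out-dir out/
```

prints

```
participant classification counts:
  hdp_early_thinning_lt20w: 26
  hdp_hypoperfusion: 5
  hdp_loss_of_thinning: 20
  hdp_participants: 27
  hdp_single_eye_lot: 7
  participants: 38

empirical null exceedance at the configured rule: 0.0000 (314 pairs)
```

Read: of the 27 HDP participants, 26 had macular thinning detected before 20
weeks, 20 later lost that thinning (7 in a single eye only), and 5 suffered
a sudden confluent thinning during a ≥ 15 mmHg blood-pressure drop. The 4 µm
/ 3-sector rule never fired across 314 same-encounter replicate pairs —
planted test–retest noise alone essentially cannot produce three contiguous
4 µm artefacts.

The default configuration (`maculatrack run-all`) instead generates a cohort
whose effect sizes equal the published estimates, with marginal ~4 µm
signals; on it the interval model recovers, for example, early-interval mean
changes (µm, 95% CI)

```
     group epoch  mean  ci_lo  ci_hi
   control early -4.19  -4.70  -3.69
denovo_hdp early -3.90  -4.38  -3.41
```

and the de novo HDP MAP summaries (mmHg)

```
     group        anchor  n  mean  ci_lo  ci_hi
denovo_hdp    enrollment 12  84.3   81.7   86.8
denovo_hdp           lot 11  81.3   77.9   84.7
denovo_hdp      delivery 12 100.5   96.9  104.0
denovo_hdp lot->delivery 11  18.8   16.7   20.8
```

— loss of thinning occurs at a normal pressure, followed by a ≈ 19 mmHg rise
to delivery.

## Layout

| module | contents |
| --- | --- |
| `maculatrack.grid` | ETDRS sector model, adjacency graph, contiguity search |
| `maculatrack.change_rule` | interval change, decision rule, empirical-null calibration |
| `maculatrack.trajectory` | eye/participant longitudinal classification |
| `maculatrack.interval_model` | long table, REML mixed model, interval contrasts |
| `maculatrack.hemodynamics` | MAP computation and anchored summaries |
| `maculatrack.cohort` | synthetic-cohort generator, configs, ground truth |
| `maculatrack.io` / `pipeline` / `cli` | CSV formats, scan selection, end-to-end pipeline, CLI |

See `docs/methods.md` for the modelling assumptions, generator design and
known limitations.
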