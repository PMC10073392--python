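# wpaimc

Anchor-based psychometric validation and meaningful within-patient change
(MWPC) estimation for the **Work Productivity and Activity Impairment
questionnaire (WPAI)** in episodic and chronic migraine.

The package is for biostatisticians and outcomes researchers who need to
establish that a patient-reported outcome instrument is reliable, valid, and
responsive in a trial population, and to derive an interpretable
change-score threshold for individual patients. It implements the full
validation sequence used in preventive-migraine trials, together with a
synthetic two-visit trial generator (visit table + daily headache diary) so
every stage is testable without access to restricted subject-level data such
as the CONQUER trial's.

## What it computes

* **WPAI:SHP v2 scoring** — the four impairment percentages from the six
  items: absenteeism `100·Q2/(Q2+Q4)`, presenteeism `100·Q5/10`, overall
  work productivity loss `100·[Q2/(Q2+Q4) + (1−Q2/(Q2+Q4))·Q5/10]`, and
  activity impairment `100·Q6/10`, with employment gating and per-domain
  complete-case handling.
* **Diary aggregation** — ICHD-3-style migraine / probable-migraine day
  classification, monthly migraine headache days (MHD) with `30/x` proration
  over the non-missing days and a more-than-half-missing rule, and EM/CM
  subtyping.
* **Anchor responder classification** — MSQ-RFR improvement ≥ 25.71,
  MSQ-RFP improvement ≥ 20.00, and a ≥ 50 % MHD reduction.
* **Reliability** — a two-level random-intercept model
  `y_ij = β₀ + u_j + e_ij` fitted by REML in the stable placebo subgroup
  (|ΔMHD| ≤ 1 day), with `ICC = σ²_u/(σ²_u + σ²_e)` and agreement bands.
* **Validity** — Spearman ρ between baseline WPAI scores and the anchors,
  banded interpretation, and the |ρ| ≥ 0.30 anchor-eligibility screen.
* **Responsiveness** — ANCOVA `change ~ responder + baseline` with
  least-squares means per responder group and the LSM difference.
* **MWPC thresholds** — logistic regression and concordance AUC, ROC grids
  over candidate cut-offs with sensitivity/specificity/PPV/NPV, Youden index
  `YI(c) = sens(c) + spec(c) − 1` and phi, per-anchor optimal cut-offs,
  the cross-anchor **max–min Youden consensus threshold**, misclassification
  (1 − specificity) at the threshold, and eCDF curves by responder group.

## Worked example

```
$ python examples/mwpc_thresholds.py
consensus meaningful within-patient change: -20 % units

 anchor  cutoff  youden    phi  sensitivity  specificity
  MHD50  -19.98  0.3427 0.3087       0.6197       0.7230
MSQ_RFP  -20.00  0.3720 0.3566       0.6207       0.7513
MSQ_RFR  -19.99  0.4174 0.3905       0.6625       0.7549

misclassified non-responders at -20 (MHD50): 27.7%
misclassified non-responders at -20 (MSQ_RFP): 24.9%
misclassified non-responders at -20 (MSQ_RFR): 24.5%
```

Applying the max–min Youden rule to the published presenteeism ROC grids
selects a change of **−20 % units** as the meaningful within-patient
improvement: it is the candidate whose worst-case Youden index across the
three anchors is highest, and at that cut-off roughly a quarter of anchor
non-responders would still be labelled improved (1 − specificity).

Other narrative examples in `examples/`: `score_wpai.py` (scoring one
response set), `generate_trial.py` (synthetic-trial calibration),
`reliability_icc.py` (ICC recovery), and `full_pipeline.py` (all stages on a
synthetic trial, writing the CSV report bundle).

A thin CLI wraps the same functions:

```
wpaimc generate --seed 4 --out data/         # synthetic visits.csv + diary.csv
wpaimc score data/visits.csv                 # append the four WPAI scores
wpaimc run --seed 4 --out wpaimc_out         # full pipeline + manifest
```

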