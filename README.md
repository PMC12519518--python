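# bbscreen

Simulation and evaluation toolkit for blood-based biomarker (BBBM)
pre-screening in trial enrichment. It covers the full workflow around a
two-step plasma screen-out rule (ApoE4 protein carrier step, then a pTau181
threshold step for non-carriers):

- **`bbscreen.cohort`** — synthetic screening cohorts with stratified
  carrier/amyloid structure and log10-normal biomarker panels (pTau181, GFAP,
  Abeta42, Abeta40, ApoE4p, plus a CSF model), calibrated so chosen cutoffs
  hit a target operating point; assay-noise and pre-analytical-bias knobs.
- **`bbscreen.reference`** — composite amyloid reference: CSF pTau181/Abeta42
  ratio call (cutoff 0.04, strict) OR-combined with a PET read.
- **`bbscreen.rule`** — the two-step classifier (ApoE4p > 0.668 µg/mL ⇒
  positive; otherwise pTau181 ≥ 0.830 pg/mL ⇒ positive) and the blinding
  pass-through that invites a fraction of rule-negatives onward.
- **`bbscreen.metrics`** — confusion counts, prevalence / PPA / NPA / PPV /
  1-NPV with Wilson score intervals; zero-denominator metrics are reported as
  undefined, never 0.
- **`bbscreen.transfer`** — Bayes prevalence transfer: project PPV, 1-NPV and
  expected screen-out onto any target prevalence from a (prevalence, PPA,
  NPA) operating point, with acceptance flags (screen-out of amyloid-negative
  individuals > 40 %, 1-NPV ≤ 2 %).
- **`bbscreen.cutoffs`** — exhaustive cutoff-pair grid search under those
  constraints, with a deterministic tie-breaking rule and a feasible frontier.
- **`bbscreen.risk`** — logistic risk models (IRLS), risk-percentile
  predictiveness curves (raw, monotone-smoothed and optimal PPV / 1-NPV),
  rank-based AUC, and AUC comparison of the three marker combinations.
- **`bbscreen.flow`** — orchestration of the three-arm participant flow
  (pre-screening arm, direct-entry arm, historic-imaging arm) with funnel
  accounting, acceptance flags, and deterministic serialized reports.

## CLI

The console script `bbscreen` exposes the pipeline stages:

```sh
bbscreen simulate --preset a4_like -n 10000 --seed 1 -o cohort.csv
bbscreen screen --cohort cohort.csv --blind-fraction 0.10 -o screened.csv
bbscreen evaluate --cohort cohort.csv --json
bbscreen transfer --prevalence 0.123 --ppa 0.946 --npa 0.445
bbscreen derive-cutoffs --cohort cohort.csv --apoe4p-grid 0.5,0.668,0.9 \
    --ptau-grid 0.7,0.83,1.0
bbscreen risk-profile --cohort cohort.csv --combo ptau_apoe4p -o curves.csv
bbscreen run -n 10000 --seed 1 --out-dir results/run1
```

Cohorts are plain CSV (one row per participant; missing values as empty
fields); cohort specs round-trip through flat `key: value` config files
(`CohortSpec.to_config` / `from_config`).

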