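# siltriage

Shock-index/lactate (SIL) triage score for sepsis mortality prediction,
with the full diagnostic-accuracy pipeline that validates it against
NEWS, qSOFA and SOFA, and a seeded synthetic emergency-department cohort
generator standing in for patient data.

The SIL score is the sum of a binned shock-index sub-score (PIS, 0–3)
and a binned arterial-lactate sub-score (PL, 0–3), range 0–6, computed
at triage. The package provides:

- **`score_engine`** — SIL, NEWS (NEWS2 Scale 1 by default), qSOFA and
  SOFA calculators over typed `VitalSigns` / `LabPanel` records.
- **`diagnostics`** — 2×2 statistics with binomial CIs,
  prevalence-adjusted predictive values, empirical ROC/AUC with DeLong
  or bootstrap CIs, paired DeLong AUC comparison, odds ratios,
  chi-square tests, and per-score-value mortality stratum tables.
- **`calibration`** — logistic recalibration with per-score-value bins
  and percentile bootstrap uncertainty bands.
- **`synthetic_cohort`** — seeded cohort generator whose defaults
  reproduce the published study margins (stratum sizes, per-stratum
  mortality, sex/shock/comorbidity fractions); rescoring a generated
  cohort always reproduces the assigned strata (`round_trip_check`).
- **`io_cli`** — CSV cohort schema, run configuration and the
  end-to-end pipeline writing a deterministic report bundle.
- **`reference`** — the published summary counts used as fixtures and
  generator defaults.

## CLI

```sh
siltriage simulate --seed 1 --n 299 --out cohort.csv
siltriage score cohort.csv --out scored.csv
siltriage evaluate scored.csv --score-column sil_total
siltriage calibrate scored.csv --seed 1 --reps 1000 --out calibration.csv
siltriage report --seed 1 --out-dir run/          # full pipeline bundle
```

Every verb accepts `--seed` and `--config <json>` (a `RunConfig`
document). `report`/`all` writes the scored cohort, accuracy and AUC
tables, ROC and calibration CSVs, the SIL stratum table and a
`manifest.json` echoing the config and seed; identical config + seed
yields a byte-identical bundle.

Library use:

```python
from siltriage import RunConfig, run_pipeline
run_pipeline(RunConfig(seed=1, n=299, out_dir="run"))
```

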