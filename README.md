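# uripept

CE-MS urinary peptidome profiling and biomarker modeling, end to end:

1. **synthetic** — simulate dosing-study peak-list cohorts (planted
   up/down markers with a transient temporal profile, internal-standard
   and housekeeping peptides, ppm-scale mass noise, affine
   migration-time distortion, per-sample dilution, missingness) plus a
   ground-truth ledger for testing.
2. **calibration** — affine migration-time and linear ppm mass
   calibration against housekeeping reference peptides; global
   multiplicative intensity normalization against internal standards.
3. **matching** — cross-sample feature matching into a master list with
   mass-dependent (50→150 ppm between 4 and 6 kDa) and time-dependent
   (1.0→2.5 min between 19 and 50 min) tolerance windows.
4. **diffstats** — detection-frequency filter (>30 %), rank-sum test on
   ln intensities, Benjamini–Hochberg FDR, Mann–Whitney AUC,
   case/control regulation factor.
5. **selection** — two-study workflow: temporal-response screen,
   cross-study intersection via tolerance windows, direction
   concordance, with a full audit trail.
6. **classify** — panel classifiers: a linear model whose per-marker
   normalization forces a scaled case/control mean distance of exactly
   2, and a linear-kernel SVM; complete take-one-out cross-validation
   with strict per-fold refitting; dose × day time-course scoring.
7. **annotate** — sequence bookkeeping (lowercase p/k/m modification
   codes), basic-residue counting, charge-stratified migration-time
   prediction, and the ±50 ppm / ±2 min / both-engines acceptance
   filter; targeted protein-fragment lookups.
8. **endpoints** — Spearman correlation (exact p for n ≤ 9 without
   ties) of marker intensities and model scores with histopathology and
   clinical-chemistry endpoints.
9. **pipeline / cli** — YAML-configured orchestration of the whole
   synthetic replication with provenance (config hash + seed) sidecars.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (distance-2
exactness, SVM LOO-CV AUC = 1.00 on the 14-vs-25 design, brute-force
oracle equivalence for matching/BH/AUC/rank-sum/Spearman, calibration
parameter recovery, null-cohort FDR control, and the end-to-end
two-study recovery plus time-course signature).

## CLI

```sh
uripept simulate --out study --seed 1
uripept calibrate --refs study/references.csv --in study/peaks --out study/cal
uripept match --in study/cal --out study/master
uripept discover --master study/master --design study/design.csv \
    --case "dose_mg_kg > 0 and 3 <= day <= 10" --control "dose_mg_kg == 0" \
    --out study/markers.csv
uripept run --out fullrun --seed 1        # whole two-study replication
```

Every stage is also importable (`uripept.matching.build_master_list`,
`uripept.classify.loo_cv`, ...).

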