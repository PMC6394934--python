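# pupyscreen

Computational layer of a targeted LC-MS/MS urine assay for purine and
pyrimidine disorders: MRM panel management, synthetic chromatogram and
cohort generation, peak quantitation with internal-standard calibration,
assay-validation statistics (LOD/LLOQ/ULOQ, precision, recovery,
resolution, carryover, stability), age-stratified reference-cutoff
estimation, and rule-based disorder screening.

Everything runs on synthetic, desk-scale inputs: a bundled
machine-readable panel (26 analytes across both ESI polarities, 11
isotopically labeled internal standards, age-conditional cutoffs,
disorder signatures) plus generators for Gaussian MRM peaks on noisy
baselines, the 10-level calibrator series (blank, then doubling from
1 to 256 uM), pediatric reference cohorts with age-dependent log-normal
excretion, and per-disorder pathological profiles.

## Package layout

| module                  | role |
|-------------------------|------|
| `pupyscreen.panel`      | panel registry: transitions, internal standards, cutoffs, signatures, validation |
| `pupyscreen.simulate`   | synthetic chromatograms, calibrator series, cohorts, patient profiles |
| `pupyscreen.prep`       | volumetric prep planning and mmol/mol back-calculation |
| `pupyscreen.quant`      | peak integration, IS-ratio calibration, read-out, carryover |
| `pupyscreen.validation` | LOD / LLOQ / ULOQ, CV, recovery, resolution, stability |
| `pupyscreen.cutoffs`    | trimming, percentile cutoffs, quantile ANOVA over age groups |
| `pupyscreen.diagnose`   | fold-over-cutoff, signature matching, confound handling |
| `pupyscreen.io` / `cli` | trace/table I/O, YAML run configs, the `pupyscreen` CLI |

## CLI

All stages are chained through one executable; every output embeds the
tool version, a config hash and the seed:

```sh
pupyscreen simulate --kind calibrators --out work --seed 1
pupyscreen simulate --kind profile --disorder ADSL --fold 5 --age 6 --out work --seed 1
pupyscreen quantify --calibrators work/calibrator_traces.tsv \
    --samples work/profile_traces.tsv --sample-meta work/sample_meta.json \
    --out work/quantified.tsv
pupyscreen diagnose --profiles work/quantified.tsv --out work/diagnosis.json
pupyscreen report --diagnosis work/diagnosis.json --out work/report.txt

pupyscreen simulate --kind cohort --n 251 --out work --seed 1
pupyscreen cutoffs --cohort work/cohort.tsv --out work/cutoffs.tsv
pupyscreen validate --out work/validation.json
pupyscreen worksheet --creatinine samples.tsv
```

`pupyscreen run --config run.yaml <stage>` drives the same stages from a
YAML config. Data formats are plain tab-separated text and JSON
throughout; the cutoff table emitted by `cutoffs` is the same dialect
the panel registry reads, closing the loop cohort -> cutoffs ->
diagnosis.

## Notes

- Retention times, response factors, peak widths and cohort
  distributions are synthetic fixture choices (documented in the module
  docstrings); only the panel masses/voltages, the decision rules and
  the cutoff values are assay constants.
- Uric acid is deliberately absent from the panel; creatinine enters as
  an externally measured input.
- The age-dependency test is a quantile ANOVA at the cutoff percentile,
  implemented as a pinball-loss reduction statistic referred to a
  permutation null (bootstrap variant behind `method="bootstrap"`).
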