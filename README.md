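# akilinked

Retrospective, population-scale implementation of the NHS England acute
kidney injury (AKI) early-warning algorithm over linked laboratory,
primary-care and hospital-admission records — for epidemiologists and
health-informatics teams who want to detect and characterise AKI across
the primary/secondary care divide from routinely collected data, rather
than inside a single hospital laboratory.

## What it computes

For every serum creatinine result *SCr* of a patient, two baselines are
selected from that patient's own history: the lowest value in the 0–7
days preceding the test, and the median value 8–365 days back. Each
yields a reference value ratio RVR = SCr / baseline, and the **higher
RVR** is staged:

* AKI 1 (low RVR): higher RVR < 1.5 and an SCr rise > 26 μmol/L within
  the preceding 48 h (implemented as a two-day window at date
  granularity);
* AKI 1 (high RVR): 1.5 ≤ RVR < 2;
* AKI 2: 2 ≤ RVR < 3;
* AKI 3: RVR ≥ 3, or RVR ≥ 1.5 with SCr ≥ 354 μmol/L.

Around that core the package provides the full study pipeline:

* **cohort selection** — practices are filtered by biochemical testing
  rate against the Tukey lower fence (Q1 − 1.5 × IQR) of an anchor-practice
  reference distribution; patients must be adults at the observation
  start and continuously registered throughout the study period;
* **alert typing** — each alert is related to inpatient spells and
  classified as community-acquired (not admitted / admitted within 7
  days / identified on admission) or hospital-acquired, plus a
  first-alert-per-patient cross-section;
* **reports** — a demographic (gender × age band) breakdown of SCr
  availability and alerting, and an alert-type table with first-alert and
  all-alert columns;
* **synthetic linked-EHR generator** — practices, patients, SCr
  trajectories with injected AKI episodes and admission spells, with
  per-episode ground truth, so everything is testable without real data.

See `docs/methods.md` for the model, parameter and design details.

## Worked example

Generate a synthetic linked bundle and run the whole pipeline:

```sh
akilinked simulate --seed 7 --out-dir data/
akilinked run --data-dir data/ --out-dir results/
```

The run prints both reports; with seed 7 and default settings
(10,000 patients, observation year 2014, look-back through 2013):

```
 group label    n  pct_scr_0_1  pct_scr_2plus  patients_alerted  pct_alerted  alerts
cohort   All 8098         71.9           28.1                36          0.4     133
gender     F 4143         72.3           27.7                16          0.4      68
gender     M 3955         71.5           28.5                20          0.5      65
   age 18-24  824         90.8            9.2                 3          0.4       8
   age 25-34 1268         89.4           10.6                 5          0.4       6
   ...
   age 85-94  245         33.5           66.5                 2          0.8       8

                         label        aki_type  first_n  first_pct  all_n  all_pct
           Not admitted CA-AKI CA_NOT_ADMITTED       10       27.8     12      9.0
 CA-AKI admitted within 7 days  CA_ADMITTED_7D        2        5.6      2      1.5
CA-AKI identified on admission CA_ON_ADMISSION        3        8.3      8      6.0
                    All CA-AKI          ALL_CA       15       41.7     22     16.5
                    All HA-AKI              HA       21       58.3    111     83.5
                         Total           TOTAL       36      100.0    133    100.0
```

Reading it: 8,098 of the 10,000 simulated patients survive cohort
selection (deficient-testing practices and incomplete registrations are
excluded); 28.1% hold the two-plus SCr results needed for detection, a
share that climbs steeply with age band; 36 patients alert during the
observation year, generating 133 alerts. Most *first* alerts arise from
community tests, while *all* alerts skew heavily hospital-acquired —
near-daily in-patient re-testing makes one episode alert many times.
The same pipeline is available as a library:

```python
from datetime import date
from akilinked import AlgorithmConfig, run_pipeline

result = run_pipeline(
    "data/patients.csv", "data/practices.csv",
    "data/scr_results.csv", "data/admissions.csv",
    study_start=date(2013, 1, 1),
    obs_start=date(2014, 1, 1), obs_end=date(2014, 12, 31),
    cfg=AlgorithmConfig(),            # every threshold is configurable
    out_dir="results/",
)
result.alerts          # staged alerts with their reference values
result.manifest        # config hash, input checksums, stage counts
```

Intermediate steps (`simulate`, `select-cohort`, `detect`, `classify`)
are also exposed as subcommands and as functions.

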