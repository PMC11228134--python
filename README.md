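# esourceflow

Clinical trials traditionally collect data by having a clinical research
coordinator read the hospital's electronic health record (EHR) and retype it
into the sponsor's electronic data capture (EDC) system. *eSource* replaces
that manual transcription: structured data is extracted from the EHR,
deidentified inside the hospital, mapped onto the trial's case report form
(CRF) standard, and pushed once — checksummed — into the sponsor's
environment. `esourceflow` implements that whole data flow on synthetic
hospital records and scores the result with the industry data-quality
metrics, for data managers and health-informatics researchers who want an
executable, testable model of an EHR→EDC pipeline.

## The data flow

1. **Synthetic study generation** — a deterministic generator emulates a
   six-patient oncology trial with four CRF domains (demographics, vital
   signs, local laboratory blood/urine panels, concomitant medication),
   realistic identifiers and dates, an electronic/paper provenance mix
   (most medication and vital-sign points exist only on paper tracking
   forms), and a parallel manually-entered EDC truth set.
2. **Three-layer deidentification** — direct-identifier columns are
   dropped; the 18 HIPAA Safe-Harbor categories are masked (dates become
   signed day offsets from a per-patient base date, record numbers become
   surrogates); project rules categorize IDs, bin ages (10-year bins capped
   at ≥90) and null low-frequency values. Every mutation is logged in an
   append-only audit trail carrying SHA-256 digests, and a reversal key is
   kept separately.
3. **ETL and one-time push** — electronic records are extracted, coded
   Chinese tokens are translated through a terminology dictionary, fields
   are mapped onto CRF pages, and the transfer set is serialized to JSON,
   XML (schema-validated) and CSV with a checksummed manifest under
   one-time push semantics.
4. **Quality evaluation** — four ratio metrics, reported as percentages
   rounded half-up to two decimals:

   | metric | definition |
   |---|---|
   | EHR-CRF availability | EHR / CRF × 100% (field dimension) |
   | eSource-CRF availability | eSource / CRF × 100% |
   | completeness | eSourceV / CRF-required points × 100% (value dimension) |
   | accuracy | matching transferred points / transferred nonnull points × 100% |

   where *CRF* is the number of fields (or required data points) the trial
   requests, *EHR* the number present in the hospital system, *eSource* the
   number electronically transferable, and *eSourceV* the number of nonnull
   points actually captured and sent.

## Worked example

```python
from esourceflow import PipelineConfig, pilot_study_config, run_pipeline

config = PipelineConfig(study=pilot_study_config(seed=1), output_dir="out")
result = run_pipeline(config)
print(result.report.to_text())
```

prints

```
             CRF domain CRF-EHR data availability CRF-eSource data availability   Data completeness        Data accuracy
           Demographics               3/6 (50.00)                   2/6 (33.33)      12/12 (100.00)       12/12 (100.00)
            Vital signs            10/10 (100.00)                  9/10 (90.00)      24/1812 (1.32)       24/24 (100.00)
Blood biochemical tests              6/10 (60.00)                  5/10 (50.00) 12968/13540 (95.78) 12968/12968 (100.00)
     Urine sample tests               6/9 (66.67)                   5/9 (55.56)       15/40 (37.50)       15/15 (100.00)
 Concomitant medication            10/10 (100.00)                  9/10 (90.00)       14/76 (18.42)       14/14 (100.00)
```

Reading the rows: only 3 of the 6 demographics fields exist in the EHR at
all (trial subject ID, ethnicity and race do not), and only 2 survive to
electronic transfer once date of birth is excluded by deidentification
policy. Vital signs are fully available yet almost entirely incomplete
(1.32%) because they are recorded on paper forms; the blood panel — a fully
electronic laboratory feed — reaches 95.78% completeness across 2708 tests.
Accuracy is 100% everywhere: whatever the pipeline does transfer matches
the manually entered EDC values exactly.

The same flow is available from the shell:

```sh
esourceflow run --config examples/pilot.yaml --output out
```

with `generate`, `deidentify`, `transform`, `push` and `evaluate`
subcommands for running stages individually, and `validate` for config
files.

## Layout

- `src/esourceflow/crf_model.py` — CRF field dictionary, mapping rules, pages
- `src/esourceflow/synthetic_ehr.py` — study configuration and generator
- `src/esourceflow/deidentify.py` — three deidentification layers, audit, reversal key
- `src/esourceflow/etl_transform.py`, `formats.py`, `terminology.py` — extraction, translation, serialization, push
- `src/esourceflow/quality_metrics.py` — the four metrics and the report
- `src/esourceflow/pipeline.py`, `cli.py` — orchestration and command line
- `docs/methods.md` — model, assumptions, parameter choices and limitations
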