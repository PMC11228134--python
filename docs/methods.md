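# Methods

## What the package models

`esourceflow` is an executable model of an eSource data flow: hospital EHR →
in-hospital deidentification → terminology translation and CRF mapping →
one-time checksummed push into a sponsor environment → data-quality
evaluation. The system under study is a small oncology trial at a single
hospital: six enrolled patients, four well-structured CRF domains, and a
mixed electronic/paper source landscape in which laboratory results arrive
through a LIMS feed while vital signs and most concomitant-medication
entries live on paper tracking forms.

## The CRF schema and availability

Availability is a *schema-level* property: a field counts as EHR-available
if the hospital system declares it as structured data, independent of any
patient's records. This makes the two availability metrics data-independent
and reproducible from the field dictionary alone.

The canonical dictionary carries 45 per-module field slots across five
modules (the blood and urine panels are separate modules because they are
scored separately). All 29 distinct collection-field names of the trial's
field list appear; the remaining slots are standard CRF fields that the
hospital systems do not hold and that motivate the availability gaps:
trial-specific identifiers ("Subject ID", "Sponsor number", "Lab ID"),
fields requiring an investigator's interpretation ("Clinically
Significant", "Not Done", adverse-event relatedness), and ConMed dosing
fields (Dose, Dose unit, Frequency, Route). Three flag choices are
assumptions the source material does not pin down exactly and are
documented as such:

* demographics: date of birth, sex and age are the three EHR-available
  fields; date of birth is excluded from transfer by deidentification
  policy, leaving sex and age transferable;
* vital signs: the temperature-measurement location is the one field held
  only as free text, hence not transferable;
* laboratory: "Laboratory name and address" is present but unstructured
  (available, not transferable).

## The synthetic study generator

The generator is a pure function of a `StudyConfig`; identical
configurations produce byte-identical serialized stores. All randomness
flows from one integer seed through named per-section generators drawn in a
fixed order (identity, corruption, vitals, blood, urine, conmed).

The value-level denominators are explicit design counts, not derived from a
visit schedule: the study's vital-signs requirement (1812 points) is not
decomposable into patients × visits × fields, so the generator distributes
configured point counts over patients and pages (pages hold up to one cell
per tracked field; trailing pages may be partial). Default counts in
`pilot_study_config()` are the pilot study's published ones: vitals
1812 required / 24 captured, blood 2708 tests × 5 transferable cells =
13,540 required / 12,968 nonnull, urine 40 / 15, ConMed 38 pages × 2
tracked fields / 7 electronic pages (≈80% paper), demographics 2 points per
patient, fully captured.

Provenance modelling differs by source system: the laboratory blood feed is
fully electronic with nulls carving out incompleteness (null cell positions
are drawn without replacement from a seeded generator); vitals, urine and
ConMed points beyond the captured counts exist only as paper-provenance
records, which the extraction stage never emits. Patient identities (names,
national-ID-like and phone-like strings, addresses, record numbers, birth
dates) are synthetic but realistic enough that the deidentification layers
do real work; coded clinical values are Chinese source tokens so the
terminology dictionary lookup is exercised on every coded field.

With `corruption_rate` > 0 each electronic cell is independently replaced
by a gross transcription error. Corruptions are designed to survive the
deidentification layer's coarsening — dates jump by 997 days, ages move to
a different 10-year bin while staying in range, accession IDs flip their
panel prefix, coded tokens switch to a different valid token — so the
observed mismatch fraction estimates the configured rate (binomially).
What the generator does **not** emulate: free-text clinical narratives,
imaging, realistic visit calendars, cross-field physiological correlation,
or missingness mechanisms beyond the configured counts. Passing tests
therefore validate the pipeline mechanics and metric arithmetic, not
performance on real hospital data.

## Deidentification

Layer 1 drops configured direct-identifier columns (name, national ID,
phone, address) before anything else touches the data. Layer 2 applies
HIPAA Safe-Harbor masking per category: dates (category 3) become signed
day offsets via `shift_date`, record/account identifiers become surrogates
recorded in the reversal key, contact categories are removed. Layer 3
applies the project's general rules: ID values reduce to ordered-rule
categories (first match wins, catch-all fallback required), ages to
10-year bins with a single ≥90 top bin (the Safe-Harbor age cap), and
low-frequency values — singletons are quasi-identifiers — are set to null
at the default threshold k = 2. The exact assignment of fields to layers 1
versus 2 is configuration, not an assertion about the original system.

Design choices: the base-date policy defaults to each patient's first
record date, which preserves within-patient intervals while decoupling
patients from one another and from the calendar; audit entries store
SHA-256 digests rather than values so the log itself leaks nothing;
idempotence is enforced by a store-level flag (a deidentified store passes
through unchanged with an empty audit log); the reversal key is written as
a separate artifact with a pluggable at-rest codec and is never part of a
transfer dataset.

## ETL, serialization and push

Only electronic-provenance records from a store flagged deidentified are
extracted. Mapping emits one CRF page per (subject, module, page index)
with a value slot for every transferable field; coded tokens go through the
dictionary and unknown tokens are flagged unmapped and excluded — they cost
completeness, never accuracy. Mapping output is sorted, making the stage
order-independent and byte-reproducible.

"Excel format" is implemented as CSV for bit-exact testability (UTF-8,
comma, quote-doubling, `\n`); nulls are kept distinct from empty strings in
every format (JSON `null`, XML `nil="true"`, an explicit `is_null` CSV
column — no CSV dialect survives a quoting-based distinction through
standard readers). Dates in transfer data are always day offsets, never
calendar dates. The push writes one file per module and format plus a
manifest (`sha256` per file, record counts); a dataset pushes exactly once
unless forced, and verification recomputes every checksum.

## Quality metrics

All four metrics are ratios printed as percentages rounded **half-up** to
two decimals; banker's rounding is rejected because 5/9 must print 55.56.
Completeness denominators are per-module design counts (see generator), not
fields × visits. Accuracy is computed only over transferred nonnull points —
the published 100% accuracy coexists with 1.32% completeness, so missing
points cannot be in the denominator — and an empty comparison raises an
error rather than scoring 100. Matching is normalized: whitespace trimmed,
coded values case-folded, integer strings compared numerically, measurement
strings compared exactly as decimal strings (the comparison is between two
transcriptions, not floating-point computations).

Because the transferred values live in deidentified coordinates, the manual
EDC truth is projected through the same rules before pairing: truth dates
are shifted with the same per-patient base, ages binned with the same bins,
accession IDs categorized with the same map. Without this projection the
accuracy metric would punish the deidentification layer instead of the
transcription.

Known discrepancy: the urine completeness fraction 15/40 equals 37.50%,
which is what the package reports; the source table prints 37.56 against
its own fraction. Accuracy pair counts are reported over *all* transferred
nonnull points per module; the original study compared subsets of sizes it
does not derive, so its accuracy denominators (e.g. 20 vital-sign points)
are not reproduced — the percentages are.

## Numerical and degenerate-input choices

* Rounding: `decimal.Decimal` quantization, `ROUND_HALF_UP`, two places.
* Zero denominators raise `MetricUndefinedError`; an empty study therefore
  completes with empty artifacts and the undefined-metric condition
  surfaced, never a row of zeros.
* Ties/ordering: pages sort by (module, subject, page index); mapping-rule
  order follows the dictionary's field order; subject surrogates are
  assigned in enrolment-roster order.
* Seeds are strings of the form `"{seed}:{section}"` fed to independent
  `random.Random` instances (stable across platforms and runs).

## Problem sizes

The default pilot design (15,480 required data points, ~2,960 records) runs
end to end in a couple of seconds; the corruption-recovery check uses a
four-patient design with ~10,000 electronic points, large enough for a
3-standard-deviation binomial band of ±0.9 percentage points around the
10% rate.

## Limitations

No network transport, VPN or HL7 message construction (the push is a
directory contract); no CDISC ODM/SDTM conformance; no statistical
disclosure-risk scoring (k-anonymity etc.); no free-text PHI detection; no
confidence intervals on the reported proportions (the evaluation reports
raw ratios, as the underlying quality-assessment rules do).
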