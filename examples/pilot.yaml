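# Pipeline configuration for the built-in pilot study.
# `study: pilot` selects the study design with the published counts
# (6 patients, 2708 blood tests, 38 ConMed pages, ...); replace it with an
# explicit mapping of StudyConfig fields to run a custom design.
study: pilot
deid: default
seed: 1
output_dir: esourceflow-out
formats: [json, xml, csv]
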