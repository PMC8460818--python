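# Reduced synthetic-cohort configuration for a quick end-to-end run.
# Omitted fields keep their defaults (see periglioma.cohort.CohortConfig);
# the full clinical scale is 45 patients / 36 controls, 78 regions,
# 300 s at 1250 Hz.
n_patients: 16
n_controls: 12
n_regions: 20
sampling_rate: 250.0
recording_duration: 52.5       # four 13.1 s epochs
artifact_rate: 0.05
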