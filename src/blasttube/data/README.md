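# Packaged data

`swine_cohort.csv` — transcription of the published 17-animal swine cohort
of the confined-space blast-tube body-armor study (per-animal body weight,
body-armor assignment, necropsy organ-damage remarks, immediate respiratory
arrest, and 3-hour outcome).  Organ-damage abbreviations: LH = lung
hemorrhage, IAH = intra-abdominal hemorrhage, BR = bladder rupture.

The remarks column is free text and is parsed by keyword matching; see
`blasttube.injury_stats.parse_cohort`.
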