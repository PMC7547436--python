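# Registry CSV data dictionary

One row per waitlisted patient, as written by `renalloc.write_registry` /
`renalloc simulate-registry`. Missing values are empty fields. All times
are in years.

| column | type | clock origin | description |
|---|---|---|---|
| `patient_id` | string | — | opaque identifier, unique per row |
| `age_at_listing` | float | — | recipient age in years when waitlisted |
| `epts` | float > 0 | — | recipient-quality score (Estimated Post-Transplant Survival); lower = better expected survival |
| `listed_time` | float | study origin | listing time (0 for a cohort listed at origin) |
| `transplant_time` | float > 0 or empty | listing | time to deceased-donor transplant; empty if never transplanted during follow-up |
| `donor_age` | float or empty | — | donor age in years; present iff transplanted |
| `donor_kdri` | float > 0 or empty | — | donor-quality score (Kidney Donor Risk Index); higher = worse expected graft survival; present iff transplanted |
| `graft_failure_time` | float > 0 or empty | transplant | time to graft failure; at most one of graft failure / death is observed per record |
| `death_time` | float > 0 or empty | listing if untransplanted, transplant if transplanted | time to death |
| `censor_time` | float > 0 | listing if untransplanted, transplant if transplanted | administrative censoring time on the same clock as the record's terminal events |

The post-graft-failure dialysis cohort (second dataset, from
`generate_post_graft_failure_cohort`) has two columns: `time` (years on
dialysis since graft failure, integer-valued at events) and `event`
(1 = died, 0 = administratively censored).
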