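# Trial-table column dictionary

One CSV row per patient per assessment wave (months 0, 6, 12); every
patient has exactly one row per wave. Empty cells mean *missing* — a
reported zero and an unreturned questionnaire are different facts and
are never conflated. UTF-8, comma-separated.

| column | type | meaning |
| --- | --- | --- |
| `patient_id` | string | opaque patient identifier; constant across waves |
| `arm` | `intervention` \| `control` | randomization group; constant across waves |
| `wave` | 0, 6 or 12 | assessment month |
| `gender` | `female` \| `male` | |
| `employed` | boolean | in paid employment at baseline |
| `wage_per_hour` | euros, nullable | gross hourly wage (employed patients) |
| `usual_hours_per_day` | hours, nullable | hours normally worked per day (paid or volunteer work) |
| `hdrs17` | integer 0–52, nullable | 17-item Hamilton depression score |
| `utility` | index ≤ 1, nullable | health-state utility; negative values permitted |
| `eq5d_state` | 5 digits 1–5, nullable | EQ-5D-5L profile, e.g. `21123`; used with a tariff when `utility` is empty |

Resource use over the **4-week recall window** ending at the wave
(all counts ≥ 0, fractional values allowed for hours/days):

| column | unit |
| --- | --- |
| `gp_contacts` | contacts with GP / practice nurse |
| `mental_care_contacts` | contacts with psychiatrist, psychiatric nurse, psychologist, social worker |
| `other_care_contacts` | physiotherapist, dietician, alternative care |
| `home_help_hours` | paid home help hours |
| `medication_days` | days of psychotropic medication use |
| `travel_trips` | care-related trips |
| `family_help_hours` | informal help from family/friends |
| `paid_absenteeism_days` | full days absent from paid work |
| `paid_presenteeism_days` | efficiency-equivalent lost days while at paid work |
| `unpaid_absenteeism_days` | days absent from volunteer/unpaid work |
| `unpaid_presenteeism_days` | efficiency-equivalent lost unpaid-work days |

Treatment sessions accrued **since the previous wave** (lump
quantities, costed per elapsed period, treated as administrative
records rather than recall items):

| column | unit |
| --- | --- |
| `rtms_sessions` | stimulation sessions |
| `psychotherapy_sessions` | psychotherapy (e.g. CBT) sessions |

The unit-cost table (`src/trialcea/data/unit_costs.csv`, illustrative
values) maps each resource to euros per unit with columns `resource`,
`unit`, `unit_cost_eur`, `source_year`; a consumer-price-index factor
re-expresses the price year once, at load.
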