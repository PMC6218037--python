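# Cohort file schema (v1)

Cohort waves are CSV: UTF-8, header row, one row per participant-wave,
missing marker `NA`. Columns and units:

| column | type | description |
|---|---|---|
| id | int | participant identifier, stable across waves |
| wave | str | `baseline` or `followup` |
| eb_id | int/str | enumeration-block (first-stage cluster) id |
| lq_id | int/str | living-quarters (second-stage cluster) id |
| age | years | ≥ 60 |
| gender | str | `man` / `woman` |
| ethnicity | str | `malay` / `chinese` / `indian` / `other` |
| marital_status | str | `married` / `divorced` / `widowed` / `single` |
| education_level | str | `none` / `primary` / `secondary` / `tertiary` |
| living_arrangement | str | `with_others` / `alone` |
| income_monthly | currency | monthly household income |
| dssi_score | int | Duke Social Support Index total |
| mmse_score | int | Mini-Mental State Examination, 0–30; < 9 excluded at load |
| chronic_diseases | str | `;`-separated disease labels, empty for none |
| weight_current | kg | measured weight |
| weight_at25 | kg | self-reported weight at age 25 |
| height | cm | measured height |
| grip_left_1, grip_left_2 | kgf | left-hand dynamometer trials |
| grip_right_1, grip_right_2 | kgf | right-hand dynamometer trials |
| walk_time_1, walk_time_2 | s | 4-m walk trials |
| pase_score | real ≥ 0 | Physical Activity Scale for the Elderly total |
| gds_energy | str | `yes` / `no` answer to "Do you feel full of energy?" |

Generated state-mode files additionally carry `latent_state`
(robust/prefrail/frail) and any configured exposure columns (0/1).

Scoring appends: `flag_weightloss`, `flag_exhaustion`, `flag_lowactivity`,
`flag_weakness`, `flag_slowness` (0/1/NA), `frailty_score` (0–5/NA),
`frailty_state` (robust/prefrail/frail/NA). Weighting appends `weight`
(positive real). Covariate derivation appends `income_category`,
`social_support`, `cognitive_category`, `cognitive_binary`,
`chronic_count`, `chronic_band`, `age_group`, `age_band5`. Imputed files
carry a leading `imputation` index column.

Threshold sets persist as YAML with keys `pase_cutoff`,
`bmi_quartile_bounds` (per gender, [q25, q50, q75]), `grip_cutoff`
(`gender:quartile` → kgf), `height_median` (per gender, cm), `walk_cutoff`
(`gender:stratum` → s) and `derived_from` (provenance sizes).
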