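# File schemas

All tabular files are UTF-8 CSV; models, patterns and reports are JSON.
Missing values are forbidden in threshold columns. Every writer embeds
`tool`, `version` and, where applicable, `seed` and `config_hash`.

## subjects.csv

One row per enrolled subject.

| column | type | notes |
|---|---|---|
| subject_id | str | `S####` included, `X####` screen-failed |
| age | int | years |
| sex | enum | `male`, `female` |
| race | enum | `white`, `black`, `asian`, `native_american`, `pacific_islander`, `multiple`, `other` |
| ethnicity | enum | `hispanic`, `not_hispanic` |
| va_logmar | float | best-corrected acuity; 20/40 = 0.301 |
| iop_od, iop_os | float | mmHg |
| se_od, se_os | float | spherical equivalent, D |
| cyl_od, cyl_os | float | cylinder, D |
| exclusion_reason | enum | `none` for included subjects |
| binocular_capable | bool | False = tested one eye at a time |

Example row:

```
S0001,26,female,white,not_hispanic,0.113,16.4,19.1,-2.93,4.51,0.63,-1.67,none,True
```

## tests_<pattern>.csv

One row per eye per administration; one file per pattern (`tests_24-2.csv`,
`tests_10-2.csv`).

| column | type | notes |
|---|---|---|
| seq | int | position in the cohort's acquisition order (cohort files only) |
| subject_id | str | |
| eye | enum | `OD`, `OS` |
| pattern_id | enum | `24-2`, `10-2` |
| is_practice | bool | practice tests precede study tests |
| attempt | int | 1–3 (reliability retests) |
| foveal_db | float | foveal threshold, dB |
| fl_rate, fp_rate, fn_rate | float | catch-trial failure proportions in [0, 1] |
| duration_min | float | binocular test duration, minutes |
| v00 … vNN | float | thresholds in pattern order (54 or 68 columns), dB, [0, 40]; for OS rows the order is the mirrored grid's own enumeration |

## meta.json (cohort sidecar)

`tool`, `version`, `seed`, `config_hash`, the full generating `config`
(including the truth maps), and the embedded `patterns` (ordered
`[x, y, is_blind_spot]` triples per pattern). `read_cohort` restores the
cohort losslessly from these files.

## Pattern JSON

```json
{"pattern_id": "24-2", "spacing": 6, "points": [[-9, 21, false], ...]}
```

Points are re-sorted to canonical order on load; this is the supported hook
for substituting a vendor-exact layout.

## Model JSON (`format_version: 1`)

| key | content |
|---|---|
| pattern | embedded pattern JSON |
| reference_age | mean cohort age used in the build |
| alpha, slope, s2 | per-point arrays (null at blind spots); prediction is `alpha + slope * age` |
| resid_quantiles | level (%) → per-point array, levels 0.5–99.5; lower four are the TD limits |
| pd_quantiles | level → per-point pattern-deviation limits |
| gh_k | general-height rank |
| md_limits, psd_limits, foveal_limits | level → scalar limit |
| foveal_alpha, foveal_slope, foveal_s2 | foveal regression |
| n_subjects, provenance | build metadata (seed, rule, date) |

The loader re-validates monotone quantile tables, positive variances and
ordered limits, and rejects unknown format versions.

## Result JSON (analyze)

`td`, `pd` (per-point arrays, null at blind spots), `gh`, `md`, `psd`,
`foveal_dev`, per-point `prob_td`/`prob_pd` and scalar `prob_md`/`prob_psd`/
`prob_foveal` with categories `ns`, `p5`, `p2`, `p1`, `p05`.

## Sample-size CSV

One row per candidate n: `n`, `n_sim`, `nonoverlap_fraction`,
`nonoverlap_across_simulations`, and per-percentile across-simulation CI
bounds `p<level>_ci_lo` / `p<level>_ci_hi`.
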