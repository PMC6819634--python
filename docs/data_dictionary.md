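# Data dictionary: wide cohort CSV

One row per woman; empty cell = missing. Columns:

| column | values | notes |
|---|---|---|
| `id` | text | unique |
| `ipv_w1` … `ipv_w6` | `Y`, `N`, empty | "Have you ever been in a violent relationship with a partner/spouse?" at waves 1..6 (1996, 2004, 2007, 2010, 2013, 2016; source surveys 1, 4, 5, 6, 7, 8) |
| `rel_w1` … `rel_w6` | `married`, `defacto`, `separated`, `divorced`, `widowed`, `single`, empty | relationship status per wave |
| `pstress_w1` … `pstress_w6` | `Y`, `N`, empty | very/extremely stressed about partner relationship |
| `istress_w1` … `istress_w6` | `Y`, `N`, empty | income impossible/always difficult to manage on |
| `area` | `major_city`, `inner_regional`, `outer_regional`, `remote_very_remote`, empty | baseline ARIA+ remoteness category |
| `qual` | `lt_year12`, `year12`, `trade_cert_diploma`, `university`, empty | baseline highest qualification |

Alternative cell codes can be mapped via the `dialect` argument of
`read_cohort` (e.g. `{"area_codes": {"MC": "major_city"}}`).

## Relationship-trajectory truth table

Let b / e = separated-or-divorced at the first / last answered wave, and
*ever* = separated or divorced at any answered wave. Widowed and single
count as not separated/divorced.

| ever | b | e | trajectory |
|---|---|---|---|
| no | – | – | `never_sep_div` |
| yes | yes | yes | `remained_sep_div` |
| yes | yes | no | `became_partnered` |
| yes | no | any | `became_sep_div` |

All statuses missing → missing covariate (record flagged incomplete, kept
in descriptives, dropped-and-reported by the regression).
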