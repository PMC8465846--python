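# Data dictionary

All tables are UTF-8 CSV with a header row; missing values are empty
fields. Dates are DD/MM/YYYY or ISO-8601 (`YYYY-MM-DD`); writers emit ISO.

## Inputs (consumed by `read_trial` / produced by `simulate`)

### genotypes.csv
| column | type | notes |
|---|---|---|
| id | string | unique genotype id |
| role | enum | `female_parent`, `male_parent`, `hybrid`, `check_replicated`, `check_unreplicated` |
| female_id | string | present iff role = hybrid; must resolve in this file |
| male_id | string | present iff role = hybrid |

### trial_meta.csv
| column | type | notes |
|---|---|---|
| location | string | |
| latitude, longitude | degrees | |
| plot_size_m2 | m² | |
| sowing_date, harvest_date | date | harvest > sowing |
| sowing_density_factor | unitless | hybrid density relative to lines, (0, 1] |

### plots.csv
| column | type | notes |
|---|---|---|
| plot_id | string | globally unique |
| location | string | must resolve in trial_meta.csv |
| block | integer | 1..n_blocks |
| genotype_id | string | must resolve in genotypes.csv |

### traits_long.csv
| column | type | notes |
|---|---|---|
| plot_id | string | |
| trait | enum | one of the 21 trait codes below |
| value | float | trait units; empty = missing |

Trait codes: YLD (t/ha), GPC (%), SW (kg/hL), HD (days from Jan 1),
HT (cm), SEEDA (mm²), SEEDL (mm), SEEDW (mm), TKW (g), GPY (t/ha),
GPSM (grains/m²), Nmax (NDVI), GPA/FPA/SPA/DPA/TA (NDVI·°C days),
TFN90/TFN50/TFN10/TFN1 (°C days from heading).

### ndvi_long.csv
| column | type | notes |
|---|---|---|
| plot_id | string | |
| date | date | observation date |
| ndvi | float | [0, 1] |

### weather.csv
| column | type | notes |
|---|---|---|
| location | string | |
| date | date | contiguous daily coverage of the cycle |
| tmin, tmax | °C | tmax ≥ tmin |
| rainfall | mm | |

## Pipeline outputs

* `phenology_traits.csv` — plot_id + nmax, tfn90..tfn1, gpa..ta.
* `phenology_models.csv` — fitted coefficients a1..b3, NDVI_final/amplitude,
  phase boundaries, per-phase R, availability flags.
* `blues_location.csv`, `blues_combined.csv` — long (unit, location, trait,
  value, level) adjusted means.
* `heritability.csv` — trait, scope, location, h2, sigma2_g, sigma2_gxl,
  sigma2_res, n_bar, l, truncated.
* `heterosis_records.csv` — per (hybrid, trait) values, mid/best parent,
  het_mp/het_bp (%), undefined flag.
* `heterosis_summary.csv` — trait, kind, n_hybrids, mean_pct, p_value,
  min/max_pct, cv, frac_positive.
* `correlations.csv` — trait_a, trait_b, r, p, n, stars (long, symmetric).
* `ancova_results.csv`, `gpd.csv`, `gpd_test.csv` — group contrasts.
* `truth/*.csv` — simulator ground truth (never read by the pipeline).
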