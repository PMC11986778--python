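# Default covariate codebook: the individual-, household- and neighbourhood-level
# roster used by the main model, with treatment-coding reference levels.
#
# kinds:
#   indicator    -- 1 where source == level, 0 otherwise (reference = other level)
#   categorical  -- one dummy per non-reference level, named <name>_<level>
#   continuous   -- numeric value; standardize: true -> centred/scaled before modelling
#   threshold_ge -- 1 where source >= threshold (binary contrast)
#   range        -- 1 where lo <= source <= hi
covariates:
  sex_male:
    source: sex
    role: individual
    kind: indicator
    level: male
    reference: female
  ethnicity_other:
    source: ethnicity
    role: individual
    kind: indicator
    level: other
    reference: white
  obesity:
    source: obesity
    role: individual
    kind: categorical
    reference: normal
    levels: [normal, overweight, obese]
  longstanding_illness:
    source: longstanding_illness
    role: individual
    kind: indicator
    level: 1
    reference: 0
  poverty_below:
    source: poverty
    role: household
    kind: indicator
    level: 1
    reference: 0
  maternal_education:
    source: maternal_education_nvq
    role: household
    kind: categorical
    reference: 1
    levels: [1, 2, 3, 4, 5]
  maternal_depression:
    source: maternal_depression_at_birth
    role: household
    kind: indicator
    level: 1
    reference: 0
  family_single:
    source: family_structure
    role: household
    kind: indicator
    level: single
    reference: couple
  urban:
    source: urban
    role: neighborhood
    kind: indicator
    level: 1
    reference: 0
  pm25:
    source: pm25
    role: neighborhood_time_varying
    kind: continuous
    units: ug/m3
  pm10:
    source: pm10
    role: neighborhood_time_varying
    kind: continuous
    units: ug/m3
  no2:
    source: no2
    role: neighborhood_time_varying
    kind: continuous
    units: ug/m3
  ndvi:
    source: ndvi
    role: neighborhood_time_varying
    kind: continuous
    standardize: true
  green_area:
    source: green_area_ha
    role: neighborhood_time_varying
    kind: continuous
    standardize: true
  imd_4_10:
    source: imd_decile
    role: neighborhood_time_varying
    kind: threshold_ge
    threshold: 4
  imd_4_7:
    source: imd_decile
    role: neighborhood_time_varying
    kind: range
    lo: 4
    hi: 7
  imd_8_10:
    source: imd_decile
    role: neighborhood_time_varying
    kind: range
    lo: 8
    hi: 10
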