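# Clinical variable schema for the simulated COPD triage cohort.
#
# Groups: profile (stable patient background), comorbidity, symptom (current),
# vital (current measurements), baseline_vital (the patient's usual values,
# used for delta features). "unknown" is an admissible response everywhere
# except age, weight, height, gender, baseline dyspnea and the symptom
# questions.
#
# Continuous units: age years; weight lb; height inches; o2sat percent;
# fev1 percent of predicted; heartrate BPM; temperature degrees F.
variables:
  - {name: age,               kind: continuous,  group: profile,        range: [40, 95],  units: years,   allows_unknown: false}
  - {name: weight,            kind: continuous,  group: profile,        range: [80, 350], units: lb,      allows_unknown: false}
  - {name: height,            kind: continuous,  group: profile,        range: [54, 80],  units: inches,  allows_unknown: false}
  - {name: gender,            kind: categorical, group: profile,        levels: [male, female],           allows_unknown: false}
  - {name: gold,              kind: categorical, group: profile,        levels: ['1', '2', '3', '4'],     allows_unknown: true}
  - {name: mmrc_base,         kind: categorical, group: profile,        levels: ['1', '2', '3', '4', '5'], allows_unknown: false}
  - {name: recent_exac,       kind: categorical, group: profile,        levels: ["yes", "no"],                allows_unknown: true}
  - {name: lives_alone,       kind: categorical, group: profile,        levels: ["yes", "no"],                allows_unknown: true}
  - {name: smoker,            kind: categorical, group: profile,        levels: ["yes", "no"],                allows_unknown: true}
  - {name: oxygen_user,       kind: categorical, group: profile,        levels: ["yes", "no"],                allows_unknown: true}
  - {name: assisted_activity, kind: categorical, group: profile,        levels: ["yes", "no"],                allows_unknown: true}
  - {name: chf,               kind: categorical, group: comorbidity,    levels: ["yes", "no"],                allows_unknown: true}
  - {name: hbp,               kind: categorical, group: comorbidity,    levels: ["yes", "no"],                allows_unknown: true}
  - {name: cad,               kind: categorical, group: comorbidity,    levels: ["yes", "no"],                allows_unknown: true}
  - {name: diabetes,          kind: categorical, group: comorbidity,    levels: ["yes", "no"],                allows_unknown: true}
  - {name: anemia,            kind: categorical, group: comorbidity,    levels: ["yes", "no"],                allows_unknown: true}
  - {name: pulm_htn,          kind: categorical, group: comorbidity,    levels: ["yes", "no"],                allows_unknown: true}
  - {name: acid_reflux,       kind: categorical, group: comorbidity,    levels: ["yes", "no"],                allows_unknown: true}
  - {name: shortbreath,       kind: categorical, group: symptom,        levels: ['1', '2', '3'],          allows_unknown: false}
  - {name: cough,             kind: categorical, group: symptom,        levels: ['1', '2', '3'],          allows_unknown: false}
  - {name: wheeze,            kind: categorical, group: symptom,        levels: ['1', '2', '3'],          allows_unknown: false}
  - {name: sputum_col,        kind: categorical, group: symptom,        levels: ["yes", "no"],                allows_unknown: false}
  - {name: sputum_vol,        kind: categorical, group: symptom,        levels: ["yes", "no"],                allows_unknown: false}
  - {name: infection,         kind: categorical, group: symptom,        levels: ["yes", "no"],                allows_unknown: false}
  - {name: med_comp,          kind: categorical, group: symptom,        levels: ['1', '2', '3'],          allows_unknown: false}
  - {name: sleeplessness,     kind: categorical, group: symptom,        levels: ["yes", "no"],                allows_unknown: false}
  - {name: mmrc_cur,          kind: categorical, group: symptom,        levels: ['1', '2', '3', '4', '5'], allows_unknown: false}
  - {name: o2sat,             kind: continuous,  group: vital,          range: [50, 100], units: percent, allows_unknown: true}
  - {name: fev1,              kind: continuous,  group: vital,          range: [1, 100],  units: pct_predicted, allows_unknown: true}
  - {name: heartrate,         kind: continuous,  group: vital,          range: [30, 220], units: bpm,     allows_unknown: true}
  - {name: temperature,       kind: continuous,  group: vital,          range: [90, 108], units: degF,    allows_unknown: true}
  - {name: o2sat_base,        kind: continuous,  group: baseline_vital, range: [50, 100], units: percent, allows_unknown: true}
  - {name: fev1_base,         kind: continuous,  group: baseline_vital, range: [1, 100],  units: pct_predicted, allows_unknown: true}
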